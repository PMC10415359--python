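# g4origin

Analysis toolkit linking **clustered G-quadruplex motifs (pG4s)** to **DNA
replication origins**, for genomicists studying replication initiation in
vertebrate genomes. The package covers the full post-alignment chain:
motif detection and cluster classification, GC/size-matched random-
background enrichment statistics, strand-aware origin–motif association,
anchored coverage meta-profiles, origin-strength scoring, and Repli-seq
replication-timing analysis — plus a fully ground-truthed synthetic-data
generator so every stage can be exercised without external datasets.

## The statistics at the core

**pG4s and clusters.** A pG4 is a match to the canonical quadparser rule
G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3, scanned on both strands (minus-strand
motifs are C-rich on the reference). *Clustered* pG4s are runs of 2–6
same-strand motifs with gaps ≤ 100 bp — the cis-signal whose association
with replication origins this toolkit quantifies; single motifs are
*monomeric*, longer runs are reported as *oversize*.

**Enrichment (logOR).** Real segments (e.g. origins) and random segments
matched per feature on exact length and GC bin are extended ±1 kb around
their anchors; a binary flag marks ≥1 bp overlap with a feature class.
Logistic regression `class ~ flag` gives the log-odds ratio

    logOR = ln(ad / bc),   se = sqrt(1/a + 1/b + 1/c + 1/d)

(a/b: flagged/unflagged real, c/d: random), with a two-sided Wald test.
logOR = 0 means the feature is equally associated with real and random
segments; logOR > 0 means stronger association with the real segments.

**Replication timing.** S-phase fraction reads (S1 early … S4 late) in
50-kb windows at 10-kb intervals are normalized by an asynchronous
sample, standardized, spline-smoothed, and combined as the weighted
average

    WA = 0.750·S1 + 0.583·S2 + 0.417·S3 + 0.250·S4

(higher = earlier). Locus-level timing changes between two conditions use
the RT-shift statistic on %S1..%S4 vectors:

    RT shift = −ΔL + ΔE,  ΔL = %(S3+S4)_with − %(S3+S4)_without,
                          ΔE = %S1_with − %S1_without

**Origin strength** is SNS reads within an origin divided by origin
length (reads/bp); *strong* origins are the top 25%.

See `docs/methods.md` for assumptions, parameter rationale, and the
synthetic-data model.

## Worked example

Run the full synthetic pipeline (two 500-kb chromosomes, 150 origins):

```python
from g4origin.pipeline import run_pipeline
from g4origin.simulate import SimulationConfig

report = run_pipeline(
    SimulationConfig(seed=7, n_chroms=2, chrom_length=500_000, n_origins=150),
    "out/",
)
for r in report["enrichment"]:
    print(f"{r['feature']:<14} logOR={r['logor']:+.3f} se={r['se']:.3f} "
          f"p={r['p_value']:.2e}")
print(report["rt"])
```

prints

```
pg4_monomeric  logOR=+0.922 se=0.249 p=2.09e-04
pg4_clustered  logOR=+1.777 se=0.309 p=9.17e-09
nfr            logOR=+1.616 se=0.323 p=5.70e-07
h2az           logOR=+0.852 se=0.246 p=5.33e-04
cgi            logOR=+0.105 se=0.453 p=8.17e-01
{'delta_e': 20.785, 'delta_l': -19.929, 'rt_shift': 40.715, 'locus': ['chr1', 495000]}
```

Origins are strongly enriched for clustered pG4s and NFRs relative to
GC/size-matched random segments (positive logOR, tiny Wald p), weakly for
monomeric pG4s and H2A.Z, and not for CGIs in this simulation — matching
how the generator planted them. The RT block recovers the planted local
replication-timing advance: 20 percentage points of nascent-strand signal
moved from the late fractions to S1 gives ΔE ≈ +20, ΔL ≈ −20, hence an RT
shift ≈ +40 (earlier replication).

The same stages are available as a command line tool:

```bash
g4origin simulate --seed 7 --outdir sim/
g4origin detect-pg4 --fasta sim/genome.fa --out motifs.bed
g4origin cluster --motifs motifs.bed --outdir clusters/
g4origin run --seed 7 --outdir run/          # everything, with a JSON report
```

## Layout

```
src/g4origin/
  core.py            intervals, genome, BED/FASTA/bedGraph I/O, merging, GC
  motifs.py          pG4 detection and monomer/cluster/oversize partition
  matched_random.py  GC/size-matched random background sampler
  association.py     overlap flags, strand-aware flags, logistic enrichment
  profiles.py        anchored sliding-window coverage profiles
  timing.py          Repli-seq processing, WA, RT shift, origin strength
  simulate.py        ground-truthed synthetic genomes/features/reads
  pipeline.py        stage orchestration and JSON report
  cli.py             `g4origin` command line tool
```
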