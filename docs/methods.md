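# Methods

## Scope and model

`g4origin` implements the computational analysis linking clustered putative
G-quadruplex motifs (pG4s) to DNA replication origins in vertebrate
genomes, together with the Repli-seq replication-timing statistics used to
characterize origin activity. The package operates downstream of read
mapping and peak calling: its inputs are a genome (FASTA) and feature or
read intervals (BED6), or the outputs of its own synthetic-data generator.

The analytical chain is:

1. **pG4 detection.** Both strands are scanned for the canonical quadparser
   pattern `G{3,}(N{1,7}G{3,}){3}` (four G-tracts of ≥3 G separated by
   loops of 1–7 bp). The minus strand is scanned as the reverse complement,
   so C-rich motifs on the reference ("pC4s") are reported as minus-strand
   pG4s at reference coordinates. Matching is leftmost-greedy and
   non-overlapping per strand; overlapping motifs on opposite strands are
   both kept. Published pG4 annotations can be supplied as BED6 instead of
   running the detector.
2. **Cluster classification.** Same-strand motifs are chained transitively
   whenever consecutive gaps are ≤ 100 bp (the length of DNA wrapped around
   one nucleosome). Runs of 2–6 motifs are *clustered* pG4s — the dimeric
   cis-signal of interest — runs of 1 are monomers, and longer runs are
   reported separately as *oversize* (assignable by configuration, since
   the category definition is bounded above).
3. **Matched random background.** Each feature is paired with random
   segments of identical length whose GC fraction falls in the same GC bin
   (2% bins by default), positioned uniformly over the genome by rejection
   sampling. Features whose bin cannot be matched are excluded together
   with their (absent) partners, keeping the design paired.
4. **Enrichment.** Segments and features are extended ±1 kb around their
   anchor point (the integer midpoint by default); a binary flag records
   ≥1 bp intersection of the extended windows. Enrichment of real over
   random segments is the flag coefficient of the logistic regression
   `class ~ intercept + flag` — the log-odds ratio (logOR), equal to
   ln(ad/bc) of the 2×2 table for a single binary covariate — with
   se = √(1/a+1/b+1/c+1/d) and a two-sided Wald test. Zero cells receive
   the Haldane–Anscombe +0.5 correction with an explicit flag. A
   strand-aware variant flags origins with a plus-strand pG4 in
   [peak−1 kb, peak) or a minus-strand pG4 in [peak, peak+1 kb).
5. **Coverage profiles.** Feature counts in sliding windows (20 bp wide,
   stepping 10 bp, ±1 kb span → 199 offsets) around anchors, averaged
   across anchors with per-offset standard errors. Items are counted in
   every window they intersect (intersection counting, not per-bp pileup).
   Minus-strand anchors can be mirrored so profiles read 5′→3′; pG4
   anchors default to the first position, NFR/H2A.Z anchors to the
   midpoint.
6. **Origin strength.** SNS reads (assigned by midpoint) within an origin
   divided by origin length (reads/bp). Strong origins are the top 25% of
   the strength distribution, with threshold ties all included. Strength is
   stratified by CGI status and by counts of monomeric/clustered pG4s
   within the 1-kb-extended origin span, with two-sided 95% Student-t CIs
   per group (undefined and flagged for singleton groups).
7. **Replication timing.** S-phase fraction reads (S1 early … S4 late) are
   counted in 50-kb windows at 10-kb intervals (window assignment by read
   midpoint; trailing partial windows keep their true width). Each
   fraction is normalized by the asynchronous sample for global and local
   coverage — r_f(w) = (c_f(w)/Σc_f)/(a(w)/Σa) — centered and standardized
   over windows with non-zero asynchronous coverage, then smoothed with a
   cubic smoothing spline per chromosome. The single combined profile is
   the weighted average

       WA = 0.750·S1 + 0.583·S2 + 0.417·S3 + 0.250·S4

   where an increase indicates earlier replication. The locus-level RT
   shift compares %S1..%S4 vectors of two conditions:
   ΔL = %(S3+S4)_with − %(S3+S4)_without, ΔE = %S1_with − %S1_without,
   RT shift = −ΔL + ΔE (positive = earlier). Percent vectors are validated
   to sum to 100 rather than silently renormalized.

## Key parameters

| Parameter | Default | Rationale |
|---|---|---|
| G-tract length | 3 | classical quadparser rule |
| loop length | 1–7 bp | classical quadparser rule |
| cluster gap | ≤ 100 bp | nucleosomal DNA length; matches `mergeBed -d 100` semantics (a gap equal to the maximum still merges; a strict `<` switch exists) |
| cluster size | 2–6 | bounded category definition |
| extension flank | 1000 bp | segment–feature association window |
| GC bin width | 0.02 | exact GC matching is infeasible; binning is recorded in output metadata |
| profile window/step/span | 20/10/1000 bp | meta-profile resolution |
| Repli-seq window/step | 50/10 kb | timing track resolution |
| strong-origin quantile | 0.75 | top 25% definition |
| spline penalty | GCV | the smoothing parameter is otherwise unspecified; generalized cross-validation per chromosome, exposed as a parameter |

Anchor points are integer midpoints (floor) because peak summits are not
available without signal data; a "start" (first-position) mode serves
motif-anchored profiles. Coordinates are 0-based half-open everywhere.
N bases are excluded from GC denominators; all-N intervals are flagged
(NaN) and excluded from matching.

## Synthetic data generator

The generator produces a multi-chromosome genome with full ground truth so
every stage has a no-download test surface. Reference conditions: 5
chromosomes × 2 Mb, base GC 0.42, 30 planted monomeric pG4s and 8 planted
clusters per Mb, 600 origins of 300 bp, SNS background 0.005 reads/bp,
Repli-seq depth 300 reads per 50-kb window. Motif densities are far below
real genome-wide pG4 densities (~350/Mb in chicken); they are chosen so
that the flagged fraction of the genome (~3.5% for clusters) yields stable
2×2 tables at desk scale while planted units remain separable.

Design points that matter for correctness:

- **Planted motifs are exact.** Loops and inter-motif spacers are drawn at
  background GC under constraints (no G- or C-run reaching the tract
  length, non-G edges, gaps ≥ 8 bp > the loop maximum), so the detector
  recovers exactly the planted monomer/cluster structure, and planted
  units do not distort the local GC landscape the matched sampler sees.
  An early all-A/T filler design made planted neighborhoods low-GC magnets
  for GC-matched segments and visibly biased the null flag rate.
- **Analytic implied logOR.** Origins are placed near a random cluster
  with probability p_c (uniform jitter ±1.5 kb, guaranteeing the flag),
  near a monomer with p_m, and otherwise uniformly over the genome, where
  they can still be flagged by chance with probability p0 (the flagged
  genome fraction, computed exactly from the planted anchors). The implied
  flag probability p1 = p_near + (1−p_c−p_m)·p0 gives the true
  logOR = logit(p1) − logit(p0) in closed form; target-logOR settings
  invert this relation. Placing background origins *outside* the flag
  space instead makes the origins' GC-bin distribution underrepresent
  flagged regions and biases the matched null — another rejected design.
- **Origins never overlap** (minimum spacing of one origin length), so
  per-origin read counts are separable and the strength estimator is
  unbiased (slope 1 against truth, intercept = background rate).
- **Strengths are additive**: baseline + β_cluster·(clusters in the
  extended span) + β_monomer·(monomers) + β_CGI·(CGI overlap), with
  Poisson(strength × length) reads uniform within the origin.
- **Repli-seq** uses a sinusoidal early/late timing landscape (period
  2 × 500 kb); window totals are Poisson and split multinomially between
  fractions by the local timing. The planted RT advance moves 20
  percentage points of late (S3+S4) probability mass to S1 in the windows
  of a late-replicating locus, using the same half-open window-midpoint
  selection as the measurement, so the expected RT shift is exactly 40.
- NFRs are planted 5′ of origin-associated clusters (strand-aware), H2A.Z
  peaks near pG4 units irrespective of origin status, emulating the
  asymmetric NFR pattern and the non-specific H2A.Z pattern respectively.

What the generator does *not* emulate: sequencing error, mappability and
GC amplification bias, realistic pG4 sequence diversity (only canonical
planted motifs plus chance matches in random background), spatial
autocorrelation of features beyond the planted structure, and real
chromatin. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated model, not performance on real
sequencing data.

## Numerical choices and degenerate inputs

- Standardization precedes smoothing; the WA combines the smoothed tracks
  (a switch uses raw standardized tracks).
- Windows with zero asynchronous coverage are masked (NaN) rather than
  normalized; chromosomes with fewer than 5 usable windows skip smoothing.
- Sorting ties break on (chrom, start, end, strand); all outputs are
  deterministic for a fixed seed. The sampler derives one independent RNG
  stream per feature index from the root seed, so adding features does not
  perturb earlier draws.
- The logistic fit uses a frequency-weighted binomial GLM when all four
  cells are positive (it equals the closed form to ≤1e−6, which the test
  suite verifies against an independent closed-form oracle) and the
  corrected closed form otherwise.
- `strong_origins` uses the linear-interpolation quantile; all ties at the
  threshold are included.

## Problem sizes used by the test suite

Parameter-recovery tests run the full pipeline on 5 × 2 Mb genomes: 200
replicates (50 per planted logOR level in {0, 0.5, 1.0, 1.5}) for logOR CI
coverage, 100 seeds for the RT-shift mean, and 200 replicates (fixed motif
layout, fresh origins and reads) for the strength-effect recovery. Unit
and property tests use 50–500 kb genomes. The full suite completes in a
few minutes on one CPU.

## Known limitations

- The Wald CI is first-order; with very sparse flags (cells < ~5) its
  coverage degrades, which bounds how small a synthetic genome the
  recovery conditions can use.
- The matched sampler's null is exactly paired per feature but does not
  model spatial autocorrelation; permutation or block-bootstrap nulls are
  out of scope.
- Monomeric-pG4 ground-truth logORs are approximate at realistic GC
  because chance canonical motifs in the random background add detected
  monomers that the placement model does not track; clustered-pG4 truths
  are essentially exact (chance clusters are rare).
- The locus %S1..%S4 vectors consumed by the RT-shift statistic are an
  input contract; the generator derives them from window counts around the
  locus.
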