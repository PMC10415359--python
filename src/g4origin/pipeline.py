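"""End-to-end orchestration: simulate -> detect -> cluster -> sample-random
-> enrich -> profile -> strength -> timing, with a machine-readable report.

This is the library behind the ``g4origin`` command line tool; each stage is
also callable on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, matched_random, motifs, profiles, timing
from .core import GenomeSequence, IntervalSet, write_bed, write_bedgraph
from .simulate import SimulationConfig, simulate_all

log = logging.getLogger("g4origin")


def estimate_feature_enrichment(
    segments: IntervalSet,
    feature_sets: dict[str, IntervalSet],
    genome: GenomeSequence,
    seed: int = 0,
    samples_per_feature: int = 3,
    extend_flank: int = 1000,
    gc_bin_width: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched-random sampling plus per-feature logistic enrichment.

    Returns (association table, enrichment report).
    """
    cfg = matched_random.MatchedSamplerConfig(
        samples_per_feature=samples_per_feature,
        gc_bin_width=gc_bin_width,
        seed=seed,
    )
    rnd = matched_random.sample_matched_random(segments, genome, cfg)
    kept = matched_random.matched_features(segments, rnd)
    table = association.association_table(
        kept, rnd.intervals, feature_sets, extend_flank=extend_flank
    )
    report = association.enrichment_report(table)
    return table, report


def detect_and_cluster(
    genome: GenomeSequence,
    max_gap: int = 100,
    min_k: int = 2,
    max_k: int = 6,
    **detector_kwargs,
) -> tuple[list[motifs.PG4Motif], motifs.PG4ClusterSet]:
    found = motifs.detect_pg4(genome, **detector_kwargs)
    return found, motifs.cluster_pg4(found, max_gap=max_gap, min_k=min_k, max_k=max_k)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    sim_config: SimulationConfig,
    outdir: str | Path,
    samples_per_feature: int = 3,
) -> dict:
    """Full synthetic run: every stage output is written under ``outdir``
    and declared in the returned JSON-serializable report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": {}, "seed": sim_config.seed}
    t0 = time.time()

    def stage(name: str):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}

    def declare(name: str, path: Path):
        report["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    stage("simulate")
    sim = simulate_all(sim_config)
    genome, truth = sim.genome, sim.truth
    fasta = outdir / "genome.fa"
    genome.to_fasta(fasta)
    declare("genome_fasta", fasta)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    declare("truth_json", truth_path)
    cfg_path = outdir / "sim_config.yaml"
    sim_config.to_yaml(cfg_path)
    declare("sim_config", cfg_path)
    for name, iset in sim.features.items():
        p = outdir / f"{name}.bed"
        write_bed(iset, p)
        declare(f"{name}_bed", p)
    sns_path = outdir / "sns_reads.bed"
    write_bed(sim.sns_reads, sns_path)
    declare("sns_reads_bed", sns_path)

    stage("detect_pg4")
    found, clusters = detect_and_cluster(genome)
    for label, iset in (
        ("pg4_monomeric", clusters.monomer_intervals()),
        ("pg4_clustered", clusters.cluster_spans()),
        ("pg4_oversize", clusters.oversize_spans()),
    ):
        p = outdir / f"{label}.bed"
        write_bed(iset, p)
        declare(f"{label}_bed", p)
    fractions = clusters.category_fractions()
    report["pg4"] = {"n_motifs": len(found), **fractions}

    stage("enrich")
    feature_sets = {
        "pg4_monomeric": clusters.monomer_intervals(),
        "pg4_clustered": clusters.cluster_spans(),
        "nfr": sim.features["nfr"],
        "h2az": sim.features["h2az"],
        "cgi": sim.features["cgi"],
    }
    origins = sim.features["origins"]
    table, enrich = estimate_feature_enrichment(
        origins, feature_sets, genome,
        seed=sim_config.seed, samples_per_feature=samples_per_feature,
    )
    table_path = outdir / "association_table.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    declare("association_table", table_path)
    enrich_path = outdir / "enrichment.tsv"
    enrich.to_csv(enrich_path, sep="\t", index=False)
    declare("enrichment", enrich_path)
    report["enrichment"] = enrich.to_dict(orient="records")

    stage("strand_aware")
    sa = association.strand_aware_origin_pg4_flags(origins, found)
    report["strand_aware"] = {
        "frac_flagged": float(sa["flag"].mean()),
        "frac_plus_upstream": float(sa["plus_upstream"].mean()),
        "frac_minus_downstream": float(sa["minus_downstream"].mean()),
    }

    stage("profile")
    prof = profiles.coverage_profile(
        clusters.cluster_spans(),
        sim.features["nfr"],
        profiles.ProfileConfig(anchor_mode="first-position", orient_by_strand=True),
        genome=genome,
    )
    prof_path = outdir / "nfr_around_clusters.tsv"
    prof.to_tsv(prof_path)
    declare("nfr_profile", prof_path)

    stage("strength")
    strengths = timing.origin_strength(origins, sim.sns_reads)
    strong = timing.strong_origins(origins, strengths)
    strong_path = outdir / "strong_origins.bed"
    write_bed(strong, strong_path)
    declare("strong_origins_bed", strong_path)
    strata = timing.stratify_strength(
        origins, strengths, clusters, sim.features["cgi"], genome
    )
    strata_path = outdir / "strength_table.tsv"
    strata.to_csv(strata_path, sep="\t", index=False)
    declare("strength_table", strata_path)
    report["strength"] = {
        "n_strong": len(strong),
        "mean_strength": float(np.mean(strengths)),
    }

    stage("rt")
    rs = sim.repliseq
    prof_rt = timing.normalize_standardize_smooth(rs.without_advance)
    wa = prof_rt.wa()
    wa_path = outdir / "wa_timing.bedgraph"
    write_bedgraph(prof_rt.to_bedgraph_records(wa), wa_path)
    declare("wa_bedgraph", wa_path)
    pw = timing.fraction_percentages(
        rs.with_advance, rs.locus_chrom, rs.locus_center,
        halfwidth=sim_config.advance_halfwidth,
    )
    pwo = timing.fraction_percentages(
        rs.without_advance, rs.locus_chrom, rs.locus_center,
        halfwidth=sim_config.advance_halfwidth,
    )
    shift = timing.rt_shift(pw, pwo)
    report["rt"] = {
        "delta_e": shift.delta_e,
        "delta_l": shift.delta_l,
        "rt_shift": shift.rt_shift,
        "locus": [rs.locus_chrom, rs.locus_center],
    }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
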