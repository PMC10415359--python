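"""Synthetic-data generator: determinism, planted structure, recovery."""

import numpy as np
import pytest

from g4origin import (
    SimulationConfig,
    audit_ground_truth,
    overlap_flags,
    p_origin_for_logor,
    simulate_all,
    simulate_genome_with_motifs,
    simulate_origins_and_marks,
    simulate_repliseq_counts,
)
from g4origin.profiles import ProfileConfig, coverage_profile
from g4origin.simulate import timing_landscape
from g4origin.timing import fraction_percentages, normalize_standardize_smooth, origin_strength, rt_shift


SMALL = dict(n_chroms=1, chrom_length=400_000, n_origins=80)


class TestDeterminism:
    def test_same_seed_identical_genome_and_truth(self):
        a_g, a_t = simulate_genome_with_motifs(SimulationConfig(seed=5, **SMALL))
        b_g, b_t = simulate_genome_with_motifs(SimulationConfig(seed=5, **SMALL))
        assert a_g.sequences == b_g.sequences
        assert [m.interval for m in a_t.motifs] == [m.interval for m in b_t.motifs]

    def test_different_seed_differs(self):
        a_g, _ = simulate_genome_with_motifs(SimulationConfig(seed=5, **SMALL))
        c_g, _ = simulate_genome_with_motifs(SimulationConfig(seed=6, **SMALL))
        assert a_g.sequences != c_g.sequences

    def test_fasta_roundtrip_byte_identical(self, tmp_path, small_sim):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        small_sim.genome.to_fasta(p1)
        small_sim.genome.to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPlanting:
    def test_null_planting(self):
        cfg = SimulationConfig(seed=1, monomer_rate=0, cluster_rate=0, **SMALL)
        _, truth = simulate_genome_with_motifs(cfg)
        assert not truth.motifs
        assert len(truth.cluster_spans) == 0

    def test_planted_count_poisson(self):
        """Planted unit counts over 50 seeds stay within 3 sigma of the
        Poisson expectation."""
        cfg_kw = dict(n_chroms=1, chrom_length=300_000, n_origins=10)
        mono = clust = 0
        n_seeds = 50
        for seed in range(n_seeds):
            _, truth = simulate_genome_with_motifs(
                SimulationConfig(seed=seed, **cfg_kw)
            )
            mono += len(truth.monomer_intervals)
            clust += len(truth.cluster_spans)
        mb = 0.3 * n_seeds
        cfg = SimulationConfig(**cfg_kw)
        for total, rate in ((mono, cfg.monomer_rate), (clust, cfg.cluster_rate)):
            expected = rate * mb
            assert abs(total - expected) <= 3 * np.sqrt(expected)

    def test_audit_consistency(self, small_sim):
        audit_ground_truth(small_sim.genome, small_sim.truth)

    def test_cluster_gaps_and_sizes_within_bounds(self, small_sim):
        truth = small_sim.truth
        by_cluster = {}
        for m, cid in zip(truth.motifs, truth.motif_cluster_id):
            if cid is not None:
                by_cluster.setdefault(cid, []).append(m)
        cfg = SimulationConfig()
        for members in by_cluster.values():
            assert 2 <= len(members) <= 6
            ms = sorted(members, key=lambda m: m.start)
            for a, b in zip(ms, ms[1:]):
                assert cfg.gap_min <= b.start - a.end <= cfg.gap_max

    def test_infeasible_density_raises(self):
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=60_000, monomer_rate=2000, n_origins=5
        )
        with pytest.raises(RuntimeError):
            simulate_genome_with_motifs(cfg)


class TestOrigins:
    def test_category_flags_exact(self, small_sim):
        truth = small_sim.truth
        flags = overlap_flags(truth.origins, truth.cluster_spans, extend_flank=1000)
        for f, cat in zip(flags, truth.origin_category):
            if cat == "clustered":
                assert f == 1
            elif cat == "monomeric":
                assert f == 0

    def test_origins_never_overlap(self, small_sim):
        by_chrom = small_sim.truth.origins.by_chrom()
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start >= a.end

    def test_target_logor_realized_in_truth(self):
        cfg = SimulationConfig(seed=2, target_logor_clustered=1.2, **SMALL)
        genome, truth = simulate_genome_with_motifs(cfg)
        simulate_origins_and_marks(cfg, genome, truth)
        assert truth.true_logor_clustered == pytest.approx(1.2, abs=1e-9)

    def test_implied_probability_inverts_logit(self):
        for p0 in (0.01, 0.1, 0.4):
            for L in (0.0, 0.7, 1.5):
                p1 = p_origin_for_logor(L, p0)
                back = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
                assert back == pytest.approx(L, abs=1e-12)


class TestSNS:
    def test_strength_estimator_slope_near_one(self):
        slopes = []
        for seed in (3, 4, 5):
            sim = simulate_all(SimulationConfig(seed=seed, n_chroms=2,
                                                chrom_length=1_000_000,
                                                n_origins=300))
            est = origin_strength(sim.features["origins"], sim.sns_reads)
            slopes.append(np.polyfit(sim.truth.true_strengths, est, 1)[0])
        assert abs(np.mean(slopes) - 1) < 0.05

    def test_null_strength_only_background(self):
        cfg = SimulationConfig(
            seed=6, baseline_strength=0.0, beta_cluster=0.0,
            beta_monomer=0.0, beta_cgi=0.0, **SMALL
        )
        sim = simulate_all(cfg)
        est = origin_strength(sim.features["origins"], sim.sns_reads)
        assert np.all(sim.truth.true_strengths == 0)
        assert est.mean() == pytest.approx(cfg.sns_background_per_bp, rel=0.3)


class TestRepliseq:
    def test_planted_advance_recovered(self, small_sim):
        rs = small_sim.repliseq
        pw = fraction_percentages(rs.with_advance, rs.locus_chrom, rs.locus_center)
        pwo = fraction_percentages(rs.without_advance, rs.locus_chrom, rs.locus_center)
        shift = rt_shift(pw, pwo).rt_shift
        assert shift == pytest.approx(2 * SimulationConfig().rt_advance_points, abs=12)

    def test_no_advance_centered_on_zero(self):
        genome, _ = simulate_genome_with_motifs(
            SimulationConfig(seed=1, monomer_rate=0, cluster_rate=0,
                             n_cgis_per_chrom=0, n_chroms=1,
                             chrom_length=2_000_000, n_origins=5)
        )
        shifts = []
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, rt_advance_points=0.0,
                                   n_chroms=1, chrom_length=2_000_000,
                                   n_origins=5)
            rs = simulate_repliseq_counts(cfg, genome)
            pw = fraction_percentages(rs.with_advance, rs.locus_chrom, rs.locus_center)
            pwo = fraction_percentages(rs.without_advance, rs.locus_chrom, rs.locus_center)
            shifts.append(rt_shift(pw, pwo).rt_shift)
        assert abs(np.mean(shifts)) < 2.0

    def test_wa_higher_in_early_domains(self):
        genome, _ = simulate_genome_with_motifs(
            SimulationConfig(seed=2, monomer_rate=0, cluster_rate=0,
                             n_cgis_per_chrom=0, n_chroms=1,
                             chrom_length=2_000_000, n_origins=5)
        )
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_chroms=1,
                                   chrom_length=2_000_000, n_origins=5)
            rs = simulate_repliseq_counts(cfg, genome)
            prof = normalize_standardize_smooth(rs.without_advance)
            wa = prof.wa()
            tau = timing_landscape(cfg, rs.without_advance.midpoints)
            assert np.nanmean(wa[tau > 0.8]) > np.nanmean(wa[tau < 0.2])


class TestNFRAsymmetry:
    def test_nfr_enriched_5prime_of_origin_clusters(self, small_sim):
        """NFRs are planted 5' of origin-associated clusters, so the
        strand-oriented profile is asymmetric with more signal upstream."""
        prof = coverage_profile(
            small_sim.truth.cluster_spans,
            small_sim.features["nfr"],
            ProfileConfig(anchor_mode="first-position", orient_by_strand=True),
            genome=small_sim.genome,
        )
        n = len(prof.offsets)
        upstream = np.nansum(prof.values[: n // 2])
        downstream = np.nansum(prof.values[n // 2 + 1:])
        assert upstream > downstream
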