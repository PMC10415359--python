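"""Repli-seq timing processing, RT shift, and origin strength."""

import numpy as np
import pandas as pd
import pytest

from g4origin.core import GenomeSequence, GenomicInterval, IntervalSet
from g4origin.motifs import PG4ClusterSet
from g4origin.timing import (
    FRACTIONS,
    FractionCounts,
    count_in_windows,
    fraction_percentages,
    make_windows,
    normalize_standardize_smooth,
    origin_strength,
    rt_shift,
    stratify_strength,
    strong_origins,
    weighted_average,
    windowed_counts,
)

from conftest import random_genome
from oracles import brute_origin_strength, brute_window_counts, sort_slice_strong


def _reads(chrom, positions, length=2):
    return IntervalSet(
        [GenomicInterval(chrom, int(p), int(p) + length) for p in positions]
    )


class TestWindows:
    def test_trailing_partial_window_kept(self):
        genome = GenomeSequence({"chr1": "A" * 73_000})
        w = make_windows(genome, window=50_000, step=10_000)
        assert list(w["start"]) == [0, 10_000, 20_000, 30_000, 40_000,
                                    50_000, 60_000, 70_000]
        assert w["end"].iloc[0] == 50_000 and w["end"].iloc[-1] == 73_000

    def test_step_above_window_rejected(self):
        genome = GenomeSequence({"chr1": "A" * 1000})
        with pytest.raises(ValueError):
            make_windows(genome, window=100, step=200)

    def test_single_read_hits_window_per_step_ratio(self):
        genome = GenomeSequence({"chr1": "A" * 200_000})
        w = make_windows(genome)
        counts = count_in_windows(_reads("chr1", [105_000]), w)
        assert counts.sum() == 5  # window/step = 50k/10k overlapping windows
        hit = w[counts > 0]
        assert all(
            s <= 105_001 < e for s, e in zip(hit["start"], hit["end"])
        )

    def test_counts_match_bruteforce(self):
        genome = random_genome(41, {"chr1": 80_000, "chr2": 40_000})
        w = make_windows(genome, window=5_000, step=2_000)
        rng = np.random.default_rng(12)
        reads = []
        for _ in range(10_000):
            chrom = str(rng.choice(["chr1", "chr2"]))
            s = int(rng.integers(0, genome.lengths[chrom] - 100))
            reads.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 100))))
        reads = IntervalSet(reads)
        got = count_in_windows(reads, w)
        assert np.array_equal(got, brute_window_counts(reads, w))

    def test_windowed_counts_requires_all_fractions(self):
        genome = GenomeSequence({"chr1": "A" * 100_000})
        with pytest.raises(ValueError, match="missing"):
            windowed_counts({"S1": IntervalSet()}, IntervalSet(), genome)


def _fc(counts_by_fraction, async_counts, window=1000, step=1000, chrom="chr1"):
    n = len(async_counts)
    windows = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": np.arange(n) * step,
            "end": np.arange(n) * step + window,
        }
    )
    return FractionCounts(
        windows,
        {f: np.asarray(counts_by_fraction[f]) for f in FRACTIONS},
        np.asarray(async_counts),
        window,
        step,
    )


class TestNormalization:
    def test_proportional_to_async_gives_flat_zero(self):
        rng = np.random.default_rng(2)
        a = rng.integers(50, 150, 40)
        fc = _fc({f: a * (i + 1) for i, f in enumerate(FRACTIONS)}, a)
        prof = normalize_standardize_smooth(fc)
        for f in FRACTIONS:
            assert np.allclose(prof.standardized[f], 0.0, atol=1e-12)
            assert np.allclose(prof.smoothed[f], 0.0, atol=1e-9)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(3)
        counts = {f: rng.integers(10, 200, 50) for f in FRACTIONS}
        a = rng.integers(50, 100, 50)
        p1 = normalize_standardize_smooth(_fc(counts, a))
        counts10 = dict(counts)
        counts10["S2"] = counts["S2"] * 10
        p2 = normalize_standardize_smooth(_fc(counts10, a))
        assert np.allclose(p1.standardized["S2"], p2.standardized["S2"], atol=1e-12)

    def test_standardized_moments(self):
        rng = np.random.default_rng(4)
        counts = {f: rng.integers(10, 200, 200) for f in FRACTIONS}
        a = rng.integers(50, 100, 200)
        prof = normalize_standardize_smooth(_fc(counts, a))
        for f in FRACTIONS:
            z = prof.standardized[f][prof.mask]
            assert abs(z.mean()) < 1e-6
            assert abs(z.std() - 1) < 1e-6

    def test_zero_async_windows_masked(self):
        a = np.array([100, 0, 100, 100, 80, 90, 100, 100])
        counts = {f: np.full(8, 50) for f in FRACTIONS}
        prof = normalize_standardize_smooth(_fc(counts, a))
        assert not prof.mask[1]
        assert np.isnan(prof.standardized["S1"][1])

    def test_all_zero_async_rejected(self):
        counts = {f: np.full(4, 5) for f in FRACTIONS}
        with pytest.raises(ValueError):
            normalize_standardize_smooth(_fc(counts, np.zeros(4)))

    def test_planted_step_landscape_sign(self):
        """S1-enriched left half vs S4-enriched right half is recovered in
        the smoothed standardized S1 track in every seed."""
        n = 100
        left = np.arange(n) < n // 2
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.poisson(300, n)
            s1 = rng.poisson(np.where(left, 450, 150))
            s4 = rng.poisson(np.where(left, 150, 450))
            fc = _fc({"S1": s1, "S2": base, "S3": base, "S4": s4},
                     rng.poisson(300, n), window=50_000, step=10_000)
            prof = normalize_standardize_smooth(fc)
            s = prof.smoothed["S1"]
            if np.nanmean(s[left]) > np.nanmean(s[~left]):
                wins += 1
        assert wins == 100


class TestWeightedAverage:
    def test_printed_coefficients(self):
        assert weighted_average(1, 0, 0, 0) == pytest.approx(0.750)
        assert weighted_average(0, 1, 0, 0) == pytest.approx(0.583)
        assert weighted_average(0, 0, 1, 0) == pytest.approx(0.417)
        assert weighted_average(0, 0, 0, 1) == pytest.approx(0.250)
        assert weighted_average(1, 1, 1, 1) == pytest.approx(2.000)

    def test_linearity_and_early_shift_increases(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=(4, 30))
        wa = weighted_average(*s)
        assert np.allclose(weighted_average(*(2 * s)), 2 * wa)
        shifted = s.copy()
        shifted[0] += 0.5
        shifted[3] -= 0.5
        assert np.all(weighted_average(*shifted) > wa)


class TestRTShift:
    def test_identical_vectors_zero(self):
        r = rt_shift([25, 25, 25, 25], [25, 25, 25, 25])
        assert r.rt_shift == 0.0

    def test_worked_example(self):
        r = rt_shift([40, 30, 20, 10], [25, 25, 25, 25])
        assert r.delta_e == pytest.approx(15)
        assert r.delta_l == pytest.approx(-20)
        assert r.rt_shift == pytest.approx(35)

    def test_five_points_late_to_early_gives_ten(self):
        base = [20, 30, 30, 20]
        moved = [25, 30, 30, 15]
        assert rt_shift(moved, base).rt_shift == pytest.approx(10)

    def test_antisymmetry(self):
        a, b = [40, 30, 20, 10], [10, 20, 30, 40]
        assert rt_shift(a, b).rt_shift == pytest.approx(-rt_shift(b, a).rt_shift)

    @pytest.mark.parametrize(
        "bad", [[50, 50, 0], [30, 30, 30, 30], [-5, 45, 30, 30]]
    )
    def test_malformed_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            rt_shift(bad, [25, 25, 25, 25])

    def test_fraction_percentages_sum_100(self):
        rng = np.random.default_rng(7)
        counts = {f: rng.integers(10, 100, 30) for f in FRACTIONS}
        fc = _fc(counts, rng.integers(10, 100, 30),
                 window=50_000, step=10_000)
        p = fraction_percentages(fc, "chr1", 150_000, 50_000)
        assert p.sum() == pytest.approx(100)


class TestOriginStrength:
    def test_definition(self):
        origins = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        reads = _reads("chr1", np.linspace(1100, 1900, 100))
        assert origin_strength(origins, reads)[0] == pytest.approx(0.1)

    def test_no_reads_zero(self):
        origins = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        assert origin_strength(origins, IntervalSet())[0] == 0.0

    def test_matches_counting_oracle_and_order_invariance(self):
        rng = np.random.default_rng(44)
        origins = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 500)))
            for s in rng.integers(0, 50_000, 50)
        ]
        reads = _reads("chr1", rng.integers(0, 55_000, 3000))
        got = origin_strength(IntervalSet(origins), reads)
        assert np.allclose(got, brute_origin_strength(origins, reads))
        perm = rng.permutation(len(origins))
        shuffled = origin_strength(
            IntervalSet([origins[i] for i in perm]), reads
        )
        assert np.allclose(shuffled, got[perm])


class TestStrongOrigins:
    def test_distinct_strengths_exact_quartile(self):
        rng = np.random.default_rng(9)
        origins = IntervalSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(100)]
        )
        strengths = rng.permutation(100).astype(float)
        assert len(strong_origins(origins, strengths)) == 25

    def test_all_ties_selected(self):
        origins = IntervalSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(10)]
        )
        assert len(strong_origins(origins, np.full(10, 3.0))) == 10

    def test_matches_sort_slice_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            origins = IntervalSet(
                [GenomicInterval("chr1", i * 500, i * 500 + 100) for i in range(n)]
            )
            strengths = np.round(rng.random(n), 2)  # induces ties
            got = sorted(
                (o.chrom, o.start, o.end) for o in strong_origins(origins, strengths)
            )
            assert got == sort_slice_strong(origins, strengths, 0.75)


class TestStratify:
    def _empty_clusters(self):
        return PG4ClusterSet()

    def test_constant_strengths(self):
        genome = GenomeSequence({"chr1": "A" * 100_000})
        origins = IntervalSet(
            [GenomicInterval("chr1", i * 5000, i * 5000 + 300) for i in range(10)]
        )
        table = stratify_strength(
            origins, np.full(10, 0.2), self._empty_clusters(),
            IntervalSet(), genome,
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["mean_strength"] == pytest.approx(0.2)
        assert row["ci_low"] == pytest.approx(0.2) and row["ci_high"] == pytest.approx(0.2)

    def test_singleton_group_ci_undefined(self):
        genome = GenomeSequence({"chr1": "A" * 100_000})
        origins = IntervalSet([GenomicInterval("chr1", 0, 300)])
        table = stratify_strength(
            origins, np.array([0.5]), self._empty_clusters(), IntervalSet(), genome
        )
        assert not table.iloc[0]["ci_defined"]
        assert np.isnan(table.iloc[0]["ci_low"])

    def test_cgi_split_and_counts(self, small_sim):
        from g4origin.motifs import cluster_pg4, detect_pg4
        from g4origin.timing import origin_strength as os_

        cs = cluster_pg4(detect_pg4(small_sim.genome))
        origins = small_sim.features["origins"]
        strengths = os_(origins, small_sim.sns_reads)
        table = stratify_strength(
            origins, strengths, cs, small_sim.features["cgi"], small_sim.genome
        )
        assert table["n"].sum() == len(origins)
        assert set(table["cgi"]) <= {"CGI", "non-CGI"}
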