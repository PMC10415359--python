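"""Repli-seq timing and origin-strength analysis.

S-phase fraction read counts (S1 early ... S4 late) in 50-kb windows at
10-kb intervals are normalized by the asynchronous sample (global and local
coverage), centered and standardized, smoothed with cubic smoothing splines,
and combined into a single weighted-average (WA) timing track:

    WA = 0.750*S1 + 0.583*S2 + 0.417*S3 + 0.250*S4

where an increase in WA indicates earlier replication. The locus-level
RT-shift statistic compares two conditions' fraction percentages:

    dL = %(S3+S4)_with - %(S3+S4)_without
    dE = %S1_with - %S1_without
    RT shift = -dL + dE        (positive = earlier)

Origin strength is SNS reads mapping within an origin divided by origin
length (reads/bp); strong origins are the top 25% of that distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .core import GenomeSequence, IntervalSet
from .motifs import PG4ClusterSet

FRACTIONS = ("S1", "S2", "S3", "S4")
WA_COEFFS = {"S1": 0.750, "S2": 0.583, "S3": 0.417, "S4": 0.250}


# ---------------------------------------------------------------- windows --

@dataclass
class FractionCounts:
    """Read counts per sliding window for the four S-phase fractions and the
    asynchronous control."""

    windows: pd.DataFrame  # columns: chrom, start, end
    counts: dict[str, np.ndarray]
    async_counts: np.ndarray
    window: int = 50_000
    step: int = 10_000

    def __post_init__(self) -> None:
        n = len(self.windows)
        for name, arr in self.counts.items():
            if len(arr) != n:
                raise ValueError(f"counts[{name!r}] length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"negative counts in {name!r}")
        if len(self.async_counts) != n:
            raise ValueError("async_counts length mismatch")

    @property
    def midpoints(self) -> np.ndarray:
        return (
            self.windows["start"].to_numpy() + self.windows["end"].to_numpy()
        ) // 2


def make_windows(
    genome: GenomeSequence, window: int = 50_000, step: int = 10_000
) -> pd.DataFrame:
    """Sliding windows per chromosome; trailing partial windows keep their
    true (shorter) width."""
    if step > window:
        raise ValueError("step must be <= window")
    rows = []
    for chrom, L in genome.lengths.items():
        for start in range(0, L, step):
            rows.append((chrom, start, min(start + window, L)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _midpoint_index(reads: IntervalSet) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(np.array([iv.midpoint for iv in ivs], dtype=np.int64))
        for chrom, ivs in reads.by_chrom().items()
    }


def count_in_windows(reads: IntervalSet, windows: pd.DataFrame) -> np.ndarray:
    """Reads assigned to every window containing their midpoint."""
    idx = _midpoint_index(reads)
    out = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in windows.groupby("chrom", sort=False):
        mids = idx.get(chrom)
        if mids is None:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        out[grp.index] = np.searchsorted(mids, ends, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
    return out


def windowed_counts(
    fraction_reads: dict[str, IntervalSet],
    async_reads: IntervalSet,
    genome: GenomeSequence,
    window: int = 50_000,
    step: int = 10_000,
) -> FractionCounts:
    """Window-level counts for the four fractions plus the asynchronous
    sample."""
    missing = set(FRACTIONS) - set(fraction_reads)
    if missing:
        raise ValueError(f"missing fractions: {sorted(missing)}")
    windows = make_windows(genome, window, step)
    counts = {f: count_in_windows(fraction_reads[f], windows) for f in FRACTIONS}
    return FractionCounts(
        windows, counts, count_in_windows(async_reads, windows), window, step
    )


# ---------------------------------------------------------------- profile --

@dataclass
class RTProfile:
    """Normalized / standardized / smoothed per-fraction timing tracks."""

    windows: pd.DataFrame
    normalized: dict[str, np.ndarray]
    standardized: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    mask: np.ndarray  # True where async coverage allows normalization

    def wa(self, use_smoothed: bool = True) -> np.ndarray:
        return weighted_average_rt(self, use_smoothed=use_smoothed)

    def to_bedgraph_records(self, track: np.ndarray):
        for (_, row), v in zip(self.windows.iterrows(), track):
            if not np.isnan(v):
                yield (row["chrom"], int(row["start"]), int(row["end"]), float(v))


def normalize_standardize_smooth(
    fc: FractionCounts, spline_smoothing: float | None = None
) -> RTProfile:
    """Normalize each fraction by the asynchronous coverage (global and
    local), center and standardize, then smooth with a cubic smoothing
    spline per chromosome.

    ``spline_smoothing`` is the spline penalty (lam); None selects it by
    generalized cross-validation.
    """
    a = fc.async_counts.astype(float)
    mask = a > 0
    if not mask.any():
        raise ValueError("all windows have zero asynchronous coverage")
    a_frac = a / a.sum()

    normalized: dict[str, np.ndarray] = {}
    standardized: dict[str, np.ndarray] = {}
    smoothed: dict[str, np.ndarray] = {}
    mids = fc.midpoints
    chroms = fc.windows["chrom"].to_numpy()
    for f in FRACTIONS:
        c = fc.counts[f].astype(float)
        total = c.sum()
        if total == 0:
            raise ValueError(f"fraction {f} has zero total counts")
        r = np.full(len(c), np.nan)
        r[mask] = (c[mask] / total) / a_frac[mask]
        normalized[f] = r
        mu = np.nanmean(r[mask])
        sd = np.nanstd(r[mask])
        z = np.full(len(c), np.nan)
        if sd > 0:
            z[mask] = (r[mask] - mu) / sd
        else:
            z[mask] = 0.0
        standardized[f] = z
        s = np.array(z)
        for chrom in fc.windows["chrom"].unique():
            sel = (chroms == chrom) & mask
            x = mids[sel].astype(float)
            y = z[sel]
            if len(x) >= 5 and np.all(np.diff(x) > 0):
                spl = make_smoothing_spline(x, y, lam=spline_smoothing)
                s[sel] = spl(x)
        smoothed[f] = s
    return RTProfile(fc.windows, normalized, standardized, smoothed, mask)


def weighted_average(s1, s2, s3, s4):
    """WA = 0.750*S1 + 0.583*S2 + 0.417*S3 + 0.250*S4 (higher = earlier)."""
    return (
        WA_COEFFS["S1"] * np.asarray(s1)
        + WA_COEFFS["S2"] * np.asarray(s2)
        + WA_COEFFS["S3"] * np.asarray(s3)
        + WA_COEFFS["S4"] * np.asarray(s4)
    )


def weighted_average_rt(profile: RTProfile, use_smoothed: bool = True) -> np.ndarray:
    """Combine the four per-fraction tracks into the single WA track."""
    tracks = profile.smoothed if use_smoothed else profile.standardized
    missing = set(FRACTIONS) - set(tracks)
    if missing:
        raise ValueError(f"missing fractions: {sorted(missing)}")
    return weighted_average(*(tracks[f] for f in FRACTIONS))


# --------------------------------------------------------------- RT shift --

@dataclass(frozen=True)
class RTShiftResult:
    """RT shift = -dL + dE, in percentage points; positive = earlier."""

    delta_e: float
    delta_l: float

    @property
    def rt_shift(self) -> float:
        return -self.delta_l + self.delta_e


def _check_percent(vec, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.shape != (4,):
        raise ValueError(f"{name} must have exactly 4 entries (S1..S4)")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 100.0) > 1e-6:
        raise ValueError(f"{name} must sum to 100 (got {v.sum()!r})")
    return v


def rt_shift(percent_with, percent_without) -> RTShiftResult:
    """RT-shift statistic from %S1..%S4 vectors of two conditions."""
    w = _check_percent(percent_with, "percent_with")
    wo = _check_percent(percent_without, "percent_without")
    delta_l = (w[2] + w[3]) - (wo[2] + wo[3])
    delta_e = w[0] - wo[0]
    return RTShiftResult(delta_e=float(delta_e), delta_l=float(delta_l))


def fraction_percentages(
    fc: FractionCounts, chrom: str, center: int, halfwidth: int = 25_000
) -> np.ndarray:
    """%S1..%S4 over the windows whose midpoint lies within
    [center - halfwidth, center + halfwidth) on ``chrom`` — the locus-level
    input to :func:`rt_shift`."""
    mids = fc.midpoints
    sel = (
        (fc.windows["chrom"].to_numpy() == chrom)
        & (mids >= center - halfwidth)
        & (mids < center + halfwidth)
    )
    if not sel.any():
        raise ValueError("no windows in the requested locus")
    sums = np.array([fc.counts[f][sel].sum() for f in FRACTIONS], dtype=float)
    total = sums.sum()
    if total == 0:
        raise ValueError("locus has zero fraction counts")
    return 100.0 * sums / total


# ---------------------------------------------------------------- origins --

def origin_strength(origins: IntervalSet, sns_reads: IntervalSet) -> np.ndarray:
    """SNS reads (by midpoint) within each origin divided by origin length,
    in reads/bp."""
    idx = _midpoint_index(sns_reads)
    out = np.zeros(len(origins))
    for i, origin in enumerate(origins):
        mids = idx.get(origin.chrom)
        n = 0
        if mids is not None:
            n = int(
                np.searchsorted(mids, origin.end, side="left")
                - np.searchsorted(mids, origin.start, side="left")
            )
        out[i] = n / len(origin)
    return out


def strong_origins(
    origins: IntervalSet, strengths: np.ndarray, quantile: float = 0.75
) -> IntervalSet:
    """Origins at or above the given strength quantile (top 25% by default);
    ties at the threshold are all included."""
    strengths = np.asarray(strengths, dtype=float)
    if len(strengths) != len(origins):
        raise ValueError("strengths length must match origins")
    thr = np.quantile(strengths, quantile)
    return IntervalSet(
        [iv for iv, s in zip(origins, strengths) if s >= thr]
    )


def stratify_strength(
    origins: IntervalSet,
    strengths: np.ndarray,
    clusters: PG4ClusterSet,
    cgis: IntervalSet,
    genome: GenomeSequence,
    flank: int = 1000,
    max_count: int = 3,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Group origins by CGI status and by counts of monomeric / clustered
    pG4s within the origin's 1-kb-extended span; report per-group mean
    strength with a two-sided t-based CI.

    Counts >= ``max_count`` are binned together ("3+" by default). Groups of
    size 1 have an undefined CI (NaN bounds, ``ci_defined`` False).
    """
    strengths = np.asarray(strengths, dtype=float)
    mono_mids = clusters.monomer_intervals().anchors("midpoint")
    clust_mids = clusters.cluster_spans().anchors("midpoint")
    cgi_by_chrom = {
        chrom: (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
        for chrom, ivs in cgis.by_chrom().items()
    }

    def count_in(mids: dict[str, np.ndarray], chrom: str, s: int, e: int) -> int:
        pts = mids.get(chrom)
        if pts is None:
            return 0
        return int(
            np.searchsorted(pts, e, side="left")
            - np.searchsorted(pts, s, side="left")
        )

    rows = []
    for i, origin in enumerate(origins):
        s = max(0, origin.start - flank)
        e = min(genome.lengths[origin.chrom], origin.end + flank)
        n_mono = min(count_in(mono_mids, origin.chrom, s, e), max_count)
        n_clust = min(count_in(clust_mids, origin.chrom, s, e), max_count)
        is_cgi = False
        if origin.chrom in cgi_by_chrom:
            starts, ends = cgi_by_chrom[origin.chrom]
            j = np.searchsorted(starts, origin.end, side="left")
            is_cgi = bool(np.any(ends[:j] > origin.start))
        rows.append(
            {
                "origin_index": i,
                "cgi": "CGI" if is_cgi else "non-CGI",
                "n_monomeric": n_mono,
                "n_clustered": n_clust,
                "strength": strengths[i],
            }
        )
    per_origin = pd.DataFrame(rows)

    out = []
    for (cgi, nm, nc), grp in per_origin.groupby(
        ["cgi", "n_monomeric", "n_clustered"]
    ):
        vals = grp["strength"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sem = stats.sem(vals)
            if sem > 0:
                lo, hi = stats.t.interval(ci_level, n - 1, loc=mean, scale=sem)
            else:
                lo = hi = mean
            ci_defined = True
        else:
            lo = hi = float("nan")
            ci_defined = False
        out.append(
            {
                "cgi": cgi,
                "n_monomeric": nm,
                "n_clustered": nc,
                "n": n,
                "mean_strength": mean,
                "ci_low": lo,
                "ci_high": hi,
                "ci_defined": ci_defined,
            }
        )
    return pd.DataFrame(out)
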