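"""Feature co-occurrence flags and logistic-regression enrichment.

Real segments (e.g. replication origins) and their size/GC-matched random
partners are both extended 1 kb around their anchor point; a segment is
flagged for a feature class when the extended windows intersect by at least
1 bp. Enrichment of real over random is the flag coefficient of the logistic
regression class ~ intercept + flag: the log-odds ratio (logOR), with
logOR = 0 meaning the feature is equally associated with real segments and
random segments, logOR > 0 meaning stronger association with real segments.
With a single binary covariate the ML estimate equals ln(ad/bc) of the 2x2
table, and se = sqrt(1/a + 1/b + 1/c + 1/d); significance is the Wald test.

The strand-aware origin variant flags origins with a plus-strand pG4
upstream of the peak or a minus-strand pG4 (a reference-strand pC4)
downstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import GenomicInterval, IntervalSet
from .motifs import PG4Motif


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 counts and the logistic log-odds ratio with its Wald test.

    counts = (a, b, c, d): a real segments with the flag, b real without,
    c random with, d random without. When any cell is zero the
    Haldane-Anscombe +0.5 correction is applied to all cells and
    ``continuity_corrected`` is set.
    """

    counts: tuple[int, int, int, int]
    logor: float
    se: float
    wald_z: float
    p_value: float
    continuity_corrected: bool = False

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.logor - z * self.se, self.logor + z * self.se)


def _anchor_index(features: IntervalSet, mode: str) -> dict[str, np.ndarray]:
    return features.anchors(mode)


def overlap_flags(
    segments: IntervalSet,
    features: IntervalSet,
    extend_flank: int = 1000,
    segment_anchor: str = "midpoint",
    feature_anchor: str = "midpoint",
) -> np.ndarray:
    """1 per segment iff its anchor window [p - flank, p + flank) intersects
    some feature's anchor window by >= 1 bp, i.e. anchors closer than
    2 * flank."""
    if extend_flank <= 0:
        raise ValueError("extend_flank must be > 0")
    feat_anchors = _anchor_index(features, feature_anchor)
    flags = np.zeros(len(segments), dtype=np.int8)
    reach = 2 * extend_flank
    for i, seg in enumerate(segments):
        pts = feat_anchors.get(seg.chrom)
        if pts is None or len(pts) == 0:
            continue
        p = seg.anchor(segment_anchor)
        # strict inequality both sides: |p - q| < 2*flank <=> half-open
        # extended windows share >= 1 bp
        lo = np.searchsorted(pts, p - reach, side="right")
        hi = np.searchsorted(pts, p + reach, side="left")
        flags[i] = 1 if hi > lo else 0
    return flags


def strand_aware_origin_pg4_flags(
    origins: IntervalSet,
    motifs: list[PG4Motif],
    flank: int = 1000,
    origin_anchor: str = "midpoint",
) -> pd.DataFrame:
    """Strand-aware pG4-origin association.

    Per origin peak p: ``plus_upstream`` = a + strand motif midpoint in
    [p - flank, p); ``minus_downstream`` = a - strand motif midpoint in
    [p, p + flank); ``flag`` = either. Columns are int8 vectors.
    """
    for m in motifs:
        if m.strand not in ("+", "-"):
            raise ValueError("all motifs must be stranded")
    plus: dict[str, list[int]] = {}
    minus: dict[str, list[int]] = {}
    for m in motifs:
        (plus if m.strand == "+" else minus).setdefault(m.chrom, []).append(
            m.interval.midpoint
        )
    plus_arr = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in plus.items()}
    minus_arr = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in minus.items()}

    n = len(origins)
    up = np.zeros(n, dtype=np.int8)
    down = np.zeros(n, dtype=np.int8)
    for i, origin in enumerate(origins):
        p = origin.anchor(origin_anchor)
        pts = plus_arr.get(origin.chrom)
        if pts is not None:
            lo = np.searchsorted(pts, p - flank, side="left")
            hi = np.searchsorted(pts, p, side="left")
            up[i] = 1 if hi > lo else 0
        pts = minus_arr.get(origin.chrom)
        if pts is not None:
            lo = np.searchsorted(pts, p, side="left")
            hi = np.searchsorted(pts, p + flank, side="left")
            down[i] = 1 if hi > lo else 0
    return pd.DataFrame(
        {
            "flag": (up | down).astype(np.int8),
            "plus_upstream": up,
            "minus_downstream": down,
        }
    )


def logistic_enrichment(
    real_flags: np.ndarray, random_flags: np.ndarray
) -> EnrichmentResult:
    """Fit class ~ intercept + flag by maximum likelihood and return the
    flag coefficient (logOR) with its Wald test."""
    real_flags = np.asarray(real_flags)
    random_flags = np.asarray(random_flags)
    if real_flags.size == 0 or random_flags.size == 0:
        raise ValueError(
            "both real and random flag vectors must be non-empty "
            "(class label needs both levels)"
        )
    a = int(np.count_nonzero(real_flags))
    b = int(real_flags.size - a)
    c = int(np.count_nonzero(random_flags))
    d = int(random_flags.size - c)

    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        logor = float(np.log(aa * dd / (bb * cc)))
        se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
        corrected = True
    else:
        # weighted binomial GLM over the four (class, flag) cells
        endog = np.array([1.0, 1.0, 0.0, 0.0])
        exog = sm.add_constant(np.array([1.0, 0.0, 1.0, 0.0]))
        weights = np.array([a, b, c, d], dtype=float)
        fit = sm.GLM(
            endog, exog, family=sm.families.Binomial(), freq_weights=weights
        ).fit()
        logor = float(fit.params[1])
        se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
        corrected = False
    wald_z = logor / se
    p = float(2 * stats.norm.sf(abs(wald_z)))
    return EnrichmentResult((a, b, c, d), logor, se, wald_z, p, corrected)


def association_table(
    real_segments: IntervalSet,
    random_segments: IntervalSet,
    feature_sets: dict[str, IntervalSet],
    extend_flank: int = 1000,
    feature_anchors: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Binary co-occurrence flags for real and matched random segments.

    One row per segment with ``class_label`` ("real" / "random") and one
    int8 column per feature class.
    """
    feature_anchors = feature_anchors or {}
    rows = {
        "class_label": ["real"] * len(real_segments)
        + ["random"] * len(random_segments)
    }
    both = IntervalSet(list(real_segments) + list(random_segments))
    for name, feats in feature_sets.items():
        rows[name] = overlap_flags(
            both,
            feats,
            extend_flank=extend_flank,
            feature_anchor=feature_anchors.get(name, "midpoint"),
        )
    return pd.DataFrame(rows)


def enrichment_from_table(
    table: pd.DataFrame,
    feature: str,
    restrict_to: str | None = None,
) -> EnrichmentResult:
    """Enrichment of one feature class from an association table.

    ``restrict_to`` filters both classes to segments flagged for another
    column first (e.g. the pG4-bearing-only conditional comparisons).
    """
    if restrict_to is not None:
        table = table[table[restrict_to] == 1]
    real = table.loc[table["class_label"] == "real", feature].to_numpy()
    random_ = table.loc[table["class_label"] == "random", feature].to_numpy()
    return logistic_enrichment(real, random_)


def enrichment_report(
    table: pd.DataFrame,
    features: list[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One row per feature class: counts, logOR, se, Wald z, p (raw by
    default; optional Benjamini-Hochberg adjusted column)."""
    if features is None:
        features = [c for c in table.columns if c != "class_label"]
    rows = []
    for feat in features:
        r = enrichment_from_table(table, feat)
        rows.append(
            {
                "feature": feat,
                "a": r.counts[0], "b": r.counts[1],
                "c": r.counts[2], "d": r.counts[3],
                "logor": r.logor, "se": r.se,
                "wald_z": r.wald_z, "p_value": r.p_value,
                "continuity_corrected": r.continuity_corrected,
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
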