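"""Size- and GC-matched random genomic backgrounds.

Every enrichment test compares a real feature set against random segments
drawn from the same genome, matched per feature on exact length and on
GC-content bin (2% bins by default). The design is paired: each random
segment inherits one feature's length and GC bin, so the random set
reproduces the feature length multiset exactly and the per-bin GC counts
exactly, up to features whose bin cannot be matched (reported and excluded
together with their feature).

Randomness is reproducible: one root seed, with an independent deterministic
stream per feature index, so adding features never perturbs earlier draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeSequence, GenomicInterval, IntervalSet, merge_intervals

_BATCH = 64


@dataclass
class MatchedSamplerConfig:
    samples_per_feature: int = 1
    gc_bin_width: float = 0.02
    max_attempts_per_feature: int = 2000
    seed: int = 0
    exclude: IntervalSet | None = None

    def __post_init__(self) -> None:
        if not (0 < self.gc_bin_width <= 1):
            raise ValueError("gc_bin_width must be in (0, 1]")
        if self.max_attempts_per_feature < 1:
            raise ValueError("max_attempts_per_feature must be >= 1")
        if self.samples_per_feature < 1:
            raise ValueError("samples_per_feature must be >= 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples_per_feature": self.samples_per_feature,
            "gc_bin_width": self.gc_bin_width,
            "max_attempts_per_feature": self.max_attempts_per_feature,
            "seed": self.seed,
            "n_exclude": 0 if self.exclude is None else len(self.exclude),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class RandomSegmentSet:
    """Matched random segments plus their pairing provenance."""

    intervals: IntervalSet
    provenance: pd.DataFrame  # columns: segment_name, feature_index, gc_bin
    unmatched: list[int] = field(default_factory=list)

    @property
    def matched_feature_indices(self) -> np.ndarray:
        return self.provenance["feature_index"].to_numpy()


def gc_bin(gc: float, width: float) -> int:
    """Bin index of a GC fraction; -1 flags undefined GC (all-N interval)."""
    if math.isnan(gc):
        return -1
    return min(int(gc / width), int(round(1 / width)) - 1)


class _ExcludeIndex:
    """O(log n) overlap queries against a merged exclude set."""

    def __init__(self, exclude: IntervalSet | None):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if exclude is None or len(exclude) == 0:
            return
        merged = merge_intervals(exclude, max_gap=0)
        for chrom, ivs in merged.by_chrom().items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self.by_chrom[chrom] = (starts, ends)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends[i - 1] > start


def sample_matched_random(
    features: IntervalSet,
    genome: GenomeSequence,
    config: MatchedSamplerConfig,
) -> RandomSegmentSet:
    """Draw ``samples_per_feature`` random segments per feature, matched on
    exact length and GC bin, uniformly positioned over the genome (rejection
    sampling), outside the optional exclude set."""
    if len(features) == 0:
        raise ValueError("feature set is empty")
    chroms = genome.chrom_names
    lengths = genome.lengths
    max_feature = max(len(iv) for iv in features)
    if max(lengths.values()) < max_feature:
        raise ValueError("genome shorter than the longest feature")
    exclude_idx = _ExcludeIndex(config.exclude)

    segments: list[GenomicInterval] = []
    prov_rows: list[tuple[str, int, int]] = []
    unmatched: list[int] = []

    for i, feat in enumerate(features):
        L = len(feat)
        target_bin = gc_bin(genome.gc_content(feat.chrom, feat.start, feat.end),
                            config.gc_bin_width)
        if target_bin < 0:
            unmatched.append(i)
            continue
        # valid start positions per chromosome, cumulated for a single
        # uniform draw over the whole genome
        n_starts = np.array(
            [max(0, lengths[c] - L + 1) for c in chroms], dtype=np.int64
        )
        cum = np.concatenate(([0], np.cumsum(n_starts)))
        total = int(cum[-1])
        rng = np.random.default_rng([config.seed, i])
        found: list[GenomicInterval] = []
        attempts = 0
        while len(found) < config.samples_per_feature and attempts < (
            config.max_attempts_per_feature * config.samples_per_feature
        ):
            draws = rng.integers(0, total, size=_BATCH)
            attempts += _BATCH
            for u in draws:
                ci = int(np.searchsorted(cum, u, side="right")) - 1
                chrom = chroms[ci]
                start = int(u - cum[ci])
                end = start + L
                if exclude_idx.overlaps(chrom, start, end):
                    continue
                if gc_bin(genome.gc_content(chrom, start, end),
                          config.gc_bin_width) != target_bin:
                    continue
                found.append(
                    GenomicInterval(chrom, start, end, feat.strand,
                                    f"rnd_{i}_{len(found)}", float(target_bin))
                )
                if len(found) == config.samples_per_feature:
                    break
        if len(found) < config.samples_per_feature:
            unmatched.append(i)
            continue
        for seg in found:
            segments.append(seg)
            prov_rows.append((seg.name, i, target_bin))

    provenance = pd.DataFrame(
        prov_rows, columns=["segment_name", "feature_index", "gc_bin"]
    )
    return RandomSegmentSet(IntervalSet(segments), provenance, unmatched)


def matched_features(
    features: IntervalSet, result: RandomSegmentSet
) -> IntervalSet:
    """The features retained after matching (paired design: a feature whose
    random partner failed is dropped from downstream tests)."""
    dropped = set(result.unmatched)
    return IntervalSet(
        [iv for i, iv in enumerate(features) if i not in dropped]
    )
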