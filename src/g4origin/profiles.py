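"""Anchored meta-profiles: average feature counts in sliding windows.

Around each anchor (a pG4 first position, an NFR midpoint, ...) the signal
set is counted in sliding windows (20 bp wide, stepping 10 bp by default)
spanning +/- ``span`` bp. A signal item contributes to every window it
intersects (intersection counting, not per-bp pileup). Minus-strand anchors
can be mirrored before averaging so profiles read 5' -> 3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeSequence, IntervalSet


@dataclass
class ProfileConfig:
    span: int = 1000
    window: int = 20
    step: int = 10
    anchor_mode: str = "midpoint"  # or "first-position"
    orient_by_strand: bool = False
    drop_clipped: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be > 0")
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if self.span < self.window:
            raise ValueError("span must be >= window")
        if self.anchor_mode not in ("midpoint", "first-position"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")

    @property
    def n_offsets(self) -> int:
        return (2 * self.span - self.window) // self.step + 1

    def window_starts(self) -> np.ndarray:
        """Window start positions relative to the anchor."""
        return -self.span + self.step * np.arange(self.n_offsets, dtype=np.int64)

    def offsets(self) -> np.ndarray:
        """Window centers relative to the anchor."""
        return self.window_starts() + self.window / 2


@dataclass
class CoverageProfile:
    offsets: np.ndarray          # window centers, bp relative to anchor
    values: np.ndarray           # mean count per window across anchors
    se: np.ndarray               # standard error of the mean per offset
    n: np.ndarray                # per-offset denominator (clipping-adjusted)
    n_anchors: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.values, "se": self.se, "n": self.n}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _signal_index(signal: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, ivs in signal.by_chrom().items():
        starts = np.sort(np.array([iv.start for iv in ivs], dtype=np.int64))
        ends = np.sort(np.array([iv.end for iv in ivs], dtype=np.int64))
        out[chrom] = (starts, ends)
    return out


def coverage_profile(
    anchors: IntervalSet,
    signal: IntervalSet,
    config: ProfileConfig | None = None,
    genome: GenomeSequence | None = None,
) -> CoverageProfile:
    """Average signal-interval counts in sliding windows around anchors.

    For a minus-strand anchor with ``orient_by_strand`` the window layout is
    reflected around the anchor point, so mirroring every anchor's strand
    reverses the profile exactly. Windows falling entirely outside the
    chromosome (requires ``genome``) are removed from that offset's
    denominator; with ``drop_clipped`` the whole anchor is dropped instead.
    """
    config = config or ProfileConfig()
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    idx = _signal_index(signal)
    n_off = config.n_offsets
    rel_starts = config.window_starts()
    w = config.window
    anchor_mode = "start" if config.anchor_mode == "first-position" else "midpoint"

    sums = np.zeros(n_off)
    sq_sums = np.zeros(n_off)
    denom = np.zeros(n_off, dtype=np.int64)
    used = 0
    for anchor in anchors:
        p = anchor.anchor(anchor_mode)
        mirrored = config.orient_by_strand and anchor.strand == "-"
        if mirrored:
            # reflected layout: offset j covers [p + span - j*step - w, ...)
            ws = p + config.span - config.step * np.arange(n_off, dtype=np.int64) - w
        else:
            ws = p + rel_starts
        we = ws + w
        if genome is not None:
            L = genome.lengths[anchor.chrom]
            in_bounds = (we > 0) & (ws < L)
            if config.drop_clipped and not in_bounds.all():
                continue
        else:
            in_bounds = np.ones(n_off, dtype=bool)
        counts = np.zeros(n_off)
        if anchor.chrom in idx:
            starts, ends = idx[anchor.chrom]
            # interval intersects [ws, we) iff start < we and end > ws
            counts = (
                np.searchsorted(starts, we, side="left")
                - np.searchsorted(ends, ws, side="right")
            ).astype(float)
        counts[~in_bounds] = 0.0
        sums += counts
        sq_sums += counts**2
        denom += in_bounds
        used += 1
    if used == 0:
        raise ValueError("no anchors left after clipping")
    safe = np.maximum(denom, 1)
    means = sums / safe
    var = np.maximum(sq_sums / safe - means**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(denom > 1, np.sqrt(var / np.maximum(denom - 1, 1)), np.nan)
    means = np.where(denom > 0, means, np.nan)
    return CoverageProfile(config.offsets(), means, se, denom, used)
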