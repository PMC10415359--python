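"""Genomic interval and sequence primitives.

All coordinates are 0-based half-open (BED convention). Intervals carry a
strand in {"+", "-", "."}; sorting order is (chrom, start, end, strand),
which makes every downstream output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-", ".")
_ALPHABET = set("ACGTN")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed."""


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : chromosome name.
    start, end : 0-based half-open coordinates, ``0 <= start < end``.
    strand : one of ``+``, ``-``, ``.``.
    name : free-text label (BED column 4).
    score : numeric score (BED column 5).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor((start+end)/2)."""
        return (self.start + self.end) // 2

    def anchor(self, mode: str = "midpoint") -> int:
        """Reference point used for extension and profiling.

        ``midpoint`` is the default; ``start`` anchors on the 5' reference
        position (used for motif-first-position profiles).
        """
        if mode == "midpoint":
            return self.midpoint
        if mode == "start":
            return self.start
        raise ValueError(f"unknown anchor mode {mode!r}")

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


class GenomeSequence:
    """An in-memory genome: ordered chromosomes of {A,C,G,T,N} sequence.

    GC content queries are O(1) via cached cumulative base counts.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            extra = set(seq) - _ALPHABET
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {extra}"
                )
            self.sequences[name] = seq
        self._cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._check_bounds(chrom, start, end)
        return self.sequences[chrom][start:end]

    def _check_bounds(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.sequences[chrom]) or start >= end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"[0, {len(self.sequences[chrom])})"
            )

    def _cumulative(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        # cumulative (#G+#C, #N) with a leading 0 for O(1) range queries
        if chrom not in self._cum:
            arr = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)
            gc = (arr == ord("G")) | (arr == ord("C"))
            nn = arr == ord("N")
            self._cum[chrom] = (
                np.concatenate(([0], np.cumsum(gc, dtype=np.int64))),
                np.concatenate(([0], np.cumsum(nn, dtype=np.int64))),
            )
        return self._cum[chrom]

    def gc_content(self, chrom: str, start: int, end: int) -> float:
        """GC fraction over [start, end); N bases are excluded from the
        denominator. Returns NaN when the interval is all N."""
        self._check_bounds(chrom, start, end)
        gc_cum, n_cum = self._cumulative(chrom)
        n_n = int(n_cum[end] - n_cum[start])
        denom = (end - start) - n_n
        if denom == 0:
            return float("nan")
        return float(gc_cum[end] - gc_cum[start]) / denom

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        sequences = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate chromosome {rec.id!r} in {path}")
            sequences[rec.id] = str(rec.seq).upper()
        return cls(sequences)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Most operations expect (and guarantee) sorted order by
    (chrom, start, end, strand).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), sorted: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self._sorted = sorted

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def is_sorted(self) -> bool:
        return self._sorted or all(
            a.sort_key() <= b.sort_key()
            for a, b in zip(self.intervals, self.intervals[1:])
        )

    def sorted_copy(self) -> "IntervalSet":
        return IntervalSet(
            builtins_sorted(self.intervals, key=GenomicInterval.sort_key), sorted=True
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def anchors(self, mode: str = "midpoint") -> dict[str, np.ndarray]:
        """Per-chromosome sorted arrays of anchor points."""
        out: dict[str, np.ndarray] = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = np.sort(np.array([iv.anchor(mode) for iv in ivs], dtype=np.int64))
        return out

    def validate_against(self, genome: GenomeSequence) -> None:
        for iv in self.intervals:
            genome._check_bounds(iv.chrom, iv.start, iv.end)


builtins_sorted = sorted


def read_bed(path: str | Path, genome: GenomeSequence | None = None) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`.

    Strand defaults to "." when column 6 is absent. When a genome is given,
    every record is validated against its chromosome bounds.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand, name, score)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    iset = IntervalSet(intervals)
    if genome is not None:
        iset.validate_against(genome)
    return iset


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED6, tab-separated, no header."""
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def write_bedgraph(
    records: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    """Write a bedGraph track: (chrom, start, end, value) per line."""
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def merge_intervals(
    iset: IntervalSet, max_gap: int = 0, stranded: bool = False
) -> IntervalSet:
    """Merge intervals whose gap (next.start - prev.end) is <= ``max_gap``.

    Mirrors bedtools ``merge -d``: a gap equal to ``max_gap`` still merges.
    With ``stranded``, merging happens within each strand class separately.
    The member count of each merged run is stored in the score field.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if len(iset) == 0:
        return IntervalSet(sorted=True)

    def group_key(iv: GenomicInterval):
        return (iv.chrom, iv.strand) if stranded else (iv.chrom,)

    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in iset:
        groups.setdefault(group_key(iv), []).append(iv)

    merged: list[GenomicInterval] = []
    for key, ivs in groups.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end, count = ivs[0].start, ivs[0].end, 1
        strand = ivs[0].strand if stranded else "."
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
                count += 1
            else:
                merged.append(
                    GenomicInterval(key[0], cur_start, cur_end, strand, "merged", count)
                )
                cur_start, cur_end, count = iv.start, iv.end, 1
        merged.append(
            GenomicInterval(key[0], cur_start, cur_end, strand, "merged", count)
        )
    merged.sort(key=GenomicInterval.sort_key)
    return IntervalSet(merged, sorted=True)


def extend_around_point(
    interval: GenomicInterval,
    flank: int,
    genome: GenomeSequence,
    anchor_mode: str = "midpoint",
) -> GenomicInterval:
    """Return the window [p - flank, p + flank) around the interval's anchor
    point p, clipped to chromosome bounds. Strand and name are preserved."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    p = interval.anchor(anchor_mode)
    length = genome.lengths[interval.chrom]
    start = max(0, p - flank)
    end = min(length, p + flank)
    return replace(interval, start=start, end=end)


def gc_fraction(genome: GenomeSequence, interval: GenomicInterval) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over the interval; NaN when the
    interval is entirely N."""
    return genome.gc_content(interval.chrom, interval.start, interval.end)
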