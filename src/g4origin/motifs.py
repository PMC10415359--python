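"""Detection and clustering of putative G-quadruplex (pG4) motifs.

A pG4 is four or more runs of guanines ("G-tracts", >= ``tract_len`` each)
separated by short loops (1-7 bp by default): the classical quadparser rule
``G{3,}(N{1,7}G{3,}){3}``. The minus strand is scanned as the reverse
complement, so C-rich motifs on the reference ("pC4s") are reported as
minus-strand pG4s at reference coordinates.

Clustering chains same-strand motifs whose consecutive gaps are at most
``max_gap`` (100 bp by default, the length of DNA wrapped around one
nucleosome). Runs of 2-6 motifs are "clustered" pG4s — the dimeric cis-signal
associated with replication origin activity — runs of 1 are monomers, and
longer runs are reported separately as oversize.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import GenomeSequence, GenomicInterval, IntervalSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PG4Motif:
    """One detected pG4 motif.

    ``n_tracts`` and ``loop_lengths`` describe the motif in its G-rich
    orientation (the reverse complement for minus-strand motifs).
    """

    interval: GenomicInterval
    n_tracts: int
    tract_len: int
    loop_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("pG4 motif must be stranded (+ or -)")
        if self.n_tracts < 2:
            raise ValueError("pG4 motif needs at least 2 G-tracts")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class PG4Cluster:
    """A maximal same-strand run of motifs chained at gaps <= max_gap."""

    members: tuple[PG4Motif, ...]
    span: GenomicInterval

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass
class PG4ClusterSet:
    """Partition of detected motifs into monomers, clusters and oversize runs.

    Every motif appears in exactly one category. ``oversize`` holds runs
    longer than ``max_k`` (excluded from both named categories, reported so
    they can be reassigned by configuration).
    """

    clusters: list[PG4Cluster] = field(default_factory=list)
    monomers: list[PG4Motif] = field(default_factory=list)
    oversize: list[PG4Cluster] = field(default_factory=list)

    @property
    def n_motifs(self) -> int:
        return (
            len(self.monomers)
            + sum(c.k for c in self.clusters)
            + sum(c.k for c in self.oversize)
        )

    def category_fractions(self) -> dict[str, float]:
        """Fraction of motifs in each category (by motif count)."""
        n = self.n_motifs
        if n == 0:
            return {"monomeric": 0.0, "clustered": 0.0, "oversize": 0.0}
        return {
            "monomeric": len(self.monomers) / n,
            "clustered": sum(c.k for c in self.clusters) / n,
            "oversize": sum(c.k for c in self.oversize) / n,
        }

    def monomer_intervals(self) -> IntervalSet:
        return IntervalSet(
            sorted((m.interval for m in self.monomers), key=GenomicInterval.sort_key),
            sorted=True,
        )

    def cluster_spans(self) -> IntervalSet:
        return IntervalSet(
            sorted((c.span for c in self.clusters), key=GenomicInterval.sort_key),
            sorted=True,
        )

    def oversize_spans(self) -> IntervalSet:
        return IntervalSet(
            sorted((c.span for c in self.oversize), key=GenomicInterval.sort_key),
            sorted=True,
        )


def _pg4_regex(tract_len: int, loop_min: int, loop_max: int, n_tracts: int) -> re.Pattern:
    return re.compile(
        f"G{{{tract_len},}}"
        f"(?:[ACGT]{{{loop_min},{loop_max}}}G{{{tract_len},}}){{{n_tracts - 1}}}"
    )


def _annotate(seq: str, tract_len: int) -> tuple[int, tuple[int, ...]]:
    """Count G-tracts (>= tract_len) and the gaps between them in a match."""
    tracts = [m.span() for m in re.finditer(f"G{{{tract_len},}}", seq)]
    loops = tuple(b[0] - a[1] for a, b in zip(tracts, tracts[1:]))
    return len(tracts), loops


def detect_pg4(
    genome: GenomeSequence,
    tract_len: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    n_tracts: int = 4,
) -> list[PG4Motif]:
    """Scan both strands of a genome for pG4 motifs.

    Matching is leftmost-greedy and non-overlapping within a strand; the two
    strands are scanned independently (overlapping +/- motifs are both kept).
    Minus-strand motifs come from scanning the reverse complement and are
    reported at reference coordinates.
    """
    if tract_len < 2:
        raise ValueError("tract_len must be >= 2")
    if loop_min < 1 or loop_max < loop_min:
        raise ValueError("require 1 <= loop_min <= loop_max")
    if n_tracts < 2:
        raise ValueError("n_tracts must be >= 2")
    pattern = _pg4_regex(tract_len, loop_min, loop_max, n_tracts)
    motifs: list[PG4Motif] = []
    for chrom, seq in genome.sequences.items():
        for m in pattern.finditer(seq):
            n, loops = _annotate(m.group(), tract_len)
            motifs.append(
                PG4Motif(
                    GenomicInterval(chrom, m.start(), m.end(), "+", "pG4"),
                    n, tract_len, loops,
                )
            )
        rc = reverse_complement(seq)
        L = len(seq)
        for m in pattern.finditer(rc):
            n, loops = _annotate(m.group(), tract_len)
            motifs.append(
                PG4Motif(
                    GenomicInterval(chrom, L - m.end(), L - m.start(), "-", "pG4"),
                    n, tract_len, loops,
                )
            )
    motifs.sort(key=lambda mo: mo.interval.sort_key())
    return motifs


def cluster_pg4(
    motifs: list[PG4Motif],
    max_gap: int = 100,
    min_k: int = 2,
    max_k: int = 6,
    strict_gap: bool = False,
) -> PG4ClusterSet:
    """Chain same-strand motifs into clusters.

    Consecutive same-strand motifs are chained transitively whenever the gap
    (next.start - prev.end) is <= ``max_gap`` (or strictly < with
    ``strict_gap``). Runs of size 1 are monomers, sizes in [min_k, max_k] are
    clusters, larger runs are oversize.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not (1 <= min_k <= max_k):
        raise ValueError("require 1 <= min_k <= max_k")
    result = PG4ClusterSet()
    groups: dict[tuple[str, str], list[PG4Motif]] = {}
    for mo in motifs:
        groups.setdefault((mo.chrom, mo.strand), []).append(mo)

    def close_run(run: list[PG4Motif]) -> None:
        # runs below min_k (size 1 under the defaults) count as monomers
        if len(run) < min_k:
            result.monomers.extend(run)
            return
        span = GenomicInterval(
            run[0].chrom,
            min(m.start for m in run),
            max(m.end for m in run),
            run[0].strand,
            "pG4_cluster",
            len(run),
        )
        cluster = PG4Cluster(tuple(run), span)
        if min_k <= len(run) <= max_k:
            result.clusters.append(cluster)
        else:
            result.oversize.append(cluster)

    for (chrom, strand), ivs in groups.items():
        ivs.sort(key=lambda m: (m.start, m.end))
        run = [ivs[0]]
        run_end = ivs[0].end
        for mo in ivs[1:]:
            gap = mo.start - run_end
            chained = gap < max_gap if strict_gap else gap <= max_gap
            if chained:
                run.append(mo)
                run_end = max(run_end, mo.end)
            else:
                close_run(run)
                run = [mo]
                run_end = mo.end
        close_run(run)

    result.monomers.sort(key=lambda m: m.interval.sort_key())
    result.clusters.sort(key=lambda c: c.span.sort_key())
    result.oversize.sort(key=lambda c: c.span.sort_key())
    return result


def motifs_by_strand(motifs: list[PG4Motif], strand: str) -> list[PG4Motif]:
    return [m for m in motifs if m.strand == strand]


def motif_intervals(motifs: list[PG4Motif]) -> IntervalSet:
    return IntervalSet(
        sorted((m.interval for m in motifs), key=GenomicInterval.sort_key),
        sorted=True,
    )
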