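"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is deliberately naive (quadratic scans, graph closure, closed
forms) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from g4origin.core import GenomicInterval


def brute_merge(intervals, max_gap: int, stranded: bool):
    """Transitive-closure merging: union any two intervals in the same
    group whose gap is <= max_gap, via graph connected components."""
    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for i, a in enumerate(intervals):
        for j, b in enumerate(intervals):
            if j <= i:
                continue
            if a.chrom != b.chrom:
                continue
            if stranded and a.strand != b.strand:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_gap:
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = [intervals[i] for i in comp]
        out.append(
            (
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
                members[0].strand if stranded else ".",
                len(members),
            )
        )
    return sorted(out)


def brute_cluster_partition(motifs, max_gap: int):
    """Connected components of the same-strand gap graph; returns a sorted
    list of frozensets of motif indices."""
    g = nx.Graph()
    g.add_nodes_from(range(len(motifs)))
    for i, a in enumerate(motifs):
        for j, b in enumerate(motifs):
            if j <= i:
                continue
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_gap:
                g.add_edge(i, j)
    return sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=sorted
    )


def closed_form_logor(a: int, b: int, c: int, d: int):
    """ln(ad/bc) and its standard error from the 2x2 table."""
    logor = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return logor, se


def brute_overlap_flags(segments, features, flank: int, genome):
    """All-pairs intersection of the extended (clipped) windows."""
    flags = np.zeros(len(segments), dtype=np.int8)
    ext_feats = []
    for f in features:
        p = f.midpoint
        L = genome.lengths[f.chrom]
        ext_feats.append((f.chrom, max(0, p - flank), min(L, p + flank)))
    for i, s in enumerate(segments):
        p = s.midpoint
        L = genome.lengths[s.chrom]
        a, b = max(0, p - flank), min(L, p + flank)
        for chrom, fa, fb in ext_feats:
            if chrom == s.chrom and a < fb and b > fa:
                flags[i] = 1
                break
    return flags


def brute_window_counts(reads, windows):
    """Per-window midpoint containment by full scan."""
    mids = [(r.chrom, r.midpoint) for r in reads]
    out = np.zeros(len(windows), dtype=np.int64)
    for k, (_, row) in enumerate(windows.iterrows()):
        out[k] = sum(
            1
            for chrom, m in mids
            if chrom == row["chrom"] and row["start"] <= m < row["end"]
        )
    return out


def brute_origin_strength(origins, reads):
    out = np.zeros(len(origins))
    for i, o in enumerate(origins):
        n = sum(
            1
            for r in reads
            if r.chrom == o.chrom and o.start <= r.midpoint < o.end
        )
        out[i] = n / (o.end - o.start)
    return out


def sort_slice_strong(origins, strengths, quantile: float):
    """Sort-and-slice selection respecting the tie rule."""
    thr = np.quantile(np.asarray(strengths, dtype=float), quantile)
    return sorted(
        (o.chrom, o.start, o.end)
        for o, s in zip(origins, strengths)
        if s >= thr
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=200,
                     stranded=False):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        strand = rng.choice(["+", "-"]) if stranded else "."
        out.append(
            GenomicInterval(
                str(rng.choice(list(chroms))), start, start + length, strand
            )
        )
    return out
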