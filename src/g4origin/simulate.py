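"""Synthetic genomes with planted pG4s, origins, chromatin marks and
Repli-seq counts — a fully ground-truthed test surface for the pipeline.

The generator emulates the statistical structure the analysis assumes:

* a multi-chromosome background genome with configurable GC (optionally a
  gradient) and GC-elevated CpG-island blocks;
* canonical pG4 motifs planted at Poisson densities per strand, either as
  monomers or as same-strand clusters of 2-6 motifs with gaps of 8-100 bp;
* replication origins whose placement depends on pG4 clustering with a
  configurable (or target-logOR-derived) conditional probability, with true
  strengths following an additive reads/bp model;
* NFRs placed 5' of origin-associated clusters (the asymmetric nucleosome
  pattern), H2A.Z peaks near pG4s independent of origin status;
* SNS reads (Poisson per origin plus uniform background) and window-level
  S1-S4 fraction counts over an early/late timing landscape with an
  optional planted local advance of replication timing.

Planted units keep a separation buffer (4 kb by default) so that origin
placement categories translate into exact feature flags: the implied
log-odds ratios are computed analytically from the placement probabilities
and the flagged fraction of the genome, not tuned empirically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeSequence, GenomicInterval, IntervalSet
from .motifs import PG4Motif, reverse_complement
from .timing import FRACTIONS, FractionCounts, make_windows

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


# ----------------------------------------------------------------- config --

@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the reference synthetic
    study conditions (5 chromosomes x 2 Mb)."""

    # genome
    n_chroms: int = 5
    chrom_length: int = 2_000_000
    base_gc: float = 0.42
    gc_gradient: float = 0.0      # total GC change start -> end of a chrom
    # CpG islands (GC-elevated blocks)
    n_cgis_per_chrom: int = 5
    cgi_length: int = 2_000
    cgi_gc: float = 0.65
    # planted motifs
    monomer_rate: float = 30.0    # monomeric pG4s per Mb, both strands
    cluster_rate: float = 8.0     # clusters per Mb
    cluster_size_probs: dict = field(
        default_factory=lambda: {2: 0.50, 3: 0.20, 4: 0.15, 5: 0.10, 6: 0.05}
    )
    gap_min: int = 8              # > loop_max so members stay distinct motifs
    gap_max: int = 100
    tract_len: int = 3
    loop_min: int = 1
    loop_max: int = 7
    unit_buffer: int = 4_000      # min distance between planted units
    edge_margin: int = 2_500
    # origins
    n_origins: int = 600
    origin_length: int = 300
    p_origin_near_clustered: float = 0.20
    p_origin_near_monomeric: float = 0.15
    target_logor_clustered: float | None = None   # overrides p_... if set
    target_logor_monomeric: float | None = None
    assoc_flank: int = 1_000
    placement_jitter: int = 1_500
    # origin strength model (reads/bp)
    baseline_strength: float = 0.05
    beta_cluster: float = 0.05
    beta_monomer: float = 0.01
    beta_cgi: float = 0.02
    # SNS reads
    sns_background_per_bp: float = 0.005
    read_length: int = 150
    # chromatin marks
    p_nfr: float = 0.8
    nfr_length: int = 300
    nfr_gap: int = 50
    nfr_background_per_mb: float = 5.0
    p_h2az: float = 0.5
    h2az_length: int = 200
    h2az_jitter: int = 500
    h2az_background_per_mb: float = 10.0
    # Repli-seq
    domain_length: int = 500_000
    repliseq_window: int = 50_000
    repliseq_step: int = 10_000
    repliseq_reads_per_window: float = 300.0
    rt_advance_points: float = 20.0
    advance_halfwidth: int = 25_000
    advance_center: int | None = None   # default: late-domain trough, chrom 1
    early_profile: tuple = (0.55, 0.25, 0.12, 0.08)
    late_profile: tuple = (0.08, 0.12, 0.25, 0.55)

    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.base_gc, self.cgi_gc, self.p_origin_near_clustered,
            self.p_origin_near_monomeric, self.p_nfr, self.p_h2az,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.monomer_rate < 0 or self.cluster_rate < 0:
            raise ValueError("rates must be >= 0")
        total = sum(self.cluster_size_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cluster_size_probs must sum to 1")
        if not all(2 <= k <= 6 for k in self.cluster_size_probs):
            raise ValueError("cluster sizes must lie in [2, 6]")
        if self.p_origin_near_clustered + self.p_origin_near_monomeric > 1:
            raise ValueError("placement probabilities sum above 1")
        if self.gap_min <= self.loop_max:
            raise ValueError(
                "gap_min must exceed loop_max, otherwise adjacent planted "
                "motifs merge into a single detected motif"
            )
        if abs(sum(self.early_profile) - 1) > 1e-9 or abs(
            sum(self.late_profile) - 1
        ) > 1e-9:
            raise ValueError("fraction profiles must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cluster_size_probs" in d:
            d["cluster_size_probs"] = {
                int(k): v for k, v in d["cluster_size_probs"].items()
            }
        for key in ("early_profile", "late_profile"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def p_origin_for_logor(target_logor: float, p_background: float) -> float:
    """Conditional placement probability realizing a target logOR against a
    background flag probability: logit(p) = logit(p0) + logOR."""
    if not (0 < p_background < 1):
        raise ValueError("background probability must lie in (0, 1)")
    odds = p_background / (1 - p_background) * math.exp(target_logor)
    return odds / (1 + odds)


# ------------------------------------------------------------ ground truth --

@dataclass
class GroundTruth:
    """Everything that was planted, for recovery testing."""

    motifs: list[PG4Motif] = field(default_factory=list)
    motif_cluster_id: list = field(default_factory=list)  # None = monomer
    cluster_spans: IntervalSet = field(default_factory=IntervalSet)
    monomer_intervals: IntervalSet = field(default_factory=IntervalSet)
    cgis: IntervalSet = field(default_factory=IntervalSet)
    origins: IntervalSet = field(default_factory=IntervalSet)
    origin_category: list = field(default_factory=list)
    origin_n_clustered: np.ndarray | None = None
    origin_n_monomeric: np.ndarray | None = None
    true_strengths: np.ndarray | None = None
    nfrs: IntervalSet = field(default_factory=IntervalSet)
    h2az: IntervalSet = field(default_factory=IntervalSet)
    p_background_clustered: float | None = None
    p_background_monomeric: float | None = None
    true_logor_clustered: float | None = None
    true_logor_monomeric: float | None = None
    rt_advance_points: float | None = None
    advance_locus: tuple | None = None  # (chrom, center)

    def to_json(self, path: str | Path) -> None:
        def iv(i: GenomicInterval):
            return [i.chrom, i.start, i.end, i.strand, i.score]

        payload = {
            "motifs": [iv(m.interval) for m in self.motifs],
            "motif_cluster_id": self.motif_cluster_id,
            "cluster_spans": [iv(i) for i in self.cluster_spans],
            "monomers": [iv(i) for i in self.monomer_intervals],
            "cgis": [iv(i) for i in self.cgis],
            "origins": [iv(i) for i in self.origins],
            "origin_category": self.origin_category,
            "true_strengths": None
            if self.true_strengths is None
            else list(map(float, self.true_strengths)),
            "nfrs": [iv(i) for i in self.nfrs],
            "h2az": [iv(i) for i in self.h2az],
            "p_background_clustered": self.p_background_clustered,
            "p_background_monomeric": self.p_background_monomeric,
            "true_logor_clustered": self.true_logor_clustered,
            "true_logor_monomeric": self.true_logor_monomeric,
            "rt_advance_points": self.rt_advance_points,
            "advance_locus": self.advance_locus,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


# ------------------------------------------------------- genome and motifs --

def _background_bases(rng, length: int, gc_start: float, gc_end: float) -> np.ndarray:
    """Per-base draw with GC interpolated linearly along the chromosome."""
    u = rng.random(length)
    gc = np.linspace(gc_start, gc_end, num=length)
    at = 1.0 - gc
    # order A, T, G, C with cumulative thresholds
    codes = np.full(length, 3, dtype=np.uint8)  # C
    codes[u < at / 2] = 0                        # A
    codes[(u >= at / 2) & (u < at)] = 1          # T
    codes[(u >= at) & (u < at + gc / 2)] = 2     # G
    return _BASES[codes]


def _constrained_bases(rng, n: int, gc: float, run_limit: int) -> str:
    """Background-composition filler for loops and spacers.

    Constraints keep the planted structure exact under the detector: no G or
    C run reaches ``run_limit`` (no spurious tracts on either strand), and
    the first/last base is never G (no tract extension across boundaries,
    so loop and gap lengths are preserved)."""
    out: list[str] = []
    at = 1 - gc
    for i in range(n):
        edge = i == 0 or i == n - 1
        while True:
            u = rng.random()
            b = ("A" if u < at / 2 else "T" if u < at
                 else "G" if u < at + gc / 2 else "C")
            if edge and b == "G":
                continue
            if (
                len(out) >= run_limit - 1
                and b in "GC"
                and all(prev == b for prev in out[-(run_limit - 1):])
            ):
                continue
            out.append(b)
            break
    return "".join(out)


def _motif_sequence(rng, cfg: SimulationConfig) -> str:
    """One canonical pG4 in G-rich orientation with background-GC loops."""
    parts = []
    for t in range(4):
        parts.append("G" * cfg.tract_len)
        if t < 3:
            n = int(rng.integers(cfg.loop_min, cfg.loop_max + 1))
            parts.append(_constrained_bases(rng, n, cfg.base_gc, cfg.tract_len))
    return "".join(parts)


def _spacer(rng, n: int, cfg: SimulationConfig) -> str:
    return _constrained_bases(rng, n, cfg.base_gc, cfg.tract_len)


def simulate_genome_with_motifs(
    config: SimulationConfig,
) -> tuple[GenomeSequence, GroundTruth]:
    """Background genome + CGI blocks + planted monomeric/clustered pG4s."""
    rng = np.random.default_rng([config.seed, 1])
    truth = GroundTruth()
    sequences: dict[str, str] = {}
    sizes = sorted(config.cluster_size_probs)
    size_p = [config.cluster_size_probs[k] for k in sizes]
    cluster_counter = 0
    cgis: list[GenomicInterval] = []
    monomers: list[GenomicInterval] = []
    spans: list[GenomicInterval] = []

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        g2 = config.gc_gradient / 2
        seq = _background_bases(rng, L, config.base_gc - g2, config.base_gc + g2)

        # CGI blocks: GC-elevated background, may later host planted motifs
        placed_cgi: list[tuple[int, int]] = []
        for _ in range(config.n_cgis_per_chrom):
            for _attempt in range(200):
                s = int(rng.integers(config.edge_margin,
                                     L - config.cgi_length - config.edge_margin))
                e = s + config.cgi_length
                if all(s >= pe or e <= ps for ps, pe in placed_cgi):
                    placed_cgi.append((s, e))
                    seq[s:e] = _background_bases(rng, config.cgi_length,
                                                 config.cgi_gc, config.cgi_gc)
                    cgis.append(GenomicInterval(chrom, s, e, ".", "CGI"))
                    break

        # build planted units (sequence + member offsets) before placement
        mb = L / 1e6
        n_mono = int(rng.poisson(config.monomer_rate * mb))
        n_clust = int(rng.poisson(config.cluster_rate * mb))
        units = []  # (seq, strand, member offsets in reference orientation, is_cluster, k)
        for _ in range(n_mono):
            m = _motif_sequence(rng, config)
            strand = "+" if rng.random() < 0.5 else "-"
            u = m if strand == "+" else reverse_complement(m)
            units.append((u, strand, [(0, len(m))], False, 1))
        for _ in range(n_clust):
            k = int(rng.choice(sizes, p=size_p))
            parts, offsets, pos = [], [], 0
            for j in range(k):
                m = _motif_sequence(rng, config)
                parts.append(m)
                offsets.append((pos, pos + len(m)))
                pos += len(m)
                if j < k - 1:
                    gap = int(rng.integers(config.gap_min, config.gap_max + 1))
                    parts.append(_spacer(rng, gap, config))
                    pos += gap
            useq = "".join(parts)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                n = len(useq)
                useq = reverse_complement(useq)
                offsets = [(n - e, n - s) for s, e in offsets][::-1]
            units.append((useq, strand, offsets, True, k))

        # place units uniformly with a pairwise buffer
        placed: list[tuple[int, int]] = []
        order = rng.permutation(len(units))
        for ui in order:
            useq, strand, offsets, is_cluster, k = units[ui]
            n = len(useq)
            ok = False
            for _attempt in range(500):
                s = int(rng.integers(config.edge_margin,
                                     L - n - config.edge_margin))
                e = s + n
                if all(
                    s >= pe + config.unit_buffer or e + config.unit_buffer <= ps
                    for ps, pe in placed
                ):
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    "planting density infeasible for the genome size"
                )
            placed.append((s, e))
            arr = np.frombuffer(useq.encode("ascii"), dtype=np.uint8)
            seq[s:e] = arr
            member_ivs = [
                GenomicInterval(chrom, s + ms, s + me, strand, "pG4_planted")
                for ms, me in offsets
            ]
            if is_cluster:
                cid = cluster_counter
                cluster_counter += 1
                spans.append(
                    GenomicInterval(
                        chrom,
                        min(iv.start for iv in member_ivs),
                        max(iv.end for iv in member_ivs),
                        strand, "cluster_planted", k,
                    )
                )
            else:
                cid = None
                monomers.append(member_ivs[0])
            for iv in member_ivs:
                truth.motifs.append(
                    PG4Motif(iv, 4, config.tract_len, ())
                )
                truth.motif_cluster_id.append(cid)

        sequences[chrom] = seq.tobytes().decode("ascii")

    truth.cgis = IntervalSet(
        sorted(cgis, key=GenomicInterval.sort_key), sorted=True
    )
    truth.monomer_intervals = IntervalSet(
        sorted(monomers, key=GenomicInterval.sort_key), sorted=True
    )
    truth.cluster_spans = IntervalSet(
        sorted(spans, key=GenomicInterval.sort_key), sorted=True
    )
    return GenomeSequence(sequences), truth


# ------------------------------------------------------- origins and marks --

def _flag_space(
    anchors_by_chrom: dict[str, np.ndarray], reach: int, lengths: dict[str, int]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of half-open windows [a - reach + 1, a + reach) per chromosome:
    the set of anchor positions whose extended window would intersect an
    extended feature window (strict |p - a| < reach)."""
    out = {}
    for chrom, pts in anchors_by_chrom.items():
        if len(pts) == 0:
            continue
        starts = np.maximum(pts - reach + 1, 0)
        ends = np.minimum(pts + reach, lengths[chrom])
        m_starts, m_ends = [], []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        out[chrom] = (np.array(m_starts), np.array(m_ends))
    return out


def _space_length(space) -> int:
    return int(sum((e - s).sum() for s, e in space.values()))


def _in_space(space, chrom: str, p: int) -> bool:
    if chrom not in space:
        return False
    starts, ends = space[chrom]
    i = int(np.searchsorted(starts, p, side="right"))
    return i > 0 and p < ends[i - 1]


def simulate_origins_and_marks(
    config: SimulationConfig, genome: GenomeSequence, truth: GroundTruth
) -> dict[str, IntervalSet]:
    """Place origins relative to planted pG4 categories, derive their true
    strengths, and place NFR / H2A.Z marks.

    Origin placement: with probability p_origin_near_clustered the origin
    anchor falls within +/- placement_jitter of a random planted cluster
    (guaranteeing the clustered-pG4 flag), likewise for monomers; otherwise
    it is placed uniformly over the genome, where it may still be flagged by
    chance with the background probability p0 (the flagged fraction of the
    genome). The implied flag probability of an origin is therefore
    p1 = p_near + p_background_category * p0, and the true logOR
    logit(p1) - logit(p0) follows in closed form; target_logor_* settings
    invert that relation to derive the placement probabilities.
    """
    rng = np.random.default_rng([config.seed, 2])
    lengths = genome.lengths
    chroms = genome.chrom_names
    chrom_weights = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_weights /= chrom_weights.sum()
    reach = 2 * config.assoc_flank

    clust_anchors = truth.cluster_spans.anchors("midpoint")
    mono_anchors = truth.monomer_intervals.anchors("midpoint")
    space_c = _flag_space(clust_anchors, reach, lengths)
    space_m = _flag_space(mono_anchors, reach, lengths)
    total = genome.total_length
    p0_c = _space_length(space_c) / total
    p0_m = _space_length(space_m) / total

    # solve the placement probabilities; background origins hit a flag
    # space by chance, so p1 = p_near + (1 - p_c - p_m) * p0 per category
    p_c = config.p_origin_near_clustered
    p_m = config.p_origin_near_monomeric
    tc, tm = config.target_logor_clustered, config.target_logor_monomeric
    if tc is not None and tm is not None:
        p1c = p_origin_for_logor(tc, p0_c)
        p1m = p_origin_for_logor(tm, p0_m)
        A = np.array([[1 - p0_c, -p0_c], [-p0_m, 1 - p0_m]])
        b = np.array([p1c - p0_c, p1m - p0_m])
        p_c, p_m = (float(x) for x in np.linalg.solve(A, b))
    elif tc is not None:
        p1c = p_origin_for_logor(tc, p0_c)
        p_c = (p1c - (1 - p_m) * p0_c) / (1 - p0_c)
    elif tm is not None:
        p1m = p_origin_for_logor(tm, p0_m)
        p_m = (p1m - (1 - p_c) * p0_m) / (1 - p0_m)
    if not (0 <= p_c <= 1 and 0 <= p_m <= 1 and p_c + p_m <= 1):
        raise ValueError(
            f"infeasible placement probabilities (p_c={p_c:.4f}, p_m={p_m:.4f})"
        )

    clusters = list(truth.cluster_spans)
    monomers = list(truth.monomer_intervals)
    if p_c > 0 and not clusters:
        raise ValueError("no planted clusters to place origins near")
    if p_m > 0 and not monomers:
        raise ValueError("no planted monomers to place origins near")

    half = config.origin_length // 2
    origins: list[GenomicInterval] = []
    categories: list[str] = []
    origin_cluster_hosts: list[int | None] = []
    placed_anchors: dict[str, list[int]] = {c: [] for c in chroms}

    def too_close(chrom: str, pt: int) -> bool:
        # origins never overlap: keeps per-origin read counts separable
        return any(abs(pt - a) < config.origin_length for a in placed_anchors[chrom])

    for i in range(config.n_origins):
        u = rng.random()
        host = None
        for _attempt in range(200):
            if u < p_c:
                cat = "clustered"
                if host is None:
                    host = int(rng.integers(len(clusters)))
                anchor_pt = clusters[host].midpoint + int(
                    rng.integers(-config.placement_jitter, config.placement_jitter + 1)
                )
                chrom = clusters[host].chrom
            elif u < p_c + p_m:
                cat = "monomeric"
                if host is None:
                    host = -1 - int(rng.integers(len(monomers)))
                anchor_pt = monomers[-1 - host].midpoint + int(
                    rng.integers(-config.placement_jitter, config.placement_jitter + 1)
                )
                chrom = monomers[-1 - host].chrom
            else:
                cat = "background"
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_weights))]
                anchor_pt = int(
                    rng.integers(config.edge_margin, lengths[chrom] - config.edge_margin)
                )
            if not too_close(chrom, anchor_pt):
                break
            if _attempt % 25 == 24:
                host = None  # crowded host: pick another of the same category
        else:
            raise RuntimeError("could not place non-overlapping origins")
        placed_anchors[chrom].append(anchor_pt)
        start = max(0, anchor_pt - half)
        end = min(lengths[chrom], start + config.origin_length)
        origins.append(GenomicInterval(chrom, start, end, ".", f"origin_{i}"))
        categories.append(cat)
        origin_cluster_hosts.append(host if (host is not None and host >= 0) else None)

    # true strengths: additive model over pG4 counts in the 1-kb-extended span
    n_clust = np.zeros(config.n_origins, dtype=int)
    n_mono = np.zeros(config.n_origins, dtype=int)
    cgi_flag = np.zeros(config.n_origins, dtype=int)
    cgi_idx = {
        chrom: (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
        for chrom, ivs in truth.cgis.by_chrom().items()
    }
    for i, origin in enumerate(origins):
        s = origin.start - config.assoc_flank
        e = origin.end + config.assoc_flank
        for mids, arr in ((clust_anchors, n_clust), (mono_anchors, n_mono)):
            pts = mids.get(origin.chrom)
            if pts is not None:
                arr[i] = int(
                    np.searchsorted(pts, e, "left") - np.searchsorted(pts, s, "left")
                )
        if origin.chrom in cgi_idx:
            starts, ends = cgi_idx[origin.chrom]
            j = np.searchsorted(starts, origin.end, side="left")
            cgi_flag[i] = int(np.any(ends[:j] > origin.start))
    strengths = (
        config.baseline_strength
        + config.beta_cluster * n_clust
        + config.beta_monomer * n_mono
        + config.beta_cgi * cgi_flag
    )

    # NFR 5' of origin-associated clusters (strand-aware asymmetry)
    nfrs: list[GenomicInterval] = []
    hosts_with_origin = {h for h in origin_cluster_hosts if h is not None}
    for h in sorted(hosts_with_origin):
        if rng.random() >= config.p_nfr:
            continue
        span = clusters[h]
        if span.strand == "+":
            e = span.start - config.nfr_gap
            s = e - config.nfr_length
        else:
            s = span.end + config.nfr_gap
            e = s + config.nfr_length
        if s >= 0 and e <= lengths[span.chrom]:
            nfrs.append(GenomicInterval(span.chrom, s, e, ".", "NFR"))
    n_bg_nfr = int(rng.poisson(config.nfr_background_per_mb * total / 1e6))
    for _ in range(n_bg_nfr):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_weights))]
        s = int(rng.integers(0, lengths[chrom] - config.nfr_length))
        nfrs.append(GenomicInterval(chrom, s, s + config.nfr_length, ".", "NFR"))

    # H2A.Z near pG4 units irrespective of origin status
    h2az: list[GenomicInterval] = []
    for unit in list(truth.cluster_spans) + list(truth.monomer_intervals):
        if rng.random() >= config.p_h2az:
            continue
        c = unit.midpoint + int(
            rng.integers(-config.h2az_jitter, config.h2az_jitter + 1)
        )
        s = max(0, c - config.h2az_length // 2)
        e = min(lengths[unit.chrom], s + config.h2az_length)
        h2az.append(GenomicInterval(unit.chrom, s, e, ".", "H2AZ"))
    n_bg_h2az = int(rng.poisson(config.h2az_background_per_mb * total / 1e6))
    for _ in range(n_bg_h2az):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_weights))]
        s = int(rng.integers(0, lengths[chrom] - config.h2az_length))
        h2az.append(GenomicInterval(chrom, s, s + config.h2az_length, ".", "H2AZ"))

    truth.origins = IntervalSet(origins)
    truth.origin_category = categories
    truth.origin_n_clustered = n_clust
    truth.origin_n_monomeric = n_mono
    truth.true_strengths = strengths
    truth.nfrs = IntervalSet(sorted(nfrs, key=GenomicInterval.sort_key), sorted=True)
    truth.h2az = IntervalSet(sorted(h2az, key=GenomicInterval.sort_key), sorted=True)
    truth.p_background_clustered = p0_c
    truth.p_background_monomeric = p0_m

    def _logit(p):
        return math.log(p / (1 - p))

    p_bg = 1 - p_c - p_m
    p1_c = p_c + p_bg * p0_c
    p1_m = p_m + p_bg * p0_m
    truth.true_logor_clustered = (
        _logit(p1_c) - _logit(p0_c) if 0 < p1_c < 1 and 0 < p0_c < 1 else None
    )
    truth.true_logor_monomeric = (
        _logit(p1_m) - _logit(p0_m) if 0 < p1_m < 1 and 0 < p0_m < 1 else None
    )
    return {
        "origins": truth.origins,
        "nfr": truth.nfrs,
        "h2az": truth.h2az,
        "cgi": truth.cgis,
    }


# -------------------------------------------------------------- SNS reads --

def simulate_sns_reads(
    genome: GenomeSequence, truth: GroundTruth, config: SimulationConfig
) -> IntervalSet:
    """Poisson(strength x length) reads per origin, uniform within the
    origin, plus uniform background reads."""
    if truth.true_strengths is None:
        raise ValueError("origins with true strengths required (run "
                         "simulate_origins_and_marks first)")
    rng = np.random.default_rng([config.seed, 3])
    lengths = genome.lengths
    half = config.read_length // 2
    reads: list[GenomicInterval] = []

    def add_read(chrom: str, mid: int) -> None:
        s = max(0, mid - half)
        e = min(lengths[chrom], mid + (config.read_length - half))
        reads.append(GenomicInterval(chrom, s, e, ".", "read"))

    for origin, strength in zip(truth.origins, truth.true_strengths):
        n = int(rng.poisson(strength * len(origin)))
        if n:
            for mid in rng.integers(origin.start, origin.end, size=n):
                add_read(origin.chrom, int(mid))
    n_bg = int(rng.poisson(config.sns_background_per_bp * genome.total_length))
    chroms = genome.chrom_names
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), p=weights, size=n_bg)
    for ci in picks:
        chrom = chroms[int(ci)]
        add_read(chrom, int(rng.integers(0, lengths[chrom])))
    reads.sort(key=GenomicInterval.sort_key)
    return IntervalSet(reads, sorted=True)


# ---------------------------------------------------------------- Repli-seq --

def timing_landscape(config: SimulationConfig, midpoints: np.ndarray) -> np.ndarray:
    """Earliness tau in [0, 1] along a chromosome: sinusoidal early/late
    domains with period 2 x domain_length (tau = 1 earliest)."""
    period = 2.0 * config.domain_length
    return 0.5 * (1.0 + np.sin(2.0 * np.pi * midpoints / period))


@dataclass
class RepliseqSim:
    """Paired fraction counts with and without the planted RT advance."""

    without_advance: FractionCounts
    with_advance: FractionCounts
    locus_chrom: str
    locus_center: int
    advance_points: float


def _advance_profile(p: np.ndarray, points: float) -> np.ndarray:
    """Move ``points`` percentage points of late (S3+S4) mass to S1."""
    move = points / 100.0
    q = p.copy()
    late = q[2] + q[3]
    move = min(move, late)
    if late > 0:
        q[2] -= move * q[2] / late
        q[3] -= move * q[3] / late
    q[0] += move
    return q


def simulate_repliseq_counts(
    config: SimulationConfig, genome: GenomeSequence
) -> RepliseqSim:
    """Window-level S1-S4 and asynchronous counts over the timing
    landscape; the "with" condition applies the planted local advance."""
    rng = np.random.default_rng([config.seed, 4])
    windows = make_windows(genome, config.repliseq_window, config.repliseq_step)
    mids = ((windows["start"] + windows["end"]) // 2).to_numpy()
    widths = (windows["end"] - windows["start"]).to_numpy()
    tau = timing_landscape(config, mids)
    pE = np.array(config.early_profile)
    pL = np.array(config.late_profile)
    probs = tau[:, None] * pE[None, :] + (1 - tau)[:, None] * pL[None, :]

    chrom0 = genome.chrom_names[0]
    if config.advance_center is not None:
        center = config.advance_center
    else:
        # latest-replicating window midpoint on the first chromosome
        on0 = windows["chrom"].to_numpy() == chrom0
        center = int(mids[on0][np.argmin(tau[on0])])
    # same half-open window-midpoint rule as timing.fraction_percentages
    in_locus = (
        (windows["chrom"].to_numpy() == chrom0)
        & (mids >= center - config.advance_halfwidth)
        & (mids < center + config.advance_halfwidth)
    )
    probs_adv = probs.copy()
    for i in np.flatnonzero(in_locus):
        probs_adv[i] = _advance_profile(probs[i], config.rt_advance_points)

    lam = config.repliseq_reads_per_window * widths / config.repliseq_window

    def draw(p_matrix) -> FractionCounts:
        totals = rng.poisson(lam)
        counts = {f: np.zeros(len(windows), dtype=np.int64) for f in FRACTIONS}
        for i, (n, p) in enumerate(zip(totals, p_matrix)):
            if n:
                split = rng.multinomial(n, p)
                for j, f in enumerate(FRACTIONS):
                    counts[f][i] = split[j]
        async_counts = rng.poisson(lam)
        return FractionCounts(
            windows, counts, async_counts,
            config.repliseq_window, config.repliseq_step,
        )

    without = draw(probs)
    with_adv = draw(probs_adv)
    return RepliseqSim(without, with_adv, chrom0, center, config.rt_advance_points)


# -------------------------------------------------------------------- audit --

def audit_ground_truth(genome: GenomeSequence, truth: GroundTruth) -> None:
    """Verify mutual consistency of the genome and every truth record;
    raises AssertionError on any violation."""
    for coll in (
        [m.interval for m in truth.motifs],
        truth.cluster_spans, truth.monomer_intervals, truth.cgis,
        truth.origins, truth.nfrs, truth.h2az,
    ):
        for iv in coll:
            genome._check_bounds(iv.chrom, iv.start, iv.end)
    assert len(truth.motifs) == len(truth.motif_cluster_id)
    # planted motifs carry at least 4 G-tracts in their own orientation
    for m in truth.motifs:
        seq = genome.fetch(m.chrom, m.start, m.end)
        if m.strand == "-":
            seq = reverse_complement(seq)
        assert seq.count("G" * m.tract_len) >= 1 and seq.startswith("G")
    by_cluster: dict[int, list[PG4Motif]] = {}
    for m, cid in zip(truth.motifs, truth.motif_cluster_id):
        if cid is not None:
            by_cluster.setdefault(cid, []).append(m)
    assert len(by_cluster) == len(truth.cluster_spans)
    for members in by_cluster.values():
        strands = {m.strand for m in members}
        assert len(strands) == 1
    if truth.true_strengths is not None:
        assert len(truth.true_strengths) == len(truth.origins)
        assert np.all(truth.true_strengths >= 0)


# ------------------------------------------------------------- orchestrator --

@dataclass
class SimulationResult:
    genome: GenomeSequence
    truth: GroundTruth
    features: dict[str, IntervalSet]
    sns_reads: IntervalSet
    repliseq: RepliseqSim


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Run every generator stage with the single root seed."""
    genome, truth = simulate_genome_with_motifs(config)
    features = simulate_origins_and_marks(config, genome, truth)
    sns = simulate_sns_reads(genome, truth, config)
    repliseq = simulate_repliseq_counts(config, genome)
    return SimulationResult(genome, truth, features, sns, repliseq)
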