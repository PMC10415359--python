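import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from g4origin import GenomeSequence, SimulationConfig, simulate_all


def random_genome(seed: int, lengths: dict[str, int], gc: float = 0.5) -> GenomeSequence:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ATGC", dtype=np.uint8)
    seqs = {}
    for chrom, L in lengths.items():
        u = rng.random(L)
        at = 1 - gc
        codes = np.full(L, 3, dtype=np.uint8)
        codes[u < at / 2] = 0
        codes[(u >= at / 2) & (u < at)] = 1
        codes[(u >= at) & (u < at + gc / 2)] = 2
        seqs[chrom] = bases[codes].tobytes().decode("ascii")
    return GenomeSequence(seqs)


@pytest.fixture(scope="session")
def two_chrom_genome() -> GenomeSequence:
    return random_genome(7, {"chr1": 50_000, "chr2": 30_000}, gc=0.45)


@pytest.fixture(scope="session")
def small_sim():
    """One reusable small synthetic dataset with full ground truth."""
    cfg = SimulationConfig(
        n_chroms=2, chrom_length=500_000, n_origins=120, seed=42
    )
    return simulate_all(cfg)
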