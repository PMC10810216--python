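import numpy as np
import pytest

from cistrokit.intervals import GenomicInterval, PeakSet
from cistrokit.synthetic import SyntheticConfig, simulate_dataset
from cistrokit.tagsignal import TagLibrary


def random_peakset(rng, n, n_chrom=2, span=100_000, max_width=500):
    """Random intervals on a toy genome (may overlap, unsorted)."""
    ivs = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, span - max_width))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, start + width, name=f"iv{i}"))
    return PeakSet(ivs)


def brute_force_overlap(a, b, min_bp=1):
    """All-pairs O(n^2) overlap oracle returning the same counts/pairs."""
    pairs = []
    a_hit, b_hit = set(), set()
    for i, iva in enumerate(a):
        for j, ivb in enumerate(b):
            if iva.overlap_bp(ivb) >= min_bp:
                pairs.append((i, j))
                a_hit.add(i)
                b_hit.add(j)
    return len(a), len(b), len(a_hit), len(b_hit), sorted(pairs)


def make_library(positions_by_chrom, total_tags=None, sample_id="lib"):
    pos = {c: np.asarray(p, dtype=np.int64) for c, p in positions_by_chrom.items()}
    n = sum(a.size for a in pos.values())
    return TagLibrary(pos, total_tags if total_tags is not None else n, sample_id)


@pytest.fixture(scope="session")
def small_truth():
    """A small planted dataset shared by read-only tests."""
    cfg = SyntheticConfig(
        seed=7, n_chrom=2, chrom_length=300_000, n_sites=200, n_genes=300
    )
    return simulate_dataset(cfg)
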