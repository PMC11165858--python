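import numpy as np
import pytest

from ernaqtl.intervals import GenomicInterval, IntervalSet
from ernaqtl.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_interval_set(rng, n, chrom_len=10_000, max_width=400, chrom="chrT"):
    """Random intervals on a toy chromosome for oracle comparisons."""
    starts = rng.integers(0, chrom_len - 1, size=n)
    widths = rng.integers(1, max_width, size=n)
    return IntervalSet(
        GenomicInterval(chrom, int(s), int(min(s + w, chrom_len)))
        for s, w in zip(starts, widths)
        if min(s + w, chrom_len) > s
    )


def coverage_mask(iset, chrom_len=10_000):
    """Per-base brute-force coverage oracle."""
    mask = np.zeros(chrom_len, dtype=int)
    for iv in iset:
        mask[iv.start : iv.end] += 1
    return mask


@pytest.fixture(scope="session")
def small_dataset():
    """A compact fully-simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=7, n_samples=60, n_variants=200, n_cases=300, n_controls=300,
        n_peak_samples=3, library_size_mean=8_000, background_reads=5_000,
    )
    return simulate_dataset(cfg)
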