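import numpy as np
import pandas as pd
import pytest

from canroh.simulate import SimConfig, simulate_panel, simulate_truth_individual


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_chromosomes=2, chromosome_length=20_000_000,
                     n_sites=4_000, n_ref=40, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_panel):
    sites, _ = small_panel
    return simulate_truth_individual(sites, 0.15, small_config)


def random_segments(rng, genome_bp, n, chrom="chr1", min_len=1_000,
                    max_len=100_000):
    """Sorted non-overlapping random segments on one chromosome."""
    rows = []
    cursor = 0
    for _ in range(n):
        gap = int(rng.integers(0, max_len))
        length = int(rng.integers(min_len, max_len))
        start = cursor + gap
        end = start + length
        if end > genome_bp:
            break
        rows.append((chrom, start, end))
        cursor = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
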