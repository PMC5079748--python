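import numpy as np
import pandas as pd
import pytest

from ripcall.core import SampleKey
from ripcall.simulate import SyntheticConfig, build_truth, simulate_rip


def frame(rows):
    """Interval frame from (chrom, start, end, strand[, unique]) tuples."""
    cols = ["chrom", "start", "end", "strand", "unique"][: len(rows[0])]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11,
        chrom_sizes={"chr1": 1_500_000, "chr2": 1_000_000},
        n_genes=60,
        n_tes=30,
        n_planted_regions=40,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_truth(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_truth):
    samples = {}
    for genotype in ("wt", "polmut"):
        for rep in (1, 2):
            key = SampleKey(genotype, "RIP", rep)
            samples[str(key)] = simulate_rip(small_truth, key, small_config)
    return small_truth, samples


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=1000, max_len=80):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts,
        "end": starts + lengths,
        "strand": rng.choice(["+", "-"], size=n),
    })
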