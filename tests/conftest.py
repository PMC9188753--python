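import numpy as np
import pandas as pd
import pytest

from tilemeth.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared by module tests (seeded)."""
    cfg = SimulationConfig(
        n_chromosomes=1,
        chrom_length_bp=300_000,
        n_genes=300,
        n_coupled_genes=48,
        n_planted_dmrs_per_pattern=8,
        seed=1234,
    )
    return simulate_dataset(cfg)


def random_records(rng, n=50, chrom="chr1", max_pos=10_000):
    """Random per-CpG records table (sorted, unique positions)."""
    pos = np.sort(rng.choice(max_pos, size=n, replace=False))
    total = rng.poisson(20, n)
    meth = rng.binomial(total, rng.uniform(0, 1, n))
    return pd.DataFrame({"chrom": chrom, "pos0": pos, "meth": meth, "total": total})
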