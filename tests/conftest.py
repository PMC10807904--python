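import numpy as np
import pandas as pd
import pytest

from pseudonet import CountTable, SimulationDesign, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """10 samples x 6 taxa of Poisson-ish counts, all rows positive."""
    values = rng.integers(1, 200, size=(10, 6))
    return CountTable(pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(10)],
        columns=[f"t{j}" for j in range(6)],
    ))


@pytest.fixture
def small_meta(small_counts, rng):
    n = small_counts.n_samples
    return pd.DataFrame({
        "group": ["case"] * (n // 2) + ["control"] * (n - n // 2),
        "age": rng.normal(50, 8, size=n).round(1),
        "site": ["x", "y"] * (n // 2),
    }, index=small_counts.sample_ids)


@pytest.fixture(scope="session")
def null_study():
    """Two groups drawn from one generator: no differential connectivity."""
    design = SimulationDesign(n_per_group=12, p=10, dc_block=(), seed=7)
    return simulate(design)


@pytest.fixture(scope="session")
def planted_study():
    """Planted 3-taxon block, correlated in group A only."""
    design = SimulationDesign(n_per_group=14, p=10, dc_block=(0, 1, 2),
                              dc_correlation_a=0.7, zero_inflation=0.0,
                              seed=11)
    return simulate(design)
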