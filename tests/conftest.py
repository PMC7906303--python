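import numpy as np
import pandas as pd
import pytest

from tsauc import (
    CopSimParams,
    FeatureTable,
    GaussianDesign,
    simulate_cop_trajectory,
    simulate_gaussian_groups,
)


@pytest.fixture(scope="session")
def ou_fixture():
    """625-sample OU statokinesigram, seed 42."""
    return simulate_cop_trajectory(CopSimParams(seed=42))


@pytest.fixture(scope="session")
def separable_table():
    """A table whose first feature separates the classes perfectly."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.r_[np.ones(n // 2), -np.ones(n // 2)].astype(int)
    X = pd.DataFrame(
        rng.standard_normal((n, 4)), columns=["sep", "n1", "n2", "n3"]
    )
    X["sep"] = 3.0 * y + 0.05 * rng.standard_normal(n)
    return FeatureTable(X, y)


@pytest.fixture(scope="session")
def null_table():
    """Two identical Gaussian groups (no signal), n=80, D=6."""
    return simulate_gaussian_groups(
        GaussianDesign(n_total=80, pos_fraction=0.5, n_dims=6, delta=0.0,
                       informative_fraction=1 / 3, seed=11)
    )


@pytest.fixture(scope="session")
def shifted_table():
    """Two Gaussian groups with delta=1 on the last 2 of 6 dimensions."""
    return simulate_gaussian_groups(
        GaussianDesign(n_total=80, pos_fraction=0.5, n_dims=6, delta=1.0,
                       informative_fraction=1 / 3, seed=9)
    )
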