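import numpy as np
import pytest

from twinstab.recovery import (
    correlated_factors_truth,
    cpm_truth,
    univariate_truth,
)
from twinstab.simulate import simulate
from twinstab.data import sqrt_transform


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_univariate_groups():
    """Moderate AE univariate twin sample on the analysis (sqrt) scale."""
    data, truth = simulate(univariate_truth(seed=42, n_mz=800, n_dz=1600))
    return sqrt_transform(data).group_arrays(), truth


@pytest.fixture(scope="session")
def small_cpm_dataset():
    """Small 6-wave common-pathway cohort (raw scale) plus its truth."""
    cfg = cpm_truth(seed=7, n_mz=400, n_dz=800, missing_rate=0.1)
    data, truth = simulate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def small_bivariate_groups():
    data, truth = simulate(correlated_factors_truth(seed=3, n_mz=500, n_dz=900))
    return sqrt_transform(data).group_arrays(), truth
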