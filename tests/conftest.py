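import numpy as np
import pytest

from rsscox import GeneratorParams, SurvivalDataset, SurvivalUnitModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def default_params():
    """Calibrated operating point: beta1=0.2, beta2=0, binary risk factor."""
    return GeneratorParams()


@pytest.fixture
def unit_model(default_params):
    return SurvivalUnitModel(default_params)


@pytest.fixture
def three_record_data():
    """Hand-enumerable dataset: times 1 < 2 < 3, all events, x = (1, 0, 1).

    Risk sets are {1,2,3}, {2,3}, {3}; every partial-likelihood quantity
    has a closed form that the unit tests reproduce by hand.
    """
    return SurvivalDataset(
        time=np.array([1.0, 2.0, 3.0]),
        status=np.array([1, 1, 1]),
        covariates=np.array([[1.0], [0.0], [1.0]]),
        names=("x",),
    )


def random_survival_dataset(rng, n=30, p=2, censor_frac=0.3):
    """Small random right-censored dataset with continuous (tie-free) times."""
    X = rng.standard_normal((n, p))
    beta = rng.normal(scale=0.5, size=p)
    t = rng.exponential(1.0, n) * np.exp(-(X @ beta))
    status = (rng.random(n) > censor_frac).astype(int)
    if status.sum() == 0:
        status[rng.integers(n)] = 1
    return SurvivalDataset(
        time=t, status=status, covariates=X, names=tuple(f"v{j}" for j in range(p))
    )
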