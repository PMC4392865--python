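import numpy as np
import pytest

from refcellfree import BetaMatrix, DesignMatrix, fit_total_effect, svd_expansion


@pytest.fixture
def rng():
    return np.random.default_rng(20150226)


@pytest.fixture
def small_design(rng):
    """n=12, intercept + binary + continuous covariate."""
    n = 12
    X = np.column_stack(
        [np.ones(n), np.repeat([0.0, 1.0], n // 2), rng.normal(size=n)]
    )
    return DesignMatrix(values=X, column_names=["(Intercept)", "case", "age"])


@pytest.fixture
def small_dataset(rng, small_design):
    """Random valid 30 x 12 beta matrix paired with small_design."""
    Y = BetaMatrix(values=rng.uniform(0.05, 0.95, size=(30, 12)))
    return Y, small_design


@pytest.fixture
def small_decomposition(small_dataset):
    Y, X = small_dataset
    return svd_expansion(fit_total_effect(Y, X))
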