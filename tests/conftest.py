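import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_case_control(rng, n=80, m=4, effect=1.0, maf=0.4):
    """Small synthetic case-control problem with signal on column 0."""
    X = rng.binomial(2, maf, size=(n, m)).astype(np.float64)
    eta = -0.5 + effect * X[:, 0]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.float64)
    if y.min() == y.max():  # pragma: no cover - astronomically unlikely
        y[0] = 1.0 - y[0]
    return X, y
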