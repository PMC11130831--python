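import numpy as np
import pytest

from mixedlink.inference import category_probs
from mixedlink.model import ModelSpec, SampleTable


def simulate_table(spec: ModelSpec, theta, n: int, seed: int,
                   x_range=(2000.0, 20000.0)) -> SampleTable:
    """Individual-level SampleTable drawn from a d=1 mixed-link model."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(*x_range, size=(n, 1))
    pi = category_probs(spec, theta, X)
    labels = (rng.random(n)[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
    Y = np.zeros((n, pi.shape[1]))
    Y[np.arange(n), labels] = 1.0
    return SampleTable(X, Y, covariate_names=["tnsc"])


@pytest.fixture(scope="session")
def risk_model():
    """The cumulative po loglog/logit reference model (mitotic-age only)."""
    spec = ModelSpec("cumulative", ("loglog", "logit"), "po", d=1)
    theta = np.array([4.023, 4.905, -4.228e-4])
    return spec, theta


@pytest.fixture(scope="session")
def small_table(risk_model):
    """A modest dataset from the reference model for fitting tests."""
    spec, theta = risk_model
    return simulate_table(spec, theta, n=400, seed=11)
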