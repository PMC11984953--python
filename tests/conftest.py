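import numpy as np
import pytest

from gxetrade.estimators import StratifiedSample, center_within_context


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_sample(rng, n=60, m=40, freq_a=0.3, freq_b=0.3,
                  beta_a=0.2, beta_b=0.5, sigma_a=1.0, sigma_b=1.0):
    """Draw one polymorphic two-context sample from the generative model."""
    while True:
        ga = rng.binomial(2, freq_a, size=n)
        gb = rng.binomial(2, freq_b, size=m)
        if np.ptp(ga) > 0 and np.ptp(gb) > 0:
            break
    ya = 0.3 + beta_a * ga + rng.normal(0, sigma_a, size=n)
    yb = -0.1 + beta_b * gb + rng.normal(0, sigma_b, size=m)
    return StratifiedSample(
        np.concatenate([ga, gb]),
        np.concatenate([ya, yb]),
        np.array(["A"] * n + ["B"] * m),
    )


@pytest.fixture
def centered_sample(rng):
    return center_within_context(random_sample(rng))
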