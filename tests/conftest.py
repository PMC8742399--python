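import numpy as np
import pytest

import reslife as rl


@pytest.fixture(scope="session")
def weibull22():
    return rl.FamilySpec("weibull", (2.0, 2.0))


@pytest.fixture(scope="session")
def censored_exponential_sample():
    """Residual lifetimes from an exponential law with ~20% random censoring.

    The residual law of an exponential is the same exponential, so the
    true residual CDF is available in closed form.
    """
    rng = np.random.default_rng(1234)
    t = rng.exponential(2.0, size=400)
    c = rng.exponential(8.0, size=400)
    v = np.minimum(t, c)
    delta = (t <= c).astype(int)
    return v, delta


@pytest.fixture(scope="session")
def small_weibull_residual_data(weibull22):
    """One prevalent-cohort draw, n=125, 20% administrative censoring."""
    res = rl.sample_prevalent_residuals(weibull22, 125, seed=2024)
    v, delta = rl.apply_administrative_censoring(res, 0.2)
    return v, delta
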