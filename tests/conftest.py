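import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A small linked study shared by io/qc/crosstalk tests (read-only)."""
    from lrcrosstalk.simulate import simulate_crosstalk_study

    return simulate_crosstalk_study(
        seed=11,
        n_genes=1500,
        cell_types={"B": 60, "MYELOID": 40, "T": 30},
        n_tumor_samples=3,
        n_normal_samples=2,
        n_bulk_samples=200,
        surv_beta={"RCBM01": 0.9, "LGAU01": -0.7},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_survival_data(rng, n, beta, censor_scale=40.0, p_extra=0):
    """Exponential PH survival with standard-normal covariates (test oracle input)."""
    p = len(beta) + p_extra
    X = rng.standard_normal((n, p))
    lp = X[:, : len(beta)] @ np.asarray(beta)
    T = rng.exponential(1.0 / (0.1 * np.exp(lp)))
    C = rng.exponential(censor_scale, n)
    t = np.minimum(T, C) + np.arange(n) * 1e-9
    e = (T <= C).astype(int)
    return t, e, X
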