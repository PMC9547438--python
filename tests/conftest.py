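import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pkfactor import ScenarioConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A reproducible 130-subject study at the main power scenario."""
    return simulate_study(
        ScenarioConfig(
            gmr=0.95, cv=0.4, n_total=130, p_T=0.3, p_R=0.2,
            r_pk_ada=-0.5, r_cov_ada=0.1, seed=42,
        )
    )


def simulate_from_model(beta_b, beta_c, tau, sigma_c, n, rng):
    """Draw (arm, covariate, y_b, y_c) directly from the factorization
    model's own generative equations — the independent route used by the
    parameter-recovery and marginal-interpretation checks.

    Binary equation: y_b ~ Bernoulli(Phi(b0 + b1 * covariate)).
    Continuous equation: y_c = c0 + c1 * treat + tau * (y_b - Phi) + eps.
    """
    import pandas as pd
    from scipy import stats

    from pkfactor import StudyData

    treat = (np.arange(n) < n // 2).astype(float)
    cov = rng.standard_normal(n)
    eta = beta_b[0] + beta_b[1] * cov
    prob = stats.norm.cdf(eta)
    y_b = (rng.uniform(size=n) < prob).astype(int)
    y_c = (
        beta_c[0]
        + beta_c[1] * treat
        + tau * (y_b - prob)
        + sigma_c * rng.standard_normal(n)
    )
    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "arm": np.where(treat == 1, "T", "R"),
            "log_pk": y_c,
            "ada": y_b,
            "covariate": cov,
        }
    )
    return StudyData(frame)
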