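import numpy as np
import pandas as pd
import pytest

from locoage.synthetic import sample_event_time


def simulate_feature_cohort(n, beta_true, seed, *, M0=3e-5, Gamma=0.085,
                            beta_gender=np.log(1.5), followup=9.0):
    """Cohort with one planted standardized feature of log-HR ``beta_true``.

    Returns (cohort DataFrame with a gender covariate, feature vector).
    """
    rng = np.random.default_rng(seed)
    t1 = rng.uniform(18, 84, n)
    gender = rng.binomial(1, 0.5, n)
    xi = rng.standard_normal(n)
    lp = beta_gender * gender + beta_true * xi
    t_event = sample_event_time(t1, lp, M0, Gamma, rng)
    t_cens = t1 + followup * (1 - rng.uniform(0, 1, n))
    df = pd.DataFrame({
        "t1": t1,
        "t2": np.minimum(t_event, t_cens),
        "delta": (t_event <= t_cens).astype(int),
        "gender": gender,
    })
    return df, xi


@pytest.fixture(scope="session")
def gender_cohort():
    """Medium cohort with a gender effect only (log-HR ln 1.5)."""
    df, _ = simulate_feature_cohort(8000, 0.0, seed=42)
    return df
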