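"""Synthetic survival cohorts with age-linked locomotor activity.

The generator reproduces the statistical structure the analysis assumes: a
Gompertz baseline hazard ``M0 exp(Gamma t)`` multiplied by proportional
covariate effects ``exp(beta . x)``, delayed entry at a uniformly drawn
enrollment age, administrative censoring uniform on ``(0, followup_max]``,
independent Bernoulli risk-factor covariates, and minute-level activity
tracks whose state-transition behaviour degrades monotonically with age and
with a latent per-subject frailty that also raises the hazard.

Default parameters emulate the shape of a large accelerometer-plus-death-
register cohort study: ~8,000 adults aged 18-84, up to 9 years of follow-up,
several hundred deaths, ``M0 = 3e-5``/yr and ``Gamma = 0.085``/yr.

Event times are drawn exactly by inverting the conditional Gompertz CDF:
given survival to ``t1`` and a standard-exponential draw ``E``,

    t = (1/Gamma) * ln( exp(Gamma t1) + Gamma E / (M0 exp(beta.x)) ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .activity import ActivityTrack, MINUTES_PER_DAY, N_STATES, state_count_bounds

__all__ = [
    "ActivityParams",
    "SimConfig",
    "sample_event_time",
    "generate_cohort",
    "generate_activity_track",
    "generate_activity_tracks",
    "generate_descriptor_cohort",
]


@dataclass
class ActivityParams:
    """Links age and frailty to the activity-state dynamics.

    The minute-level state track follows a mean-reverting chain whose
    daytime target level falls linearly with age and with frailty; night
    minutes revert to a near-rest level.  Setting ``age_slope`` and
    ``frailty_slope`` to zero produces age-independent dynamics (a null
    generator with no planted signal).
    """

    day_level: float = 4.2        # daytime target state at age 18, frailty 0
    age_slope: float = 0.030      # target-state drop per year of age
    frailty_slope: float = 0.55   # target-state drop per frailty SD
    night_level: float = 0.25     # nighttime target state
    persistence: float = 0.65     # AR(1) weight on the previous state
    noise_sd: float = 1.1         # innovation SD on the state scale
    night_minutes: tuple = (0, 420)  # minutes of each day spent asleep


@dataclass
class SimConfig:
    """Full specification of a simulated cohort."""

    n_subjects: int = 8000
    M0: float = 3e-5              # baseline hazard, 1/year
    Gamma: float = 0.085          # Gompertz exponent, 1/year
    beta: dict = field(default_factory=lambda: {
        "gender": float(np.log(1.5)),
        "smoking": float(np.log(2.3)),
        "diabetes": float(np.log(1.7)),
        "hypertension": float(np.log(1.2)),
    })
    prevalence: dict = field(default_factory=lambda: {
        "gender": 0.5,
        "smoking": 0.2,
        "diabetes": 0.1,
        "hypertension": 0.3,
    })
    age_range: tuple = (18.0, 84.0)
    followup_max: float = 9.0     # administrative censoring horizon, years
    frailty_effect: float = 0.5   # log-hazard per SD of latent frailty
    seed: int = 0
    activity_params: ActivityParams = field(default_factory=ActivityParams)

    def __post_init__(self):
        if self.M0 <= 0 or self.Gamma <= 0:
            raise ValueError("M0 and Gamma must be positive")
        if self.followup_max <= 0:
            raise ValueError("followup_max must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age_range must be a non-empty interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d


def sample_event_time(t1, linear_predictor, M0: float, Gamma: float,
                      rng: np.random.Generator):
    """Draw a Gompertz event time conditional on survival to ``t1``.

    Vectorised over ``t1`` / ``linear_predictor``.  The hazard beyond
    ``t1`` is ``M0 exp(Gamma t) exp(linear_predictor)``.
    """
    if M0 <= 0 or Gamma <= 0:
        raise ValueError("M0 and Gamma must be positive")
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 < 0):
        raise ValueError("t1 must be non-negative")
    lp = np.broadcast_to(np.asarray(linear_predictor, dtype=float), t1.shape)
    E = rng.exponential(size=t1.shape)
    return (1.0 / Gamma) * np.log(
        np.exp(Gamma * t1) + Gamma * E / (M0 * np.exp(lp)))


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a survival register.

    Returns a DataFrame with columns ``subject_id, t1, t2, delta``, one 0/1
    column per configured covariate, and a latent ``frailty`` column (a
    standard-normal score that multiplies the hazard by
    ``exp(frailty_effect * frailty)`` and degrades activity; it is not
    meant to be used as an observed covariate).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range

    t1 = rng.uniform(lo, hi, size=n)
    covs = {}
    lp = np.zeros(n)
    for name, b in config.beta.items():
        p = config.prevalence.get(name, 0.5)
        covs[name] = rng.binomial(1, p, size=n)
        lp = lp + b * covs[name]
    frailty = rng.standard_normal(n)
    lp = lp + config.frailty_effect * frailty

    t_event = sample_event_time(t1, lp, config.M0, config.Gamma, rng)
    followup = config.followup_max * (1.0 - rng.uniform(0.0, 1.0, size=n))
    t_cens = t1 + followup
    delta = (t_event <= t_cens).astype(int)
    t2 = np.minimum(t_event, t_cens)

    df = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)],
                       "t1": t1, "t2": t2, "delta": delta})
    for name, v in covs.items():
        df[name] = v
    df["frailty"] = frailty
    return df


def _simulate_state_chains(ages, frailty, params: ActivityParams,
                           rng: np.random.Generator,
                           n_minutes: int = 7 * MINUTES_PER_DAY):
    """Vectorised minute-by-minute simulation of activity-state tracks."""
    ages = np.asarray(ages, dtype=float)
    frailty = np.asarray(frailty, dtype=float)
    n = ages.size
    day_target = np.clip(
        params.day_level - params.age_slope * (ages - 18.0)
        - params.frailty_slope * frailty, 0.0, N_STATES - 1)
    minute_of_day = np.arange(n_minutes) % MINUTES_PER_DAY
    lo, hi = params.night_minutes
    is_night = (minute_of_day >= lo) & (minute_of_day < hi)

    states = np.empty((n, n_minutes), dtype=np.int8)
    level = np.full(n, params.night_level)
    phi = params.persistence
    for m in range(n_minutes):
        target = np.where(is_night[m], params.night_level, day_target)
        level = phi * level + (1 - phi) * target \
            + params.noise_sd * rng.standard_normal(n)
        level = np.clip(level, 0.0, N_STATES - 1)
        states[:, m] = np.rint(level).astype(np.int8)
    return states


def _counts_from_states(states, rng: np.random.Generator):
    """Emit integer activity counts uniformly within each state's bin."""
    lows, highs = state_count_bounds()
    lo = lows[states]
    hi = highs[states]
    u = rng.random(states.shape)
    return (lo + u * (hi - lo)).astype(np.int64)


def generate_activity_tracks(ages, frailty, params: ActivityParams = None, *,
                             rng: np.random.Generator = None,
                             subject_ids=None) -> list:
    """Simulate 7-day minute-level activity tracks for many subjects.

    Expected mean daily activity is monotone decreasing in age and in
    frailty because both lower the daytime target state and counts are
    monotone in state.
    """
    params = params or ActivityParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    frailty = np.broadcast_to(np.atleast_1d(
        np.asarray(frailty, dtype=float)), ages.shape)
    if subject_ids is None:
        subject_ids = [f"S{i:06d}" for i in range(ages.size)]
    states = _simulate_state_chains(ages, frailty, params, rng)
    counts = _counts_from_states(states, rng)
    return [ActivityTrack(subject_id=sid, counts=counts[i])
            for i, sid in enumerate(subject_ids)]


def generate_activity_track(age: float, frailty_score: float,
                            rng: np.random.Generator = None,
                            params: ActivityParams = None,
                            subject_id: str = "S000000") -> ActivityTrack:
    """Single-subject convenience wrapper over the vectorised generator."""
    return generate_activity_tracks([age], [frailty_score], params, rng=rng,
                                    subject_ids=[subject_id])[0]


def generate_descriptor_cohort(n_subjects: int = 5000, *,
                               M0: float = 3e-5, Gamma: float = 0.085,
                               age_range=(18.0, 84.0),
                               followup_max: float = 9.0,
                               acceleration_sd: float = 0.5,
                               mortality_effect: float = 0.4,
                               dominant_scale: float = 3.0,
                               secondary_scale: float = 1.5,
                               noise_sd: float = 1.0,
                               n_features: int = 64,
                               seed: int = 0):
    """Cohort with 64-d descriptors planted at the feature level.

    The descriptor field has a dominant component carrying *biological age*
    (chronological age plus a mortality-linked acceleration ``z``, which
    enters the log hazard with coefficient ``mortality_effect``) and a
    weaker secondary component carrying chronological age only:

        d^n = s1 (a^n + c z^n) u1 + s2 a^n u2 + noise,   u1 ⊥ u2,

    with ``a`` the standardized age.  An unsupervised first principal
    component recovers the dominant direction and therefore inherits the
    acceleration (strong mortality association, noisier age estimate); a
    supervised regression can combine both directions to cancel part of
    ``z`` and predict age better — at the cost of the mortality signal.

    Returns ``(cohort_df, descriptors)``.
    """
    rng = np.random.default_rng(seed)
    n = n_subjects
    lo, hi = age_range
    age = rng.uniform(lo, hi, size=n)
    a = (age - age.mean()) / age.std()
    z = rng.standard_normal(n)

    basis = np.linalg.qr(rng.standard_normal((n_features, 2)))[0]
    u1, u2 = basis[:, 0], basis[:, 1]
    D = (dominant_scale * np.outer(a + acceleration_sd * z, u1)
         + secondary_scale * np.outer(a, u2)
         + noise_sd * rng.standard_normal((n, n_features)))

    t1 = age
    lp = mortality_effect * z
    t_event = sample_event_time(t1, lp, M0, Gamma, rng)
    t_cens = t1 + followup_max * (1.0 - rng.uniform(0.0, 1.0, size=n))
    delta = (t_event <= t_cens).astype(int)
    t2 = np.minimum(t_event, t_cens)

    df = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "t1": t1, "t2": t2, "delta": delta,
        "age": age, "gender": rng.binomial(1, 0.5, size=n),
        "acceleration_true": z,
    })
    return df, D
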