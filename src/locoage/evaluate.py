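"""Survival-evaluation machinery: detrending, Cox tests, Kaplan-Meier.

Candidate scores (biological-age accelerations, linearized-hazard
predictions) are tested against all-cause mortality with a semiparametric
Cox proportional-hazards model on the age axis — subjects enter the risk
set at their enrollment age ``t1`` (delayed entry) and leave at ``t2``.
Ties are handled with Efron's approximation (the default of lifelines and
of R's ``survival::coxph``).
Scores are linearly detrended by the health-risk covariates and
standardized beforehand, so hazard ratios are per SD of the residual
score, and effects are converted into years of life via the Gompertz
exponent: ``years = ln(HR) / 0.085``.

Risk stratification mirrors the matched-peer construction: per gender a
smooth (local-linear, 5-year bandwidth) reference curve of predicted
biological age versus chronological age is fitted; a subject's
acceleration is the excess over that reference, and the sign of the
acceleration splits the cohort into high-/low-risk groups compared with a
delayed-entry log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import chi2

__all__ = [
    "EffectReport",
    "KMResult",
    "detrend_standardize",
    "cox_ph_test",
    "effect_to_years",
    "stratify_km",
    "km_left_truncated",
    "logrank_left_truncated",
]

#: Gompertz exponent used for the effect-to-years conversion, 1/year.
GOMPERTZ_SLOPE = 0.085


@dataclass
class EffectReport:
    covariate_name: str
    hazard_ratio: float
    ci95: tuple
    p_value: float
    years_equivalent: float
    log_hr: float = np.nan
    se: float = np.nan
    z: float = np.nan


@dataclass
class KMResult:
    curves: dict          # group label -> DataFrame(time, survival)
    logrank_p: float
    groups: pd.Series     # per-subject {"high", "low"}
    acceleration: np.ndarray
    n_events: dict


def detrend_standardize(covariates: pd.DataFrame,
                        protect=("age",)) -> pd.DataFrame:
    """Residualize each unprotected column on all other columns, then
    standardize to zero mean and unit variance.  Protected columns (age)
    pass through untouched.
    """
    X = covariates.astype(float)
    out = X.copy()
    cols = list(X.columns)
    for col in cols:
        if col in protect:
            continue
        others = [c for c in cols if c != col]
        A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy()
                                                 for c in others])
        y = X[col].to_numpy()
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            raise ValueError(f"collinear design when detrending '{col}' "
                             f"on {others}")
        resid = y - A @ coef
        sd = resid.std()
        if sd == 0:
            raise ValueError(f"column '{col}' fully explained by the "
                             "others: zero residual variance")
        out[col] = (resid - resid.mean()) / sd
    return out


def cox_ph_test(cohort: pd.DataFrame, score, adjusters: pd.DataFrame = None,
                *, t1_col: str = "t1", t2_col: str = "t2",
                event_col: str = "delta",
                name: str = "score") -> EffectReport:
    """Delayed-entry Cox partial-likelihood test of a per-subject score.

    Returns the hazard ratio per unit of ``score`` (per SD when the score
    is standardized), its Wald 95% CI and p-value, plus the equivalent in
    years of life.
    """
    score = np.asarray(score, dtype=float)
    df = pd.DataFrame({
        "t1": cohort[t1_col].to_numpy(dtype=float),
        "t2": cohort[t2_col].to_numpy(dtype=float),
        "delta": cohort[event_col].to_numpy(dtype=int),
        name: score,
    })
    if df["delta"].sum() < 2:
        raise ValueError("need at least two events for a Cox test")
    if adjusters is not None:
        for c in adjusters.columns:
            df[c] = adjusters[c].to_numpy(dtype=float)
    # lifelines requires strictly positive duration; entry ties broken at
    # machine scale only when t1 == t2
    eps = 1e-9 * max(1.0, df["t2"].abs().max())
    df.loc[df["t2"] <= df["t1"], "t2"] = df["t1"] + eps

    cph = CoxPHFitter()
    cph.fit(df, duration_col="t2", event_col="delta", entry_col="t1")
    s = cph.summary.loc[name]
    hr = float(s["exp(coef)"])
    return EffectReport(
        covariate_name=name,
        hazard_ratio=hr,
        ci95=(float(s["exp(coef) lower 95%"]),
              float(s["exp(coef) upper 95%"])),
        p_value=float(s["p"]),
        years_equivalent=effect_to_years(hr),
        log_hr=float(s["coef"]), se=float(s["se(coef)"]), z=float(s["z"]))


def effect_to_years(hazard_ratio: float, decimals: int | None = 1) -> float:
    """Convert a hazard ratio to the equivalent difference in life
    expectancy, ``ln(HR) / 0.085`` years, rounded to one decimal by
    default (pass ``decimals=None`` for the unrounded value)."""
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    years = float(np.log(hazard_ratio) / GOMPERTZ_SLOPE)
    return years if decimals is None else round(years, decimals)


def _local_linear(x_train, y_train, x_eval, bandwidth: float = 5.0):
    """Gaussian-kernel local-linear smoother (reference bioage curve)."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        w = np.exp(-0.5 * ((x_train - x0) / bandwidth) ** 2)
        sw = w.sum()
        xm = (w @ x_train) / sw
        ym = (w @ y_train) / sw
        sxx = w @ (x_train - xm) ** 2
        slope = (w @ ((x_train - xm) * (y_train - ym))) / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (x0 - xm)
    return out


def km_left_truncated(t1, t2, delta, min_risk: int = 10) -> pd.DataFrame:
    """Product-limit survival curve with delayed-entry risk sets.

    With staggered entry the earliest risk sets contain only a handful of
    subjects and a single death there would implausibly zero the whole
    curve, so the curve is estimated conditional on survival to the first
    age at which at least ``min_risk`` subjects are under observation.
    Returns a step function starting at (t_start, 1.0).
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    delta = np.asarray(delta, dtype=int)
    entry_sorted = np.sort(t1)
    t_start = entry_sorted[min(min_risk, len(entry_sorted)) - 1]
    times = [t_start]
    surv = [1.0]
    s = 1.0
    for t in np.unique(t2[(delta == 1) & (t2 > t_start)]):
        n = np.sum((t1 < t) & (t <= t2))
        d = np.sum((t2 == t) & (delta == 1))
        if n == 0:
            continue
        s *= 1.0 - d / n
        times.append(t)
        surv.append(s)
    return pd.DataFrame({"time": times, "survival": surv})


def logrank_left_truncated(t1, t2, delta, group) -> float:
    """Two-sided log-rank p-value with delayed-entry risk sets.

    At each distinct death time ``t`` the risk set is ``{n: t1 < t <= t2}``;
    observed minus expected deaths in one group is accumulated with the
    hypergeometric variance.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    delta = np.asarray(delta, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank test needs exactly two groups")
    in1 = g == labels[0]

    times = np.unique(t2[delta == 1])
    O = E = V = 0.0
    for t in times:
        at_risk = (t1 < t) & (t <= t2)
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        dying = (t2 == t) & (delta == 1)
        d = dying.sum()
        d1 = (dying & in1).sum()
        if n < 2 or d == 0:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        raise ValueError("log-rank variance is zero (a group has no events)")
    stat = (O - E) ** 2 / V
    return float(chi2.sf(stat, df=1))


def stratify_km(cohort: pd.DataFrame, bioage, age, gender, *,
                bandwidth: float = 5.0, t1_col: str = "t1",
                t2_col: str = "t2", event_col: str = "delta") -> KMResult:
    """High/low-risk Kaplan-Meier stratification by aging acceleration.

    Acceleration is predicted biological age minus the smoothed reference
    of gender- and age-matched peers; subjects with positive acceleration
    form the high-risk group.
    """
    bioage = np.asarray(bioage, dtype=float)
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender)
    reference = np.empty(len(bioage))
    for gval in np.unique(gender):
        m = gender == gval
        reference[m] = _local_linear(age[m], bioage[m], age[m], bandwidth)
    acceleration = bioage - reference
    groups = pd.Series(np.where(acceleration > 0, "high", "low"),
                       index=cohort.index)

    t1 = cohort[t1_col].to_numpy(dtype=float)
    t2 = cohort[t2_col].to_numpy(dtype=float)
    delta = cohort[event_col].to_numpy(dtype=int)

    curves, n_events = {}, {}
    for label in ("high", "low"):
        m = (groups == label).to_numpy()
        n_events[label] = int(delta[m].sum())
        curves[label] = km_left_truncated(t1[m], t2[m], delta[m])
    if min(n_events.values()) == 0:
        raise ValueError("a risk group has zero events: log-rank undefined")
    p = logrank_left_truncated(t1, t2, delta, groups.to_numpy())
    return KMResult(curves=curves, logrank_p=p, groups=groups,
                    acceleration=acceleration, n_events=n_events)
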