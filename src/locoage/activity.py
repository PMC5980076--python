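"""Locomotor-activity descriptors from minute-level accelerometer counts.

A 7-day track of per-minute "activity counts" is discretized into K = 8
intensity states with bin edges ``b_k = e^k - 1``, k = 1..7 (state 0:
``a < e - 1``; state k: ``b_k <= a < b_{k+1}``; state 7: ``a >= e^7 - 1``).
Per subject, the empirical 8x8 matrix of transition rates between
consecutive-minute states is computed (column j holds the distribution of
destinations out of state j; diagonal entries are the probabilities of
staying put), flattened row-major to a 64-vector, floored at 1e-3 (roughly
ten transitions per week) and natural-log scaled.  Aggregate covariates —
mean counts per day and its negative logarithm — come from the same valid
days.

Quality filters: mean count in [50, 5000]; a day is valid when at least
200 of its minutes are in a state above rest; subjects need >= 4 valid
days and age below 85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ActivityTrack",
    "FilterReport",
    "TransitionDescriptor",
    "TransitionMatrixFeaturizer",
    "filter_track",
    "discretize_counts",
    "valid_day_mask",
    "transition_matrix",
    "log_scale_descriptor",
    "activity_covariates",
    "describe_track",
]

MINUTES_PER_DAY = 1440
N_STATES = 8
#: bin edges b_k = e^k - 1, k = 1..7
BIN_EDGES = np.exp(np.arange(1, N_STATES)) - 1.0
#: imputation floor for near-zero transition rates
RATE_FLOOR = 1e-3

MEAN_COUNT_MIN = 50.0
MEAN_COUNT_MAX = 5000.0
MIN_ACTIVE_MINUTES = 200
MIN_VALID_DAYS = 4
MAX_AGE = 85.0


@dataclass
class ActivityTrack:
    """One subject's minute-level activity counts (nominally 7 days)."""

    subject_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")
        if len(self.counts) % MINUTES_PER_DAY != 0:
            raise ValueError("track length must be a whole number of days "
                             f"({MINUTES_PER_DAY}-minute blocks)")

    @property
    def n_days(self) -> int:
        return len(self.counts) // MINUTES_PER_DAY

    def by_day(self) -> np.ndarray:
        return self.counts.reshape(self.n_days, MINUTES_PER_DAY)


@dataclass
class FilterReport:
    subject_id: str
    mean_count: float
    n_valid_days: int
    passed: bool
    reasons: list = field(default_factory=list)


@dataclass
class TransitionDescriptor:
    subject_id: str
    tm: np.ndarray                 # 8x8, columns = from-state
    descriptor: np.ndarray         # 64, natural-log scale
    mean_daily_activity: float     # counts/day over valid days
    neg_log_activity: float


def state_count_bounds():
    """(low, high) integer count bounds of each state's half-open bin.

    Used by synthetic emission; the top state is capped one e-fold above
    its lower edge.
    """
    lows = np.concatenate([[0.0], BIN_EDGES])
    highs = np.concatenate([BIN_EDGES, [np.exp(N_STATES) - 1.0]])
    return lows, highs


def discretize_counts(counts) -> np.ndarray:
    """Map activity counts onto states 0..7 via the half-open e-fold bins."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("activity counts must be non-negative")
    return np.digitize(counts, BIN_EDGES)


def valid_day_mask(track: ActivityTrack) -> np.ndarray:
    """True for days with >= 200 minutes spent above the rest state."""
    states = discretize_counts(track.counts).reshape(track.n_days,
                                                     MINUTES_PER_DAY)
    return (states > 0).sum(axis=1) >= MIN_ACTIVE_MINUTES


def filter_track(track: ActivityTrack, age: float) -> FilterReport:
    """Apply the cohort quality rules; reasons list every violated rule."""
    mean_count = float(track.counts.mean())
    n_valid = int(valid_day_mask(track).sum())
    reasons = []
    if mean_count < MEAN_COUNT_MIN:
        reasons.append("mean_count<50")
    if mean_count > MEAN_COUNT_MAX:
        reasons.append("mean_count>5000")
    if n_valid < MIN_VALID_DAYS:
        reasons.append("valid_days<4")
    if age >= MAX_AGE:
        reasons.append("age>=85")
    return FilterReport(subject_id=track.subject_id, mean_count=mean_count,
                        n_valid_days=n_valid, passed=not reasons,
                        reasons=reasons)


def transition_matrix(states, day_mask=None) -> np.ndarray:
    """Empirical transition-rate matrix ``T[i, j] = P(to i | from j)``.

    ``states`` is a minute-level state sequence; transitions are counted
    only between consecutive minutes that both lie in valid days (junctions
    created by dropping a day are artifacts and are not counted).  Columns
    of states never used as a source stay all-zero.
    """
    states = np.asarray(states)
    if np.any((states < 0) | (states >= N_STATES)):
        raise ValueError(f"states must lie in [0, {N_STATES - 1}]")
    if day_mask is not None:
        day_mask = np.asarray(day_mask, dtype=bool)
        minute_ok = np.repeat(day_mask, MINUTES_PER_DAY)
        if minute_ok.size != states.size:
            raise ValueError("day mask does not match the track length")
    else:
        minute_ok = np.ones(states.size, dtype=bool)

    ok = minute_ok[:-1] & minute_ok[1:]
    src = states[:-1][ok]
    dst = states[1:][ok]
    if src.size == 0:
        raise ValueError("no transitions within valid days")
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (dst, src), 1.0)
    out = counts.sum(axis=0)
    tm = np.divide(counts, out, out=np.zeros_like(counts),
                   where=out > 0)
    return tm


def log_scale_descriptor(tm) -> np.ndarray:
    """Flatten row-major, floor near-zero rates at 1e-3, natural log."""
    tm = np.asarray(tm, dtype=float)
    if tm.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected an {N_STATES}x{N_STATES} matrix")
    if np.any((tm < 0) | (tm > 1)):
        raise ValueError("transition rates must lie in [0, 1]")
    flat = tm.reshape(-1).copy()
    flat[flat < RATE_FLOOR] = RATE_FLOOR
    return np.log(flat)


def activity_covariates(track: ActivityTrack, day_mask=None):
    """(mean daily counts, its negative natural log) over valid days."""
    days = track.by_day()
    if day_mask is not None:
        day_mask = np.asarray(day_mask, dtype=bool)
        days = days[day_mask]
    if len(days) == 0:
        raise ValueError("no valid days")
    mean_daily = float(days.sum(axis=1).mean())
    if mean_daily <= 0:
        raise ValueError("zero total activity: log undefined")
    return mean_daily, float(-np.log(mean_daily))


def describe_track(track: ActivityTrack, day_mask=None) -> TransitionDescriptor:
    """Full per-subject descriptor: TM, log-scaled 64-vector, aggregates."""
    if day_mask is None:
        day_mask = valid_day_mask(track)
    states = discretize_counts(track.counts)
    tm = transition_matrix(states, day_mask)
    descriptor = log_scale_descriptor(tm)
    mean_daily, neg_log = activity_covariates(track, day_mask)
    return TransitionDescriptor(subject_id=track.subject_id, tm=tm,
                                descriptor=descriptor,
                                mean_daily_activity=mean_daily,
                                neg_log_activity=neg_log)


class TransitionMatrixFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from activity tracks to 64-d log-TM descriptors.

    ``transform`` accepts a sequence of :class:`ActivityTrack` and returns
    an ``(n, 64)`` array; :meth:`describe` additionally returns the
    aggregate activity covariates and subject ids as a DataFrame.
    """

    def __init__(self, use_valid_day_mask: bool = True):
        self.use_valid_day_mask = use_valid_day_mask

    def fit(self, X, y=None):
        self.n_features_out_ = N_STATES * N_STATES
        return self

    def transform(self, X):
        return np.vstack([self._one(t).descriptor for t in X])

    def _one(self, track: ActivityTrack) -> TransitionDescriptor:
        mask = valid_day_mask(track) if self.use_valid_day_mask else None
        return describe_track(track, mask)

    def describe(self, X):
        import pandas as pd

        descs = [self._one(t) for t in X]
        df = pd.DataFrame({
            "subject_id": [d.subject_id for d in descs],
            "mean_daily_activity": [d.mean_daily_activity for d in descs],
            "neg_log_activity": [d.neg_log_activity for d in descs],
        })
        return np.vstack([d.descriptor for d in descs]), df
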