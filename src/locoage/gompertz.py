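"""Parametric Gompertz proportional-hazards model.

The mortality rate of subject ``n`` with covariates ``x`` is modelled as

    M(t, x) = M0 * exp(Gamma * t) * exp(beta . x)

where ``M0`` is the initial mortality rate (1/year), ``Gamma`` the Gompertz
exponent (1/year, mortality doubling time ln2/Gamma) and ``beta`` the vector
of log hazard ratios.  Subjects are observed on the age interval
``(t1, t2]`` (delayed entry at the enrollment age ``t1``), with event
indicator ``delta``.  The negative log-likelihood is

    -log LH = sum_n (M0/Gamma) exp(beta.x^n) f_n
              - sum_n delta^n (log M0 + beta.x^n + Gamma t2^n),

    f_n = exp(Gamma t2^n) - exp(Gamma t1^n),

the ``f_n`` term conditioning each contribution on survival to ``t1``.
Maximisation is performed by quasi-Newton descent on
``(log M0, log Gamma, beta)`` with analytic gradients, which keeps the two
positive parameters unconstrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "GompertzFit",
    "GompertzPH",
    "fit_gompertz",
    "gompertz_hazard",
    "neg_log_likelihood",
]

#: Gompertz exponent widely accepted for adult human cohorts, 1/year.
ACCEPTED_GAMMA = 0.085

_EXP_CLIP = 500.0  # exponent guard during line search


def _validate_survival(t1, t2, delta):
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    delta = np.asarray(delta)
    if t1.shape != t2.shape or t1.shape != delta.shape:
        raise ValueError("t1, t2 and delta must have identical shapes")
    if np.any(t1 < 0):
        raise ValueError("enrollment ages t1 must be non-negative")
    if np.any(t2 < t1):
        bad = int(np.sum(t2 < t1))
        raise ValueError(f"{bad} records have t2 < t1")
    if not np.isin(delta, (0, 1)).all():
        raise ValueError("delta must be a 0/1 event indicator")
    return t1, t2, delta.astype(float)


def gompertz_hazard(t, x, M0: float, Gamma: float, beta=None):
    """Hazard ``M0 * exp(Gamma t) * exp(beta . x)`` in 1/year.

    ``x`` may be None / empty when the model has no covariates.
    """
    if M0 <= 0 or Gamma <= 0:
        raise ValueError("M0 and Gamma must be positive")
    t = np.asarray(t, dtype=float)
    lp = 0.0
    if beta is not None and np.size(beta):
        lp = np.asarray(x, dtype=float) @ np.asarray(beta, dtype=float)
    return M0 * np.exp(Gamma * t + lp)


def _nll_terms(t1, t2, delta, X, M0, Gamma, beta, l2_penalty=0.0):
    """Return (nll, f_n, w_n) where w_n = exp(beta.x^n)."""
    with np.errstate(over="ignore"):
        f = np.exp(np.minimum(Gamma * t2, _EXP_CLIP)) - np.exp(
            np.minimum(Gamma * t1, _EXP_CLIP)
        )
        lp = X @ beta if X.shape[1] else np.zeros(len(t1))
        w = np.exp(np.minimum(lp, _EXP_CLIP))
        nll = (M0 / Gamma) * np.sum(w * f) - np.sum(
            delta * (np.log(M0) + lp + Gamma * t2)
        )
        nll = nll + l2_penalty * float(beta @ beta)
    return nll, f, w


def neg_log_likelihood(t1, t2, delta, X=None, *, M0: float, Gamma: float,
                       beta=None, l2_penalty: float = 0.0) -> float:
    """Negative log-likelihood of the Gompertz proportional-hazards model."""
    if M0 <= 0 or Gamma <= 0:
        raise ValueError("M0 and Gamma must be positive")
    t1, t2, delta = _validate_survival(t1, t2, delta)
    if X is None:
        X = np.empty((len(t1), 0))
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1]) if beta is None else np.asarray(beta, dtype=float)
    nll, _, _ = _nll_terms(t1, t2, delta, X, M0, Gamma, beta, l2_penalty)
    return float(nll)


@dataclass
class GompertzFit:
    """Result of a maximum-likelihood Gompertz proportional-hazards fit."""

    M0: float
    Gamma: float
    beta: pd.Series
    neg_log_likelihood: float
    converged: bool
    n_events: int
    covariance_estimate: pd.DataFrame
    n_iter: int = 0
    grad_norm: float = np.nan
    nll_path: list = field(default_factory=list, repr=False)

    @property
    def beta_se(self) -> pd.Series:
        """Analytic standard errors of beta from the observed information."""
        names = list(self.beta.index)
        if not names:
            return pd.Series(dtype=float)
        d = np.sqrt(np.diag(self.covariance_estimate.loc[names, names]))
        return pd.Series(d, index=names)

    def hazard(self, t, x=None):
        if x is None:
            x = np.zeros((np.size(t), len(self.beta)))
        return gompertz_hazard(t, x, self.M0, self.Gamma, self.beta.to_numpy())

    def expected_events(self, t1, t2, X=None) -> float:
        """Model-integrated hazard summed over the cohort."""
        t1 = np.asarray(t1, dtype=float)
        t2 = np.asarray(t2, dtype=float)
        f = np.exp(self.Gamma * t2) - np.exp(self.Gamma * t1)
        lp = 0.0
        if X is not None and len(self.beta):
            lp = np.asarray(X, dtype=float) @ self.beta.to_numpy()
        return float((self.M0 / self.Gamma) * np.sum(np.exp(lp) * f))


class GompertzPH(BaseEstimator):
    """Maximum-likelihood Gompertz proportional-hazards estimator.

    Parameters
    ----------
    l2_penalty : float
        Ridge penalty ``l2 * ||beta||^2`` added to the negative
        log-likelihood.  It never applies to ``M0`` or ``Gamma``.
    fix_M0, fix_Gamma : float or None
        Hold the baseline parameter at the given value instead of
        estimating it.  Fixing ``Gamma`` is the standard remedy for the
        shallow joint (M0, Gamma) profile in cohorts with few deaths.
    init_Gamma : float
        Starting value of the Gompertz exponent; ``M0`` is initialised so
        that expected deaths match observed deaths at ``init_Gamma``.
    gtol : float
        Gradient-norm convergence tolerance.
    max_iter : int
        Iteration cap for the quasi-Newton optimizer.

    Fitted attributes: ``M0_``, ``Gamma_``, ``beta_`` (pd.Series),
    ``fit_`` (the full :class:`GompertzFit` record).
    """

    def __init__(self, l2_penalty: float = 0.0, fix_M0=None, fix_Gamma=None,
                 init_Gamma: float = ACCEPTED_GAMMA, gtol: float = 1e-8,
                 max_iter: int = 500):
        self.l2_penalty = l2_penalty
        self.fix_M0 = fix_M0
        self.fix_Gamma = fix_Gamma
        self.init_Gamma = init_Gamma
        self.gtol = gtol
        self.max_iter = max_iter

    # -- objective ---------------------------------------------------------

    def _pack(self, logM0, logGamma, beta):
        free = []
        if self.fix_M0 is None:
            free.append(logM0)
        if self.fix_Gamma is None:
            free.append(logGamma)
        return np.concatenate([free, beta])

    def _unpack(self, theta):
        i = 0
        if self.fix_M0 is None:
            logM0 = theta[i]; i += 1
        else:
            logM0 = np.log(self.fix_M0)
        if self.fix_Gamma is None:
            logGamma = theta[i]; i += 1
        else:
            logGamma = np.log(self.fix_Gamma)
        return logM0, logGamma, theta[i:]

    def _objective(self, theta, t1, t2, delta, X, Nd):
        logM0, logGamma, beta = self._unpack(theta)
        M0, Gamma = np.exp(logM0), np.exp(logGamma)
        nll, f, w = _nll_terms(t1, t2, delta, X, M0, Gamma, beta,
                               self.l2_penalty)
        if not np.isfinite(nll):
            return np.inf, np.full_like(theta, np.nan)
        A = (M0 / Gamma) * np.sum(w * f)
        grad = []
        if self.fix_M0 is None:
            grad.append(A - Nd)
        if self.fix_Gamma is None:
            with np.errstate(over="ignore"):
                texp = t2 * np.exp(np.minimum(Gamma * t2, _EXP_CLIP)) - \
                    t1 * np.exp(np.minimum(Gamma * t1, _EXP_CLIP))
            g_logGamma = -A + M0 * np.sum(w * texp) - Gamma * np.sum(delta * t2)
            grad.append(g_logGamma)
        if X.shape[1]:
            g_beta = (M0 / Gamma) * (X.T @ (w * f)) - X.T @ delta \
                + 2.0 * self.l2_penalty * beta
            grad = np.concatenate([grad, g_beta])
        else:
            grad = np.asarray(grad)
        return nll, grad

    # -- fitting -----------------------------------------------------------

    def fit(self, df: pd.DataFrame, *, t1_col: str = "t1", t2_col: str = "t2",
            event_col: str = "delta", covariate_cols=None):
        """Fit the model on a cohort DataFrame.

        ``covariate_cols`` defaults to every column other than the three
        survival columns and ``subject_id``.
        """
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns
                              if c not in (t1_col, t2_col, event_col,
                                           "subject_id")]
        t1, t2, delta = _validate_survival(df[t1_col], df[t2_col],
                                           df[event_col])
        X = df[list(covariate_cols)].to_numpy(dtype=float)
        Nd = int(delta.sum())
        if Nd == 0 and self.fix_M0 is None:
            raise ValueError("no events in cohort: M0 is not identifiable "
                             "(fix_M0 or supply events)")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")

        Gamma0 = self.fix_Gamma if self.fix_Gamma is not None else self.init_Gamma
        f0 = np.exp(Gamma0 * t2) - np.exp(Gamma0 * t1)
        if self.fix_M0 is not None:
            M0_0 = self.fix_M0
        else:
            M0_0 = Gamma0 * Nd / max(np.sum(f0), 1e-300)
        theta0 = self._pack(np.log(M0_0), np.log(Gamma0),
                            np.zeros(X.shape[1]))

        path: list[float] = []

        def fun(theta):
            nll, grad = self._objective(theta, t1, t2, delta, X, Nd)
            return nll, grad

        def cb(theta):
            path.append(fun(theta)[0])

        res = minimize(fun, theta0, jac=True, method="BFGS",
                       callback=cb,
                       options={"gtol": self.gtol, "maxiter": self.max_iter})
        # Newton polish: BFGS stalls at gradient norms ~1e-6 on this scale;
        # a few damped Newton steps push the stationarity conditions (e.g.
        # expected deaths == observed deaths) to near machine precision.
        theta, nll_cur = res.x.copy(), float(res.fun)
        n_extra = 0
        for _ in range(25):
            g = fun(theta)[1]
            if np.max(np.abs(g)) < max(self.gtol, 1e-12 * max(abs(nll_cur), 1.0)):
                break
            H = self._hessian(theta, fun)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                break
            lam, improved = 1.0, False
            for _bt in range(30):
                nll_try = fun(theta + lam * step)[0]
                if np.isfinite(nll_try) and nll_try <= nll_cur + 1e-12:
                    theta = theta + lam * step
                    nll_cur = nll_try
                    path.append(nll_cur)
                    improved = True
                    n_extra += 1
                    break
                lam *= 0.5
            if not improved:
                break
        res.x, res.fun, res.nit = theta, nll_cur, res.nit + n_extra
        res.jac = fun(theta)[1]
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success) or grad_norm < 1e-5
        if not converged:
            warnings.warn(
                f"Gompertz fit did not converge (grad norm {grad_norm:.3g})",
                RuntimeWarning)

        logM0, logGamma, beta = self._unpack(res.x)
        names = self._param_names(covariate_cols)
        cov = self._covariance(res.x, fun, names)

        self.covariate_names_ = list(covariate_cols)
        # fixed parameters pass through exactly (no exp(log(.)) round trip)
        self.M0_ = float(self.fix_M0) if self.fix_M0 is not None \
            else float(np.exp(logM0))
        self.Gamma_ = float(self.fix_Gamma) if self.fix_Gamma is not None \
            else float(np.exp(logGamma))
        self.beta_ = pd.Series(np.asarray(beta, dtype=float),
                               index=list(covariate_cols), dtype=float)
        self.fit_ = GompertzFit(
            M0=self.M0_, Gamma=self.Gamma_, beta=self.beta_,
            neg_log_likelihood=float(res.fun), converged=converged,
            n_events=Nd, covariance_estimate=cov, n_iter=int(res.nit),
            grad_norm=grad_norm, nll_path=path)
        return self

    def _param_names(self, covariate_cols):
        names = []
        if self.fix_M0 is None:
            names.append("log_M0")
        if self.fix_Gamma is None:
            names.append("log_Gamma")
        return names + list(covariate_cols)

    @staticmethod
    def _hessian(theta, fun):
        """Observed information via central differences of the analytic
        gradient."""
        k = len(theta)
        eps = 1e-6 * np.maximum(np.abs(theta), 1.0)
        H = np.empty((k, k))
        for j in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps[j]
            tm[j] -= eps[j]
            H[:, j] = (fun(tp)[1] - fun(tm)[1]) / (2 * eps[j])
        return 0.5 * (H + H.T)

    def _covariance(self, theta, fun, names):
        k = len(theta)
        if k == 0:
            return pd.DataFrame(index=names, columns=names, dtype=float)
        H = self._hessian(theta, fun)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        return pd.DataFrame(cov, index=names, columns=names)

    # -- prediction --------------------------------------------------------

    def predict_hazard(self, t, X=None):
        return self.fit_.hazard(t, X)


def fit_gompertz(df: pd.DataFrame, *, covariate_cols=None,
                 l2_penalty: float = 0.0, fix_M0=None, fix_Gamma=None,
                 init_Gamma: float = ACCEPTED_GAMMA, **cols) -> GompertzFit:
    """Functional wrapper around :class:`GompertzPH`; returns the fit record."""
    est = GompertzPH(l2_penalty=l2_penalty, fix_M0=fix_M0,
                     fix_Gamma=fix_Gamma, init_Gamma=init_Gamma)
    est.fit(df, covariate_cols=covariate_cols, **cols)
    return est.fit_
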