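"""Perturbation-theory linearization of the Gompertz proportional-hazards loss.

Around a fitted "zero-order" model (baseline ``M0``, ``Gamma`` and effects
``beta_bar`` of the established covariates, with ``Gamma`` held fixed), the
log-likelihood is expanded to first order in the effect of a new feature
``xi``.  The expansion yields

* sample weights          ``rho^n = f_n exp(beta_bar . x^n) / sum_m f_m exp(beta_bar . x^m)``
* regression targets      ``R^n = delta^n / (rho^n N_d) - 1``
* a closed-form effect    ``beta_xi = C_rho^{-1} sum_n xi^n (delta^n - N_d rho^n)``
  with ``C_rho = N_d (<xi' xi>_rho - <xi'>_rho <xi>_rho)``
* an analytic error       ``sigma^2 = 1 / (N_d <dxi^2>_rho)`` per feature

where ``<.>_rho`` is the rho-weighted average and ``N_d`` the total death
count.  ``N_d rho^n`` is the model hazard integrated over subject ``n``'s
follow-up window, so ``delta^n - N_d rho^n`` is a martingale residual, and
the closed form is exactly the minimiser of the sample-weighted square loss

    L = sum_n rho^n (beta_xi . xi^n - R^n)^2

over rho-centred features — which is why any regressor accepting per-sample
weights can be trained against the targets ``R^n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gompertz import GompertzFit, GompertzPH

__all__ = [
    "LinearizedHazard",
    "PerturbationEffect",
    "compute_weights",
    "effect_closed_form",
    "weighted_regression_loss",
    "transform_targets",
    "linearized_vs_full_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class LinearizedHazard:
    """Zero-order weights and martingale-residual targets for a cohort.

    ``rho``, ``R`` and ``delta`` are aligned with ``keep``-masked rows of
    the cohort the zero-order model was computed on; subjects with zero
    exposure (``t1 == t2``, hence ``f_n = 0``) carry no information and are
    dropped (``n_dropped`` of them).
    """

    rho: np.ndarray
    R: np.ndarray
    delta: np.ndarray
    N_d: int
    keep: np.ndarray
    base_fit: GompertzFit
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.rho)


@dataclass
class PerturbationEffect:
    """Closed-form first-order hazard effect of features ``xi``."""

    beta_xi: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    feature_names: list


def compute_weights(df: pd.DataFrame, base_fit: GompertzFit, *,
                    t1_col: str = "t1", t2_col: str = "t2",
                    event_col: str = "delta",
                    covariate_cols=None) -> LinearizedHazard:
    """Sample weights and targets of the linearized hazard model.

    ``covariate_cols`` names the zero-order covariates (defaults to the
    covariates of ``base_fit``); ``Gamma`` is taken from ``base_fit`` and
    held fixed, as the expansion requires.
    """
    t1 = df[t1_col].to_numpy(dtype=float)
    t2 = df[t2_col].to_numpy(dtype=float)
    delta = df[event_col].to_numpy(dtype=float)
    if covariate_cols is None:
        covariate_cols = list(base_fit.beta.index)
    N_d = int(delta.sum())
    if N_d == 0:
        raise ValueError("cohort has no death events; targets undefined")

    Gamma = base_fit.Gamma
    f = np.exp(Gamma * t2) - np.exp(Gamma * t1)
    lp = np.zeros(len(df))
    if covariate_cols:
        lp = df[list(covariate_cols)].to_numpy(dtype=float) @ \
            base_fit.beta[list(covariate_cols)].to_numpy()
    w = f * np.exp(np.minimum(lp, 700.0))

    keep = w > 0
    if np.any(delta[~keep] == 1):
        raise ValueError("subject with zero exposure (f_n = 0) but an "
                         "observed death: weights degenerate")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-exposure subjects from the "
                    "linearized stage", n_dropped)

    rho = w[keep] / w[keep].sum()
    R = delta[keep] / (rho * N_d) - 1.0
    return LinearizedHazard(rho=rho, R=R, delta=delta[keep], N_d=N_d,
                            keep=keep, base_fit=base_fit,
                            n_dropped=n_dropped)


def _as_matrix(xi, lin: LinearizedHazard):
    xi = np.asarray(xi, dtype=float)
    if xi.ndim == 1:
        xi = xi[:, None]
    if xi.shape[0] == lin.keep.size and lin.keep.size != len(lin):
        xi = xi[lin.keep]
    if xi.shape[0] != len(lin):
        raise ValueError("feature matrix does not align with the cohort")
    return xi


def effect_closed_form(lin: LinearizedHazard, xi,
                       feature_names=None) -> PerturbationEffect:
    """First-order hazard effect of ``xi`` with analytic errors.

    For a single feature the error is the scalar formula
    ``sigma^2 = 1/(N_d <dxi^2>_rho)``; for several features the diagonal of
    ``C_rho^{-1}`` generalises it through the information matrix.
    """
    xi = _as_matrix(xi, lin)
    p = xi.shape[1]
    if feature_names is None:
        feature_names = [f"xi{j}" for j in range(p)]
    rho, delta, N_d = lin.rho, lin.delta, lin.N_d

    mean = rho @ xi
    xc = xi - mean
    C = N_d * (xc.T * rho) @ xc  # N_d * rho-weighted covariance
    var = np.diag(C) / N_d
    # zero variance up to rounding noise relative to the feature scale
    scale = rho @ (xi ** 2)
    degenerate = var <= 1e-12 * np.maximum(scale, 1e-300)
    if np.any(degenerate):
        bad = [feature_names[j] for j in np.where(degenerate)[0]]
        raise ValueError(f"zero rho-weighted variance for features {bad}: "
                         "C_rho singular")
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("C_rho is numerically singular (collinear "
                         f"features among {feature_names})")

    score = xi.T @ (delta - N_d * rho)
    beta = np.linalg.solve(C, score)
    Cinv = np.linalg.inv(C)
    sigma = np.sqrt(np.diag(Cinv))
    z = beta / sigma
    pval = 2.0 * norm.sf(np.abs(z))
    return PerturbationEffect(beta_xi=beta, sigma=sigma, z=z, p_value=pval,
                              feature_names=list(feature_names))


def weighted_regression_loss(beta_xi, xi, lin: LinearizedHazard) -> float:
    """Sample-weighted square loss ``sum_n rho^n (beta.xi^n - R^n)^2``.

    This is the training objective any external regressor can minimise with
    per-sample weights ``lin.rho`` and targets ``lin.R``.
    """
    xi = _as_matrix(xi, lin)
    pred = xi @ np.atleast_1d(np.asarray(beta_xi, dtype=float))
    return float(np.sum(lin.rho * (pred - lin.R) ** 2))


def transform_targets(R) -> np.ndarray:
    """Rank-based inverse-normal transform, standardized to mean 0, SD 1.

    Uses the Blom offset ``(rank - 3/8)/(n + 1/4)``; ties share the mean
    rank, so the map is monotone in ``R``.
    """
    R = np.asarray(R, dtype=float)
    n = R.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.all(R == R[0]):
        raise ValueError("all targets equal: transform degenerate")
    ranks = pd.Series(R).rank(method="average").to_numpy()
    q = norm.ppf((ranks - 0.375) / (n + 0.25))
    return (q - q.mean()) / q.std()


def linearized_vs_full_fit(df: pd.DataFrame, xi, *, base_fit=None,
                           covariate_cols=("gender",),
                           t1_col: str = "t1", t2_col: str = "t2",
                           event_col: str = "delta") -> dict:
    """Compare the first-order effect with a full maximum-likelihood refit.

    The full model re-maximises the Gompertz likelihood with ``xi`` added
    as a covariate, ``Gamma`` fixed at the zero-order value.  Agreement is
    expected in the small-effect regime; a large true effect leaves the
    linearization's validity region and a systematic discrepancy appears.
    """
    covariate_cols = list(covariate_cols)
    if base_fit is None:
        base_fit = GompertzPH().fit(
            df, t1_col=t1_col, t2_col=t2_col, event_col=event_col,
            covariate_cols=covariate_cols).fit_
    lin = compute_weights(df, base_fit, t1_col=t1_col, t2_col=t2_col,
                          event_col=event_col, covariate_cols=covariate_cols)
    eff = effect_closed_form(lin, xi)

    xi_arr = np.asarray(xi, dtype=float)
    if xi_arr.ndim == 1:
        xi_arr = xi_arr[:, None]
    full_df = df.copy()
    xi_names = [f"xi{j}" for j in range(xi_arr.shape[1])]
    for j, name in enumerate(xi_names):
        full_df[name] = xi_arr[:, j]
    full = GompertzPH(fix_Gamma=base_fit.Gamma).fit(
        full_df, t1_col=t1_col, t2_col=t2_col, event_col=event_col,
        covariate_cols=covariate_cols + xi_names).fit_
    beta_full = full.beta[xi_names].to_numpy()
    return {
        "beta_linearized": eff.beta_xi,
        "beta_full": beta_full,
        "sigma_analytic": eff.sigma,
        "discrepancy": eff.beta_xi - beta_full,
        "base_fit": base_fit,
        "full_fit": full,
        "effect": eff,
    }
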