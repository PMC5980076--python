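"""Biological age from locomotor-activity descriptors.

Two linear biological-age scores over the 64-d log-transition-matrix
descriptors:

* :class:`PCAAge` — unsupervised.  The first principal component of the
  centered descriptors is taken as the ageing score (its sign fixed so the
  score grows with age) and rescaled to years by a univariate regression
  of chronological age on the score.  No cross-validation: thousands of
  samples against 64 features leave little room to overfit.
* :class:`RidgeAge` — supervised.  An L2-regularized multivariate
  regression of chronological age on the standardized descriptors, the
  penalty chosen by 5-fold cross-validation over a logarithmic grid.

Both predictors are affine in the descriptor, so they expose a common
``(center_, weights_, intercept_)`` affine form.  Aging acceleration —
the predicted minus the reference age of matched peers — is computed in
:mod:`locoage.evaluate`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

__all__ = ["PCAAge", "RidgeAge", "fit_pca_age", "fit_reg_age",
           "predict_bioage"]


def _validate(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptor matrix must be 2-D")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("ages must be a vector matching the rows of X")
        if not np.all(np.isfinite(y)):
            raise ValueError("ages must be finite")
    return X, y


class PCAAge(RegressorMixin, BaseEstimator):
    """Unsupervised first-principal-component biological age.

    Fitted attributes: ``center_`` (column means), ``loadings_`` (first
    right singular vector, sign such that the score correlates positively
    with training age), ``slope_``/``intercept_`` (years per score unit /
    years) from the univariate rescaling, and the affine-form aliases
    ``weights_`` and ``bias_``.
    """

    kind = "pca"

    def fit(self, X, y):
        X, y = _validate(X, y)
        self.center_ = X.mean(axis=0)
        Xc = X - self.center_
        if np.allclose(Xc, 0):
            raise ValueError("descriptors have zero variance: PCA degenerate")
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        v = Vt[0]
        score = Xc @ v
        if np.cov(score, y)[0, 1] < 0:
            v = -v
            score = -score
        self.loadings_ = v
        # univariate regression of age on the PC score
        c = np.cov(score, y)
        self.slope_ = float(c[0, 1] / c[0, 0])
        self.intercept_ = float(y.mean() - self.slope_ * score.mean())
        self.weights_ = self.slope_ * self.loadings_
        self.bias_ = self.intercept_
        return self

    def score_raw(self, X):
        """Centered first-PC projection (score units, not years)."""
        X, _ = _validate(X)
        return (X - self.center_) @ self.loadings_

    def predict(self, X):
        X, _ = _validate(X)
        if X.shape[1] != self.center_.size:
            raise ValueError(f"expected {self.center_.size}-d descriptors")
        return self.intercept_ + self.slope_ * ((X - self.center_)
                                                @ self.loadings_)


class RidgeAge(RegressorMixin, BaseEstimator):
    """L2-regularized multivariate regression age, penalty by 5-fold CV.

    The penalty grid defaults to ``logspace(-3, 3, 25) * n_samples``; folds
    are shuffled with ``random_state`` and recorded in ``cv_metadata_``.
    Descriptors are centered and scaled to unit variance before the
    penalized fit (penalty comparability across columns); the exported
    ``weights_`` are mapped back to the raw descriptor scale.
    """

    kind = "ridge"

    def __init__(self, alphas=None, n_folds: int = 5, random_state: int = 0):
        self.alphas = alphas
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate(X, y)
        n = X.shape[0]
        if n < 2 * self.n_folds:
            raise ValueError("too few samples for cross-validation")
        alphas = (np.logspace(-3, 3, 25) * n if self.alphas is None
                  else np.asarray(self.alphas, dtype=float))
        if np.any(alphas <= 0):
            raise ValueError("penalties must be positive")

        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd

        kf = KFold(self.n_folds, shuffle=True,
                   random_state=self.random_state)
        folds = list(kf.split(Z))
        cv_mse = np.zeros(len(alphas))
        for itrain, itest in folds:
            for k, a in enumerate(alphas):
                r = Ridge(alpha=a).fit(Z[itrain], y[itrain])
                cv_mse[k] += np.mean((r.predict(Z[itest]) - y[itest]) ** 2)
        cv_mse /= len(folds)
        best = int(np.argmin(cv_mse))

        final = Ridge(alpha=alphas[best]).fit(Z, y)
        self.center_ = mu
        self.scale_ = sd
        self.coef_std_ = final.coef_
        self.weights_ = final.coef_ / sd
        self.bias_ = float(final.intercept_)
        self.alpha_ = float(alphas[best])
        self.cv_metadata_ = {
            "alphas": alphas,
            "cv_mse": cv_mse,
            "chosen_alpha": self.alpha_,
            "n_folds": self.n_folds,
            "random_state": self.random_state,
        }
        return self

    def predict(self, X):
        X, _ = _validate(X)
        if X.shape[1] != self.center_.size:
            raise ValueError(f"expected {self.center_.size}-d descriptors")
        return self.bias_ + (X - self.center_) @ self.weights_


def fit_pca_age(descriptors, ages) -> PCAAge:
    """Fit the unsupervised PCA biological-age model."""
    return PCAAge().fit(descriptors, ages)


def fit_reg_age(descriptors, ages, penalties=None,
                random_state: int = 0) -> RidgeAge:
    """Fit the supervised ridge biological-age model."""
    return RidgeAge(alphas=penalties, random_state=random_state).fit(
        descriptors, ages)


def predict_bioage(model, descriptor) -> np.ndarray:
    """Predict biological age (years) from 64-d descriptors."""
    d = np.asarray(descriptor, dtype=float)
    one = d.ndim == 1
    out = model.predict(d[None, :] if one else d)
    return float(out[0]) if one else out
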