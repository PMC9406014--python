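"""Least-squares support vector regression (LS-SVR) with a Gaussian RBF kernel.

LS-SVR replaces the quadratic program of epsilon-SVR with one dense linear
system over kernel evaluations:

    [ 0   1^T          ] [ b0 ]   [ 0 ]
    [ 1   K + I/gamma  ] [ b  ] = [ y ]

where ``K`` is the m x m Gram matrix ``K_ij = exp(-||x_i - x_j||^2 / (2 sigma2))``,
``gamma`` the regularisation weight and ``b0`` the offset.  The first row
enforces ``sum(b) = 0``.  Prediction is ``f(x) = b0 + sum_i b_i k(x, x_i)``.

At the dataset sizes typical of laboratory calibration (tens of samples) the
dense direct solve is both exact and fast, so no iterative solver is offered.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold, LeaveOneOut

from .exceptions import ConfigError, InvalidInputError, NumericalError

__all__ = ["rbf_kernel", "LSSVR", "rmsecv", "make_cv_folds"]

#: sample-count threshold below which the default CV scheme is leave-one-out
LOO_MAX_SAMPLES = 60


def rbf_kernel(xa: np.ndarray, xb: np.ndarray, sigma2: float):
    """Gaussian RBF kernel ``exp(-||xa - xb||^2 / (2 sigma2))``.

    Accepts two vectors (returns a scalar) or two 2-D sample matrices
    (returns the Gram matrix between their rows).
    """
    if not (np.isfinite(sigma2) and sigma2 > 0):
        raise ConfigError(f"sigma2 must be positive and finite, got {sigma2}")
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.ndim == 1 and xb.ndim == 1:
        if xa.shape != xb.shape:
            raise InvalidInputError("kernel arguments must have equal length")
        d2 = float(np.sum((xa - xb) ** 2))
        return float(np.exp(-d2 / (2.0 * sigma2)))
    xa = np.atleast_2d(xa)
    xb = np.atleast_2d(xb)
    if xa.shape[1] != xb.shape[1]:
        raise InvalidInputError(
            f"kernel arguments differ in dimension: {xa.shape[1]} vs {xb.shape[1]}"
        )
    d2 = cdist(xa, xb, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma2))


class LSSVR(RegressorMixin, BaseEstimator):
    """Least-squares SVR estimator.

    Parameters
    ----------
    gamma : float
        Regularisation weight; larger values fit the training data more
        closely (``gamma -> inf`` interpolates, ``gamma -> 0`` predicts the
        target mean).
    sigma2 : float
        RBF kernel width parameter (the ``sigma^2`` in the exponent
        denominator ``2 sigma^2``).
    center_targets : bool
        Centre ``y`` internally before solving (better conditioning); the
        centring is inverted exactly on prediction.

    Attributes
    ----------
    b_ : ndarray of shape (m,)
        Support coefficients; ``sum(b_) == 0`` up to round-off.
    b0_ : float
        Model offset (on the original target scale).
    X_fit_ : ndarray of shape (m, n)
        Stored training spectra.
    """

    def __init__(self, gamma: float = 100.0, sigma2: float = 10.0,
                 center_targets: bool = True):
        self.gamma = gamma
        self.sigma2 = sigma2
        self.center_targets = center_targets

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InvalidInputError(
                f"X {X.shape} and y {y.shape} are not conformable"
            )
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise InvalidInputError("training data contain non-finite values")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ConfigError(f"gamma must be positive and finite, got {self.gamma}")
        m = X.shape[0]
        y_mean = float(np.mean(y)) if self.center_targets else 0.0
        yc = y - y_mean

        gram = rbf_kernel(X, X, self.sigma2)
        A = np.zeros((m + 1, m + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = gram + np.eye(m) / self.gamma
        rhs = np.concatenate([[0.0], yc])
        try:
            sol = scipy.linalg.solve(A, rhs, assume_a="sym")
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise NumericalError(
                "singular LS-SVR system; decrease gamma (larger ridge 1/gamma)"
            ) from exc
        if not np.all(np.isfinite(sol)):
            raise NumericalError(
                "LS-SVR solve produced non-finite coefficients; decrease gamma"
            )
        self.X_fit_ = X
        self.y_mean_ = y_mean
        self.b0_ = float(sol[0]) + y_mean
        self.b_ = sol[1:]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_fit_.shape[1]:
            raise InvalidInputError(
                f"expected {self.X_fit_.shape[1]} features, got {X.shape[1]}"
            )
        k = rbf_kernel(X, self.X_fit_, self.sigma2)
        return k @ self.b_ + self.b0_


def make_cv_folds(m: int, cv=None, random_state=None):
    """Materialise cross-validation folds as a list of (train, test) index arrays.

    ``cv`` may be None (leave-one-out for m <= 60, else seeded 10-fold), an
    integer fold count, or an explicit iterable of (train, test) pairs.
    """
    if cv is None:
        splitter = LeaveOneOut() if m <= LOO_MAX_SAMPLES else KFold(
            n_splits=10, shuffle=True, random_state=random_state
        )
        folds = list(splitter.split(np.empty((m, 1))))
    elif isinstance(cv, int):
        if not 2 <= cv <= m:
            raise ConfigError(f"fold count {cv} invalid for m={m}")
        splitter = KFold(n_splits=cv, shuffle=True, random_state=random_state)
        folds = list(splitter.split(np.empty((m, 1))))
    else:
        folds = [(np.asarray(tr, dtype=int), np.asarray(te, dtype=int)) for tr, te in cv]
    for tr, te in folds:
        if len(te) == m or len(tr) == 0:
            raise InvalidInputError("a CV fold holds out the entire sample set")
    return folds


def rmsecv(X, y, gamma: float, sigma2: float, cv=None, random_state=None,
           center_targets: bool = True) -> float:
    """Root mean square error of cross-validation for an LS-SVR model.

    Every fold is held out once, the model refit on the remainder, and the
    squared held-out residuals pooled before the root.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = make_cv_folds(X.shape[0], cv, random_state)
    sq = 0.0
    count = 0
    for tr, te in folds:
        model = LSSVR(gamma=gamma, sigma2=sigma2, center_targets=center_targets)
        model.fit(X[tr], y[tr])
        resid = y[te] - model.predict(X[te])
        sq += float(np.sum(resid**2))
        count += len(te)
    return float(np.sqrt(sq / count))
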