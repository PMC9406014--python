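"""PLS regression baseline with MCCV + F-test latent-variable selection.

Partial least squares is the workhorse linear calibration model the ensemble
method is compared against.  The number of latent variables (LVs) is chosen
by Monte Carlo cross-validation: RMSECV is estimated for every candidate rank
from repeated random train/validation splits, and an F-test then picks the
most parsimonious rank whose error is not significantly worse than the best
one (the Haaland-Thomas convention, alpha = 0.25 by default).
"""

from __future__ import annotations

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import ShuffleSplit

from .exceptions import ConfigError, InvalidInputError

__all__ = ["PLSCalibration", "fit_pls", "select_lv_mccv_ftest"]


class PLSCalibration(RegressorMixin, BaseEstimator):
    """Univariate-y PLS (NIPALS) with mean-centred X and y.

    Parameters
    ----------
    n_lv : int
        Number of latent variables; must not exceed ``min(m - 1, n)``.

    Attributes
    ----------
    coef_ : ndarray of shape (n,)
        Regression vector on the centred scale.
    x_scores_ : ndarray of shape (m, n_lv)
        Training scores (mutually orthogonal).
    x_mean_, y_mean_ : centring records.
    """

    def __init__(self, n_lv: int = 2):
        self.n_lv = n_lv

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise InvalidInputError(f"X {X.shape} and y {y.shape} not conformable")
        m, n = X.shape
        if not 1 <= self.n_lv <= min(m - 1, n):
            raise ConfigError(
                f"n_lv={self.n_lv} exceeds the rank bound min(m-1, n)={min(m - 1, n)}"
            )
        self._pls = PLSRegression(n_components=self.n_lv, scale=False)
        self._pls.fit(X, y)
        self.coef_ = self._pls.coef_.ravel()
        self.x_scores_ = self._pls.x_scores_
        self.x_loadings_ = self._pls.x_loadings_
        self.x_weights_ = self._pls.x_weights_
        self.x_mean_ = self._pls._x_mean
        self.y_mean_ = float(np.mean(y))
        self.n_features_in_ = n
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def fit_pls(X, y, n_lv: int) -> PLSCalibration:
    """Convenience wrapper: fit a :class:`PLSCalibration` with ``n_lv`` LVs."""
    return PLSCalibration(n_lv=n_lv).fit(X, y)


def select_lv_mccv_ftest(X, y, max_lv: int = 10, n_splits: int = 50,
                         split_frac: float = 0.2, alpha_f: float = 0.25,
                         random_state: int = 0):
    """Choose the PLS rank by MCCV RMSECV plus a parsimony F-test.

    For each candidate rank ``l`` the RMSECV is pooled over ``n_splits``
    random splits holding out ``split_frac`` of the samples (fixed seed).
    With ``l* = argmin RMSECV``, the returned rank is the smallest ``l``
    whose variance ratio ``RMSECV(l)^2 / RMSECV(l*)^2`` stays below the F
    critical value at level ``alpha_f`` with (h, h) degrees of freedom, h
    being the per-split hold-out count — i.e. the simplest model not
    significantly worse than the best.

    Returns ``(n_lv, rmsecv_curve)`` with the curve indexed 1..max_lv.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m, n = X.shape
    if max_lv < 1:
        raise ConfigError(f"max_lv must be >= 1, got {max_lv}")
    if n_splits < 2:
        raise ConfigError(f"n_splits must be >= 2, got {n_splits}")
    n_holdout = int(round(split_frac * m))
    n_fit = m - n_holdout
    if n_holdout < 1 or n_fit < 2:
        raise ConfigError(
            f"split_frac={split_frac} leaves degenerate splits for m={m}"
        )
    lv_cap = min(max_lv, n_fit - 1, n)
    if lv_cap < 1:
        raise ConfigError("no admissible latent-variable count for these splits")

    splitter = ShuffleSplit(n_splits=n_splits, test_size=n_holdout,
                            random_state=random_state)
    folds = list(splitter.split(X))
    curve = np.empty(lv_cap)
    for lv in range(1, lv_cap + 1):
        sq, count = 0.0, 0
        for tr, te in folds:
            model = PLSCalibration(n_lv=lv).fit(X[tr], y[tr])
            resid = y[te] - model.predict(X[te])
            sq += float(np.sum(resid**2))
            count += len(te)
        curve[lv - 1] = np.sqrt(sq / count)

    l_star = int(np.argmin(curve)) + 1
    crit = scipy.stats.f.ppf(1.0 - alpha_f, n_holdout, n_holdout)
    best_sq = curve[l_star - 1] ** 2
    for lv in range(1, l_star + 1):
        if best_sq > 0:
            ratio = curve[lv - 1] ** 2 / best_sq
        else:
            ratio = 1.0 if curve[lv - 1] == 0 else np.inf
        if ratio < crit:
            return lv, curve
    return l_star, curve
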