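"""Weighted multiscale SVR calibration on VMD mode matrices (VMD-WMSVR).

Every training spectrum is decomposed into ``K`` narrow-band modes; the k-th
mode of every sample is stacked into a mode matrix ``U_k`` of the same shape
as the training matrix.  One LS-SVR sub-model is fitted per ``U_k`` and the
sub-models' predictions are combined by a weighted average with weights
proportional to ``RMSECV_k^-4``: sub-models whose cross-validated error is
small (typically the low-frequency, composition-carrying modes) dominate,
while noisy high-frequency modes are strongly down-weighted by the fourth
power.

Because the decomposition runs per sample, modes are aligned across samples
by sorting on centre frequency, so "mode k" means the k-th frequency band for
every sample.  Prediction-set spectra are decomposed with the identical
configuration before the sub-models are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigError, InvalidInputError
from .lssvr import LSSVR, make_cv_folds
from .model_selection import rmsep
from .vmd import VMDConfig, vmd_decompose_batch

__all__ = [
    "ModeMatrixStack",
    "build_mode_matrices",
    "VMDWMSVR",
    "select_K",
    "DEFAULT_WEIGHT_POWER",
]

#: exponent of the inverse-RMSECV weighting law
DEFAULT_WEIGHT_POWER = 4.0


@dataclass
class ModeMatrixStack:
    """K mode matrices ``U_k`` (each m x n) plus per-sample centre frequencies."""

    U: list[np.ndarray]
    omegas: np.ndarray  # (m, K)
    cfg: VMDConfig

    @property
    def K(self) -> int:
        return len(self.U)

    @property
    def shape(self) -> tuple[int, int]:
        return self.U[0].shape


def build_mode_matrices(X: np.ndarray, cfg: VMDConfig) -> ModeMatrixStack:
    """Decompose each row of ``X`` and recombine mode k across samples into ``U_k``.

    Row i of ``U_k`` is the k-th (frequency-sorted) mode of sample i, so each
    ``U_k`` has the same number of samples and variables as ``X``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    modes, omegas, _, _ = vmd_decompose_batch(X, cfg)
    U = [np.ascontiguousarray(modes[:, k, :]) for k in range(cfg.K)]
    return ModeMatrixStack(U=U, omegas=omegas, cfg=cfg)


def combine_weights(errors: np.ndarray, power: float = DEFAULT_WEIGHT_POWER):
    """Normalised inverse-power weights, ``w_k ∝ errors_k^-power``.

    A zero error would blow up; such sub-models are treated as perfect and
    receive all the weight (shared if several), with a warning.
    """
    errors = np.asarray(errors, dtype=float)
    if np.any(errors < 0):
        raise InvalidInputError("RMSECV values must be nonnegative")
    if np.any(errors == 0.0):
        warnings.warn(
            "sub-model(s) with zero RMSECV receive all ensemble weight",
            stacklevel=2,
        )
        weights = (errors == 0.0).astype(float)
    else:
        weights = errors ** (-power)
    return weights / weights.sum()


class VMDWMSVR(RegressorMixin, BaseEstimator):
    """VMD-weighted multiscale LS-SVR ensemble regressor.

    Parameters
    ----------
    K : int
        Number of VMD modes (= number of sub-models).
    alpha, tau, tol, max_iter, omega_init, dc_mode, random_seed
        VMD solver settings; see :class:`vmdcal.vmd.VMDConfig`.
    gamma, sigma2 : float
        LS-SVR hyperparameters, shared by all K sub-models (one pair per
        calibration, as is customary for this method).
    weight_power : float
        Exponent p of the weighting law ``w_k ∝ RMSECV_k^-p`` (default 4).
    cv : None, int or iterable
        Cross-validation scheme for the sub-model RMSECVs; folds are shared
        across the K sub-models so the weights compare like with like.
        None = leave-one-out for m <= 60, else seeded 10-fold.
    random_state : int
        Seed for the CV shuffling (when applicable).

    Attributes
    ----------
    submodels_ : list of LSSVR
        One fitted sub-model per mode matrix.
    weights_ : ndarray of shape (K,)
        Normalised nonnegative weights, summing to 1.
    rmsecv_per_mode_ : ndarray of shape (K,)
        Cross-validated error of each sub-model on its own mode matrix.
    """

    def __init__(self, K: int = 5, alpha: float = 2000.0, tau: float = 0.0,
                 tol: float = 1e-7, max_iter: int = 500,
                 omega_init: str = "uniform", dc_mode: bool = False,
                 random_seed: int = 0, gamma: float = 100.0,
                 sigma2: float = 10.0, weight_power: float = DEFAULT_WEIGHT_POWER,
                 cv=None, random_state: int = 0):
        self.K = K
        self.alpha = alpha
        self.tau = tau
        self.tol = tol
        self.max_iter = max_iter
        self.omega_init = omega_init
        self.dc_mode = dc_mode
        self.random_seed = random_seed
        self.gamma = gamma
        self.sigma2 = sigma2
        self.weight_power = weight_power
        self.cv = cv
        self.random_state = random_state

    def _vmd_config(self) -> VMDConfig:
        return VMDConfig(K=self.K, alpha=self.alpha, tau=self.tau, tol=self.tol,
                         max_iter=self.max_iter, omega_init=self.omega_init,
                         random_seed=self.random_seed, dc_mode=self.dc_mode)

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise InvalidInputError(f"X {X.shape} and y {y.shape} not conformable")
        stack = build_mode_matrices(X, self._vmd_config())
        return self._fit_from_stack(stack, y)

    def _fit_from_stack(self, stack: ModeMatrixStack, y: np.ndarray):
        """Fit sub-models and weights given precomputed mode matrices.

        Exposed separately so model-selection loops can reuse one expensive
        decomposition across folds (rows of the stack slice independently).
        """
        y = np.asarray(y, dtype=float).ravel()
        m = stack.shape[0]
        folds = make_cv_folds(m, self.cv, self.random_state)

        submodels, errors = [], []
        for Uk in stack.U:
            model = LSSVR(gamma=self.gamma, sigma2=self.sigma2)
            model.fit(Uk, y)
            submodels.append(model)
            sq, count = 0.0, 0
            for tr, te in folds:
                sub = LSSVR(gamma=self.gamma, sigma2=self.sigma2)
                sub.fit(Uk[tr], y[tr])
                resid = y[te] - sub.predict(Uk[te])
                sq += float(np.sum(resid**2))
                count += len(te)
            errors.append(float(np.sqrt(sq / count)))

        errors = np.array(errors)
        weights = combine_weights(errors, self.weight_power)

        self.submodels_ = submodels
        self.rmsecv_per_mode_ = errors
        self.weights_ = weights
        self.n_features_in_ = stack.shape[1]
        self.train_omegas_ = stack.omegas
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        stack = build_mode_matrices(X, self._vmd_config())
        return self._predict_from_stack(stack)

    def _predict_from_stack(self, stack: ModeMatrixStack) -> np.ndarray:
        preds = np.stack(
            [model.predict(Uk) for model, Uk in zip(self.submodels_, stack.U)]
        )
        return self.weights_ @ preds


def select_K(X_train, y_train, K_range, *, X_val=None, y_val=None,
             cv=5, random_state: int = 0, **wmsvr_params):
    """Scan the mode number K and return the argmin of the error curve.

    For each K an ensemble is fitted and scored either on a held-out
    validation set (``X_val``/``y_val`` given — the protocol that scans the
    prediction set directly, provided for fidelity with historical practice
    but leaky) or by outer cross-validation on the training set (default,
    leak-free).  Ties are broken toward the smaller K.

    Returns ``(K_star, curve)`` where ``curve`` maps each K to its error.
    """
    K_range = [int(k) for k in K_range]
    if len(K_range) == 0:
        raise InvalidInputError("empty K_range")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    n = X_train.shape[1]
    for K in K_range:
        if not 1 <= K <= n // 2:
            raise ConfigError(f"K={K} outside [1, {n // 2}]")

    use_holdout = X_val is not None
    if use_holdout:
        X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
        y_val = np.asarray(y_val, dtype=float).ravel()

    curve: dict[int, float] = {}
    for K in sorted(K_range):
        est = VMDWMSVR(K=K, random_state=random_state, **wmsvr_params)
        if use_holdout:
            est.fit(X_train, y_train)
            curve[K] = rmsep(y_val, est.predict(X_val))
        else:
            stack = build_mode_matrices(X_train, est._vmd_config())
            folds = make_cv_folds(len(y_train), cv, random_state)
            sq, count = 0.0, 0
            for tr, te in folds:
                inner = VMDWMSVR(K=K, random_state=random_state, **wmsvr_params)
                sub_stack = ModeMatrixStack(
                    U=[Uk[tr] for Uk in stack.U],
                    omegas=stack.omegas[tr], cfg=stack.cfg,
                )
                inner._fit_from_stack(sub_stack, y_train[tr])
                te_stack = ModeMatrixStack(
                    U=[Uk[te] for Uk in stack.U],
                    omegas=stack.omegas[te], cfg=stack.cfg,
                )
                resid = y_train[te] - inner._predict_from_stack(te_stack)
                sq += float(np.sum(resid**2))
                count += len(te)
            curve[K] = float(np.sqrt(sq / count))

    K_star = min(curve, key=lambda k: (curve[k], k))
    return K_star, curve
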