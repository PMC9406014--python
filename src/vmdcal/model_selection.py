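"""Sample partitioning, hyperparameter search and evaluation metrics.

Kennard-Stone picks a training set that spans the spectral space by greedy
max-min Euclidean distance; particle swarm optimisation (PSO) tunes the
LS-SVR pair (gamma, sigma2) on a log10 grid; RMSEP and Pearson R are the
figures of merit used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "SplitResult",
    "kennard_stone",
    "PSOConfig",
    "PSOResult",
    "pso_optimize",
    "rmsep",
    "rmse",
    "pearson_r",
]


class SplitResult(NamedTuple):
    train_indices: np.ndarray
    test_indices: np.ndarray


def kennard_stone(X: np.ndarray, n_train: int) -> SplitResult:
    """Kennard-Stone train/prediction split.

    Starts from the two most distant samples, then repeatedly adds the sample
    whose minimum distance to the selected set is largest (ties broken by the
    lowest row index).  Deterministic: no randomness is involved.

    Parameters
    ----------
    X : array of shape (m, n)
        Sample matrix; distances are Euclidean on the raw rows.
    n_train : int
        Training-set size, 2 <= n_train <= m.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    if not 2 <= n_train <= m:
        raise ConfigError(f"n_train={n_train} outside [2, {m}]")
    D = cdist(X, X)
    if np.all(D == 0) and m > 1:
        warnings.warn(
            "all samples identical; Kennard-Stone selection is arbitrary "
            "(taking the lowest indices)",
            stacklevel=2,
        )
    # farthest pair, lexicographically smallest on ties
    iu = np.triu_indices(m, k=1)
    if len(iu[0]) == 0:
        selected = [0]
    else:
        flat = D[iu]
        best = int(np.argmax(flat))  # argmax returns the first max: lowest (i, j)
        selected = [int(iu[0][best]), int(iu[1][best])]
    remaining = np.setdiff1d(np.arange(m), selected)
    mindist = D[remaining][:, selected].min(axis=1) if len(remaining) else None
    while len(selected) < n_train:
        pick = int(np.argmax(mindist))  # first occurrence = lowest index on ties
        selected.append(int(remaining[pick]))
        remaining = np.delete(remaining, pick)
        mindist = np.delete(mindist, pick)
        if len(remaining):
            mindist = np.minimum(mindist, D[remaining, selected[-1]])
    train = np.array(selected, dtype=int)
    test = np.setdiff1d(np.arange(m), train)
    return SplitResult(train, test)


@dataclass(frozen=True)
class PSOConfig:
    """Global-best PSO settings.

    ``bounds`` is a sequence of (low, high) per dimension; dimensions flagged
    in ``log_scale`` are searched on a log10 grid (bounds given in the
    original units).  Inertia decays linearly from ``inertia[0]`` to
    ``inertia[1]`` over the run.
    """

    bounds: Sequence[tuple[float, float]]
    swarm_size: int = 20
    n_iter: int = 50
    inertia: tuple[float, float] = (0.9, 0.4)
    c1: float = 2.0
    c2: float = 2.0
    log_scale: Sequence[bool] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigError(f"invalid bound ({lo}, {hi})")
        if self.swarm_size < 2 or self.n_iter < 1:
            raise ConfigError("swarm_size >= 2 and n_iter >= 1 required")
        if self.log_scale is not None and len(self.log_scale) != len(self.bounds):
            raise ConfigError("log_scale must match bounds in length")


class PSOResult(NamedTuple):
    best_params: np.ndarray
    best_value: float
    trace: np.ndarray  # best-so-far objective value after each iteration


def pso_optimize(objective: Callable[[np.ndarray], float], cfg: PSOConfig) -> PSOResult:
    """Minimise ``objective`` over the box with global-best PSO.

    Velocities are clamped to the box width and positions clipped to the
    bounds; a non-finite objective value marks that particle position as
    infeasible (+inf) and the search continues.  Fully deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = len(cfg.bounds)
    log_mask = np.asarray(cfg.log_scale if cfg.log_scale is not None else [False] * d)
    lo = np.array([b[0] for b in cfg.bounds], dtype=float)
    hi = np.array([b[1] for b in cfg.bounds], dtype=float)
    if np.any(log_mask & (lo <= 0)):
        raise ConfigError("log-scale dimensions require positive bounds")
    lo_s = np.where(log_mask, np.log10(np.where(log_mask, lo, 1.0)), lo)
    hi_s = np.where(log_mask, np.log10(np.where(log_mask, hi, 1.0)), hi)
    width = hi_s - lo_s

    def to_user(p):
        return np.where(log_mask, 10.0**p, p)

    def evaluate(p):
        v = objective(to_user(p))
        return float(v) if np.isfinite(v) else np.inf

    pos = lo_s + rng.random((cfg.swarm_size, d)) * width
    vel = (rng.random((cfg.swarm_size, d)) - 0.5) * width
    pbest = pos.copy()
    pbest_val = np.array([evaluate(p) for p in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    trace = np.empty(cfg.n_iter)
    w0, w1 = cfg.inertia
    for it in range(cfg.n_iter):
        w = w0 + (w1 - w0) * (it / max(cfg.n_iter - 1, 1))
        r1 = rng.random((cfg.swarm_size, d))
        r2 = rng.random((cfg.swarm_size, d))
        vel = w * vel + cfg.c1 * r1 * (pbest - pos) + cfg.c2 * r2 * (gbest - pos)
        vel = np.clip(vel, -width, width)
        pos = np.clip(pos + vel, lo_s, hi_s)
        vals = np.array([evaluate(p) for p in pos])
        improved = vals < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        trace[it] = gbest_val
    return PSOResult(to_user(gbest), gbest_val, trace)


def rmsep(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error of prediction, sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise InvalidInputError("rmsep requires equal, nonzero lengths")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


#: generic RMSE used when aggregating cross-validation residuals
rmse = rmsep


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation between prepared and predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2 or y.shape != yhat.shape:
        raise InvalidInputError("pearson_r requires equal lengths >= 2")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise InvalidInputError("correlation undefined for zero-variance input")
    return float(pearsonr(y, yhat).statistic)
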