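"""End-to-end calibration experiment: data -> split -> tune -> train -> report.

``run_experiment`` wires the full workflow behind one flat, namespaced
configuration: simulate (or load) spectra, Kennard-Stone split, optional PSO
tuning of (gamma, sigma2), optional mode-number scan, training of the PLS /
LSSVR / VMD-WMSVR models, and RMSEP + R evaluation on the prediction set.
Every run is deterministic under its seed and writes the fully resolved
configuration next to its outputs, so any artifact on disk is regenerable.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import fit_pls, select_lv_mccv_ftest
from .ensemble import VMDWMSVR, select_K
from .exceptions import ConfigError
from .io import SpectralDataset, read_spectra, read_targets, write_spectra, write_targets
from .lssvr import LSSVR, rmsecv
from .model_selection import PSOConfig, kennard_stone, pearson_r, pso_optimize, rmsep
from .synthetic import make_library, sample_fractions, synthesize

logger = logging.getLogger("vmdcal")

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_experiment"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    # data: "simulate" or "load"
    "data.source": "simulate",
    "data.spectra": None,
    "data.targets": None,
    "simulate.preset": "nir_herb_like",
    "simulate.m": 75,
    "simulate.scheme": "dirichlet",
    "simulate.target_component": 0,
    "simulate.noise_sd": 0.002,
    "simulate.baseline_amp": 0.01,
    "simulate.nonlinearity": 0.3,
    "ks.train_size": 50,
    "vmd.K": 5,
    "vmd.alpha": 2000.0,
    "vmd.tau": 0.0,
    "vmd.tol": 1e-7,
    "vmd.max_iter": 500,
    "vmd.dc_mode": False,
    "svr.gamma": 100.0,
    "svr.sigma2": 10.0,
    "svr.weight_power": 4.0,
    # cross-validation: "auto" = LOO up to 60 samples, else seeded 10-fold;
    # an integer selects seeded k-fold
    "cv.scheme": "auto",
    "tune.enabled": False,
    # "rmsecv" is leak-free; "rmsep" scores the prediction set directly
    # (historical protocol, leaks the test set into model selection)
    "tune.objective": "rmsecv",
    "pso.swarm_size": 20,
    "pso.n_iter": 50,
    "pso.c1": 2.0,
    "pso.c2": 2.0,
    "pso.inertia_start": 0.9,
    "pso.inertia_end": 0.4,
    "pso.log_low": 1e-2,
    "pso.log_high": 1e4,
    "select_k.enabled": False,
    "select_k.kmin": 2,
    "select_k.kmax": 9,
    "select_k.scan_prediction_set": False,
    "pls.max_lv": 10,
    "methods.pls": True,
    "methods.lssvr": True,
    "methods.wmsvr": True,
}


def resolve_config(overrides: dict | None = None) -> dict:
    """Merge ``overrides`` into the defaults, rejecting unknown keys."""
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(overrides or ()) - set(cfg)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides or {})
    return cfg


def _cv_arg(cfg):
    scheme = cfg["cv.scheme"]
    if scheme == "auto":
        return None
    if scheme == "loo":
        return None  # LOO is the auto behaviour at calibration sizes
    if isinstance(scheme, int):
        return scheme
    raise ConfigError(f"cv.scheme must be 'auto', 'loo' or an int, got {scheme!r}")


def _get_data(cfg):
    if cfg["data.source"] == "load":
        ds = read_spectra(cfg["data.spectra"])
        y = read_targets(cfg["data.targets"], ids=ds.ids)
        return ds, y
    if cfg["data.source"] != "simulate":
        raise ConfigError(f"data.source must be 'simulate' or 'load'")
    lib = make_library(cfg["simulate.preset"], seed=0)
    design = sample_fractions(
        cfg["simulate.m"], lib.n_components, scheme=cfg["simulate.scheme"],
        seed=cfg["seed"], target_component=cfg["simulate.target_component"],
    )
    X, y = synthesize(
        lib, design, noise_sd=cfg["simulate.noise_sd"],
        baseline_amp=cfg["simulate.baseline_amp"],
        nonlinearity=cfg["simulate.nonlinearity"], seed=cfg["seed"],
    )
    ds = SpectralDataset(X=X, axis=lib.axis, ids=[f"s{i:03d}" for i in range(len(y))])
    return ds, y


def run_experiment(config: dict | None = None, out_dir=None):
    """Run the full workflow; returns ``(report, artifacts)``.

    ``report`` is a DataFrame with one row per method (RMSEP and R on the
    prediction set); ``artifacts`` carries the resolved config, split
    indices, fitted models and, when enabled, the tuning trace and the
    error-vs-K curve.  When ``out_dir`` is given, the report, the curve and
    the resolved config are also written there as CSV/JSON.
    """
    cfg = resolve_config(config)
    t0 = time.time()
    ds, y = _get_data(cfg)
    logger.info("data: %d samples x %d points (%.2fs)", *ds.X.shape, time.time() - t0)

    split = kennard_stone(ds.X, cfg["ks.train_size"])
    Xtr, ytr = ds.X[split.train_indices], y[split.train_indices]
    Xte, yte = ds.X[split.test_indices], y[split.test_indices]
    cv = _cv_arg(cfg)
    seed = cfg["seed"]

    gamma, sigma2 = cfg["svr.gamma"], cfg["svr.sigma2"]
    artifacts = {"config": cfg, "split": split}

    if cfg["tune.enabled"]:
        t0 = time.time()
        pso_cfg = PSOConfig(
            bounds=[(cfg["pso.log_low"], cfg["pso.log_high"])] * 2,
            swarm_size=cfg["pso.swarm_size"], n_iter=cfg["pso.n_iter"],
            inertia=(cfg["pso.inertia_start"], cfg["pso.inertia_end"]),
            c1=cfg["pso.c1"], c2=cfg["pso.c2"], log_scale=[True, True], seed=seed,
        )
        if cfg["tune.objective"] == "rmsecv":
            def objective(p):
                return rmsecv(Xtr, ytr, p[0], p[1], cv=cv, random_state=seed)
        elif cfg["tune.objective"] == "rmsep":
            def objective(p):
                model = LSSVR(gamma=p[0], sigma2=p[1]).fit(Xtr, ytr)
                return rmsep(yte, model.predict(Xte))
        else:
            raise ConfigError(f"unknown tune.objective {cfg['tune.objective']!r}")
        result = pso_optimize(objective, pso_cfg)
        gamma, sigma2 = result.best_params
        artifacts["tune"] = result
        logger.info("tuned gamma=%.4g sigma2=%.4g (%.2fs)", gamma, sigma2,
                    time.time() - t0)

    vmd_kwargs = dict(alpha=cfg["vmd.alpha"], tau=cfg["vmd.tau"], tol=cfg["vmd.tol"],
                      max_iter=cfg["vmd.max_iter"], dc_mode=cfg["vmd.dc_mode"])
    K = cfg["vmd.K"]
    if cfg["select_k.enabled"]:
        t0 = time.time()
        K_range = range(cfg["select_k.kmin"], cfg["select_k.kmax"] + 1)
        if cfg["select_k.scan_prediction_set"]:
            K, curve = select_K(Xtr, ytr, K_range, X_val=Xte, y_val=yte,
                                gamma=gamma, sigma2=sigma2, random_state=seed,
                                **vmd_kwargs)
        else:
            K, curve = select_K(Xtr, ytr, K_range, cv=5, gamma=gamma, sigma2=sigma2,
                                random_state=seed, **vmd_kwargs)
        artifacts["k_curve"] = curve
        logger.info("selected K=%d (%.2fs)", K, time.time() - t0)

    rows = []
    if cfg["methods.pls"]:
        t0 = time.time()
        n_lv, lv_curve = select_lv_mccv_ftest(Xtr, ytr, max_lv=cfg["pls.max_lv"],
                                              random_state=seed)
        pls = fit_pls(Xtr, ytr, n_lv)
        p = pls.predict(Xte)
        rows.append(("PLS", rmsep(yte, p), pearson_r(yte, p)))
        artifacts["pls"] = pls
        artifacts["pls_lv"] = n_lv
        logger.info("PLS (LV=%d) done (%.2fs)", n_lv, time.time() - t0)
    if cfg["methods.lssvr"]:
        t0 = time.time()
        svr = LSSVR(gamma=gamma, sigma2=sigma2).fit(Xtr, ytr)
        p = svr.predict(Xte)
        rows.append(("LSSVR", rmsep(yte, p), pearson_r(yte, p)))
        artifacts["lssvr"] = svr
        logger.info("LSSVR done (%.2fs)", time.time() - t0)
    if cfg["methods.wmsvr"]:
        t0 = time.time()
        wmsvr = VMDWMSVR(K=K, gamma=gamma, sigma2=sigma2, cv=cv,
                         weight_power=cfg["svr.weight_power"], random_state=seed,
                         **vmd_kwargs)
        wmsvr.fit(Xtr, ytr)
        p = wmsvr.predict(Xte)
        rows.append(("VMD-WMSVR", rmsep(yte, p), pearson_r(yte, p)))
        artifacts["wmsvr"] = wmsvr
        logger.info("VMD-WMSVR (K=%d) done (%.2fs)", K, time.time() - t0)

    report = pd.DataFrame(rows, columns=["method", "RMSEP", "R"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv", index=False)
        resolved = dict(cfg, **{"vmd.K": int(K), "svr.gamma": float(gamma),
                                "svr.sigma2": float(sigma2)})
        (out / "config.json").write_text(json.dumps(resolved, indent=2, default=str))
        if "k_curve" in artifacts:
            pd.DataFrame(
                sorted(artifacts["k_curve"].items()), columns=["K", "error"]
            ).to_csv(out / "k_curve.csv", index=False)
    return report, artifacts
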