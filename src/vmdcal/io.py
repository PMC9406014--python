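"""Delimited-text I/O for spectra, targets, predictions and model containers.

Spectra travel as CSV with a numeric abscissa header (wavelengths in nm or
wavenumbers in cm^-1) and one sample per row, first column the sample id.
Targets are two-column CSV (id, target).  Models serialise to JSON; a
ModeSet serialises to a two-block delimited text file (mode matrix, then
centre frequencies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import PLSCalibration
from .ensemble import VMDWMSVR
from .exceptions import FormatError
from .lssvr import LSSVR
from .vmd import ModeSet

__all__ = [
    "SpectralDataset",
    "read_spectra",
    "write_spectra",
    "read_targets",
    "write_targets",
    "write_predictions",
    "save_model",
    "load_model",
    "write_modeset",
    "read_modeset",
]


@dataclass
class SpectralDataset:
    """In-memory spectra: ``X`` (m x n), abscissa ``axis`` (n,), sample ``ids``."""

    X: np.ndarray
    axis: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.diff(self.axis)
        if len(self.axis) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError("spectral axis must be strictly monotonic")
        if self.X.shape != (len(self.ids), len(self.axis)):
            raise FormatError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.ids)} ids x {len(self.axis)} axis points"
            )


def read_spectra(path) -> SpectralDataset:
    """Read a spectra CSV (id column + numeric axis header)."""
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    try:
        axis = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"non-numeric axis header in {path}: {exc}") from exc
    X = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(X).any():
        rows = df.index[np.isnan(X).any(axis=1)].tolist()
        raise FormatError(f"non-numeric or missing cells in rows {rows} of {path}")
    return SpectralDataset(X=X, axis=axis, ids=[str(i) for i in df.index])


def write_spectra(path, ds: SpectralDataset) -> None:
    df = pd.DataFrame(ds.X, index=ds.ids, columns=[repr(float(v)) for v in ds.axis])
    df.index.name = "id"
    df.to_csv(path)  # default float repr is shortest-exact: lossless round-trip


def read_targets(path, ids: list[str] | None = None) -> np.ndarray:
    """Read targets CSV (id, value); if ``ids`` given, align and validate."""
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] != 1:
        raise FormatError(f"{path} must have exactly two columns (id, target)")
    df.index = df.index.map(str)
    y = df.iloc[:, 0]
    if ids is not None:
        missing = [i for i in ids if i not in df.index]
        if missing:
            raise FormatError(f"ids missing from {path}: {missing}")
        y = y.loc[ids]
    try:
        return y.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric target in {path}: {exc}") from exc


def write_targets(path, ids, y, column: str = "target") -> None:
    df = pd.DataFrame({column: np.asarray(y)}, index=list(ids))
    df.index.name = "id"
    df.to_csv(path)


#: predictions share the target layout with a "predicted" column
def write_predictions(path, ids, yhat) -> None:
    write_targets(path, ids, yhat, column="predicted")


def _arr(x):
    return np.asarray(x).tolist()


def save_model(path, model) -> None:
    """Serialise a fitted LSSVR, VMDWMSVR or PLSCalibration to JSON."""
    if isinstance(model, LSSVR):
        doc = {
            "kind": "lssvr",
            "params": model.get_params(),
            "b": _arr(model.b_),
            "b0": model.b0_,
            "y_mean": model.y_mean_,
            "X_train": _arr(model.X_fit_),
        }
    elif isinstance(model, VMDWMSVR):
        doc = {
            "kind": "vmd_wmsvr",
            "params": {k: v for k, v in model.get_params().items() if k != "cv"},
            "cv": model.cv if isinstance(model.cv, (int, type(None))) else None,
            "weights": _arr(model.weights_),
            "rmsecv_per_mode": _arr(model.rmsecv_per_mode_),
            "train_omegas": _arr(model.train_omegas_),
            "submodels": [
                {
                    "b": _arr(s.b_),
                    "b0": s.b0_,
                    "y_mean": s.y_mean_,
                    "X_train": _arr(s.X_fit_),
                    "params": s.get_params(),
                }
                for s in model.submodels_
            ],
        }
    elif isinstance(model, PLSCalibration):
        doc = {
            "kind": "pls",
            "params": model.get_params(),
            "coef": _arr(model.coef_),
            "x_mean": _arr(model.x_mean_),
            "y_mean": model.y_mean_,
        }
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    Path(path).write_text(json.dumps(doc))


def _load_lssvr(doc) -> LSSVR:
    model = LSSVR(**doc["params"])
    model.X_fit_ = np.asarray(doc["X_train"], dtype=float)
    model.b_ = np.asarray(doc["b"], dtype=float)
    model.b0_ = float(doc["b0"])
    model.y_mean_ = float(doc["y_mean"])
    model.n_features_in_ = model.X_fit_.shape[1]
    return model


def load_model(path):
    """Inverse of :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "lssvr":
        return _load_lssvr(doc)
    if kind == "vmd_wmsvr":
        model = VMDWMSVR(**doc["params"], cv=doc.get("cv"))
        model.submodels_ = [_load_lssvr(s) for s in doc["submodels"]]
        model.weights_ = np.asarray(doc["weights"], dtype=float)
        model.rmsecv_per_mode_ = np.asarray(doc["rmsecv_per_mode"], dtype=float)
        model.train_omegas_ = np.asarray(doc["train_omegas"], dtype=float)
        model.n_features_in_ = model.submodels_[0].X_fit_.shape[1]
        return model
    if kind == "pls":
        model = PLSCalibration(**doc["params"])
        model.coef_ = np.asarray(doc["coef"], dtype=float)
        model.x_mean_ = np.asarray(doc["x_mean"], dtype=float)
        model.y_mean_ = float(doc["y_mean"])
        model.n_features_in_ = model.coef_.shape[0]
        return model
    raise FormatError(f"unknown model kind {kind!r} in {path}")


def write_modeset(path, ms: ModeSet) -> None:
    """Two-block text container: '# modes' matrix block, '# omegas' vector block."""
    with open(path, "w") as fh:
        fh.write("# modes\n")
        np.savetxt(fh, ms.modes, fmt="%.12g", delimiter=",")
        fh.write("# omegas\n")
        np.savetxt(fh, ms.omegas[None, :], fmt="%.12g", delimiter=",")


def read_modeset(path) -> ModeSet:
    text = Path(path).read_text().splitlines()
    try:
        i_modes = text.index("# modes")
        i_om = text.index("# omegas")
    except ValueError as exc:
        raise FormatError(f"{path} is not a ModeSet container") from exc
    modes = np.array(
        [[float(v) for v in line.split(",")] for line in text[i_modes + 1 : i_om]]
    )
    omegas = np.array([float(v) for v in text[i_om + 1].split(",")])
    return ModeSet(modes=modes, omegas=omegas, n_iterations=0, converged=True)
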