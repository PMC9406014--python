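"""Synthetic adulterated-mixture spectra with known component fractions.

Real calibration sets for adulterant quantification (blended edible oils
measured by UV-Vis, powdered herbs by NIR) are rarely shared, so every stage
of the pipeline is exercised on simulated analogues instead.  The generator
follows Beer-Lambert mixing: a library of smooth, overlapping pure-component
band profiles is combined linearly with mixture fractions that sum to 100%,
then optionally corrupted with

* a saturation nonlinearity ``x -> (1 - exp(-beta x)) / beta`` mimicking
  detector response / Beer-law departure at high absorbance,
* a random cubic-polynomial baseline per sample (drift), and
* heteroscedastic Gaussian noise with sd proportional to ``0.5 + |x|``.

Two presets mirror common instrument settings: ``uvvis_oil_like`` (6
components on a 380-800 nm grid at 1 nm) and ``nir_herb_like`` (4 components
on a 12,000-4,000 cm^-1 grid, 8 cm^-1 spacing, with the informative bands
concentrated below 8,000 cm^-1 as is typical of NIR overtone regions).
Targets are expressed as mass-percent (0-100) of a designated component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "ComponentLibrary",
    "MixtureDesign",
    "make_library",
    "sample_fractions",
    "synthesize",
    "benchmark_dataset",
    "BENCHMARK_DEFAULTS",
]


@dataclass
class ComponentLibrary:
    """Pure-component band profiles on a common abscissa.

    ``pure_spectra`` is ``(c, n)``, nonnegative, each row peak-normalised
    to 1.
    """

    axis: np.ndarray
    pure_spectra: np.ndarray
    names: list[str]

    @property
    def n_components(self) -> int:
        return self.pure_spectra.shape[0]


@dataclass
class MixtureDesign:
    """Mixture fractions on the simplex (rows sum to 1) plus the target index."""

    fractions: np.ndarray  # (m, c)
    target_component: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2 or np.any(f < -1e-12):
            raise InvalidInputError("fractions must be a nonnegative m x c matrix")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("each fraction row must sum to 1")
        self.fractions = f


def _gaussian_bands(axis, centers, widths, amps):
    x = axis[None, :]
    g = amps[:, None] * np.exp(-0.5 * ((x - centers[:, None]) / widths[:, None]) ** 2)
    return g.sum(axis=0)


def make_library(preset: str = "nir_herb_like", seed: int = 0) -> ComponentLibrary:
    """Build a preset component library.

    ``uvvis_oil_like``: 6 components on 380..800 nm (421 points), each a sum
    of 2-4 Gaussian bands of width 10-60 nm.  ``nir_herb_like``: 4 components
    on 12,000..4,000 cm^-1 (1001 points, descending), broad overtone-like
    bands mostly below 8,000 cm^-1 plus a weak high-wavenumber shoulder.
    Profiles are nonnegative and peak-normalised; fixed seed -> identical
    library.
    """
    rng = np.random.default_rng(seed)
    if preset == "uvvis_oil_like":
        axis = np.arange(380.0, 801.0, 1.0)
        # chemically related oils share a broad absorption plateau; each adds
        # one or two narrower marker bands near its own spectral home.  The
        # marker variance is pinned to half the plateau variance so profiles
        # overlap strongly yet stay distinguishable.
        plateau = _gaussian_bands(
            axis, np.array([470.0, 570.0, 670.0]), np.full(3, 60.0), np.ones(3)
        )
        homes = np.linspace(450.0, 730.0, 6)
        profiles = []
        for i in range(6):
            nb = int(rng.integers(1, 3))
            centers = homes[i] + rng.uniform(-10.0, 10.0, nb)
            marker = _gaussian_bands(axis, centers, rng.uniform(15.0, 30.0, nb),
                                     rng.uniform(0.5, 1.0, nb))
            marker *= np.sqrt(0.5 * plateau.var() / marker.var())
            profiles.append(plateau + marker)
        names = [f"oil_{i + 1}" for i in range(6)]
    elif preset == "nir_herb_like":
        axis = np.linspace(12000.0, 4000.0, 1001)
        profiles = []
        for _ in range(4):
            nb = int(rng.integers(3, 6))
            centers = rng.uniform(4200.0, 7800.0, nb)
            widths = rng.uniform(150.0, 500.0, nb)
            amps = rng.uniform(0.4, 1.0, nb)
            prof = _gaussian_bands(axis, centers, widths, amps)
            # weak broad shoulder above 8000 cm^-1, common to overtone spectra
            prof += _gaussian_bands(
                axis,
                rng.uniform(8500.0, 11000.0, 1),
                rng.uniform(600.0, 1200.0, 1),
                rng.uniform(0.05, 0.15, 1),
            )
            profiles.append(prof)
        names = [f"herb_{i + 1}" for i in range(4)]
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    S = np.vstack(profiles)
    S = S / S.max(axis=1, keepdims=True)
    return ComponentLibrary(axis=axis, pure_spectra=S, names=names)


def sample_fractions(m: int, c: int, scheme: str = "dirichlet", seed: int = 0,
                     target_component: int = 0) -> MixtureDesign:
    """Draw ``m`` mixture rows over ``c`` components.

    ``dirichlet``: uniform on the simplex (concentration 1).  ``grid``: the
    target component is swept evenly 0 -> 1 (51 samples give the classic
    0, 2, ..., 100% design) with the remainder split evenly among the
    others.
    """
    if m < 1 or c < 2:
        raise ConfigError(f"need m >= 1 and c >= 2, got m={m}, c={c}")
    if not 0 <= target_component < c:
        raise ConfigError(f"target_component {target_component} outside [0, {c})")
    if scheme == "dirichlet":
        rng = np.random.default_rng(seed)
        F = rng.dirichlet(np.ones(c), size=m)
    elif scheme == "grid":
        t = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        F = np.empty((m, c))
        F[:, target_component] = t
        rest = (1.0 - t) / (c - 1)
        for j in range(c):
            if j != target_component:
                F[:, j] = rest
    else:
        raise ConfigError(f"unknown scheme {scheme!r}")
    return MixtureDesign(fractions=F, target_component=target_component)


def synthesize(lib: ComponentLibrary, design: MixtureDesign,
               noise_sd: float = 0.0, baseline_amp: float = 0.0,
               nonlinearity: float = 0.0, seed: int = 0):
    """Render spectra ``X`` and targets ``y`` (mass-% of the target component).

    ``X = F S`` (fractions times pure spectra), then the saturation
    nonlinearity with ``beta = 3 * nonlinearity`` (beta -> 0 recovers exact
    linearity), a per-sample random cubic baseline scaled by
    ``baseline_amp``, and heteroscedastic noise ``sd = noise_sd * (0.5 + |x|)``.
    """
    if not 0.0 <= nonlinearity < 1.0:
        raise ConfigError(f"nonlinearity must be in [0, 1), got {nonlinearity}")
    F = design.fractions
    S = lib.pure_spectra
    if F.shape[1] != S.shape[0]:
        raise InvalidInputError(
            f"design has {F.shape[1]} components, library {S.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    X = F @ S
    beta = 3.0 * nonlinearity
    if beta > 0:
        X = (1.0 - np.exp(-beta * X)) / beta
    m, n = X.shape
    if baseline_amp > 0:
        s = np.linspace(-1.0, 1.0, n)
        coeffs = rng.standard_normal((m, 4))
        basis = np.vander(s, 4, increasing=True)  # 1, s, s^2, s^3
        X = X + baseline_amp * coeffs @ basis.T
    if noise_sd > 0:
        X = X + rng.standard_normal((m, n)) * noise_sd * (0.5 + np.abs(X))
    y = 100.0 * F[:, design.target_component]
    return X, y


#: study conditions of the default end-to-end benchmark (NIR-herb-like,
#: 75 samples, mild nonlinearity): the substrate for method comparisons.
BENCHMARK_DEFAULTS = dict(
    preset="nir_herb_like",
    m=75,
    noise_sd=0.002,
    baseline_amp=0.01,
    nonlinearity=0.3,
)


def benchmark_dataset(seed: int = 0, m: int | None = None):
    """Generate the default nonlinear mixture benchmark.

    Returns ``(X, y, lib)`` for ``m`` samples (default 75) drawn uniformly on
    the simplex over the 4 NIR-herb-like components, with the default
    corruption levels of :data:`BENCHMARK_DEFAULTS`.
    """
    p = BENCHMARK_DEFAULTS
    m = p["m"] if m is None else m
    lib = make_library(p["preset"], seed=0)
    design = sample_fractions(m, lib.n_components, scheme="dirichlet", seed=seed)
    X, y = synthesize(lib, design, noise_sd=p["noise_sd"],
                      baseline_amp=p["baseline_amp"],
                      nonlinearity=p["nonlinearity"], seed=seed)
    return X, y, lib
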