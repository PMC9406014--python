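# Methods

## The calibration problem

A calibration set consists of `m` absorbance spectra (rows of `X`, sampled
on a wavelength or wavenumber grid of `n` points) and a scalar target per
sample, here the mass fraction of one mixture component in percent (0–100).
The task is to predict that fraction for new spectra.  Typical laboratory
sets are small (tens of samples) and the spectra are smooth, strongly
overlapping mixtures of component bands, possibly corrupted by baseline
drift, detector noise and mild departures from Beer–Lambert linearity.

## Variational mode decomposition

VMD models a signal as `K` amplitude/frequency-modulated components, each
narrow-band around an unknown centre frequency `ω_k`, found by minimising
the total bandwidth of the modes' analytic signals subject to the modes
summing to the input.  The augmented-Lagrangian saddle point is found by
ADMM in the frequency domain:

* mode update — a Wiener filter centred on `ω_k`:
  `û_k ← (x̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)`;
* frequency update — the power-weighted mean frequency of the mode over the
  nonnegative half-axis: `ω_k ← Σ_ω ω|û_k|² / Σ_ω |û_k|²`;
* multiplier update — dual ascent `λ̂ ← λ̂ + τ(x̂ − Σ_k û_k)`;
* stop when `Σ_k ‖û_k^{new} − û_k^{old}‖²/‖û_k^{old}‖² < tol` or at
  `max_iter`.

Parameters (defaults):

| parameter | default | meaning |
| --- | --- | --- |
| `K` | 5 | number of modes; bounded by `n/2` (over-decomposition guard) |
| `alpha` | 2000 | bandwidth penalty; larger → narrower modes |
| `tau` | 0 | dual step; 0 drops exact reconstruction, tolerating noise |
| `tol` | 1e-7 | relative convergence tolerance |
| `max_iter` | 500 | iteration cap |
| `omega_init` | uniform | centres spread over [0, 0.5) cycles/sample |
| `dc_mode` | false | pin `ω_1 = 0` to make mode 1 a baseline tracker |

Frequencies are in cycles/sample, so the physical abscissa (nm vs cm⁻¹)
only labels output.  With `tau = 0` the fixed-point residual at frequency
`ω` is `x̂(ω)/(1 + Σ_k 1/(2α(ω−ω_k)²))`: zero at every centre frequency and
negligible wherever the signal has structure near some mode, which is why
summed modes reconstruct smooth spectra to well under the 5% relative-L2
bound the tests assert.

Boundary effects are suppressed by half-length mirroring before the FFT
(the reversed first half prepended, the reversed second half appended) and
exact centre-cropping afterwards.  Modes are sorted by ascending centre
frequency before return so that "mode k" is comparable across samples.

Decomposing a sample matrix runs all rows through the same iteration
schedule but freezes each row individually the moment its own convergence
criterion is met; the result is bit-identical to row-by-row runs (asserted
in the tests) while using large vectorised updates.

## Least-squares SVR

The LS-SVR dual with an equality constraint is one dense symmetric solve:

```
[ 0   1ᵀ         ] [ b0 ]   [ 0 ]
[ 1   K + I/γ    ] [ b  ] = [ y ]
```

with `K_ij = exp(-‖x_i − x_j‖²/(2σ²))`.  The first row enforces
`Σ b_i = 0` (machine-precision in practice; the tests bound it by
`1e-8·‖b‖₁`).  Targets are centred internally for conditioning and the
centring inverted on prediction.  As `γ → ∞` the model interpolates the
training targets; as `γ → 0` it shrinks to their mean.  At calibration
sizes (tens of samples) a direct solve is exact and milliseconds fast, so
no iterative path exists.  Spectra are not standardised by default: the
kernel acts on raw absorbances, and any preprocessing is the caller's
explicit choice.

RMSECV pools squared hold-out residuals over folds before the root.  The
default scheme is leave-one-out up to 60 samples (exhaustive and
deterministic), else seeded 10-fold.

## The weighted multiscale ensemble

Per-sample decomposition → frequency-sorted recombination into mode
matrices `U_k` → one LS-SVR per `(U_k, y)` → weights

```
w_k = RMSECV_k⁻⁴ / Σ_j RMSECV_j⁻⁴
```

computed with the *same* folds for every sub-model, so the weights compare
like with like.  A zero RMSECV (exactly perfect sub-model) would blow up
the law; such sub-models receive all the weight, with a warning.  The
exponent 4 is a named, configurable constant; it makes the weighting close
to a soft argmin, so in practice the best one or two sub-models dominate.
Prediction-set spectra are decomposed with the identical configuration
before sub-models are applied.  All `K` sub-models share one (γ, σ²) pair,
as is customary when one pair is reported per calibration.

The mode number is chosen by scanning an error curve over a K range.  The
default criterion is outer cross-validation on the training set (the
decomposition is per-sample, so one decomposition per K is sliced across
folds); passing a held-out set instead reproduces the historical protocol
of scanning the prediction set directly, which leaks the test set into
model selection and is therefore not the default.  Ties break toward the
smaller K.

## Supporting components

**Kennard–Stone** picks the training set greedily by max-min Euclidean
distance on raw spectra, starting from the farthest pair; ties break to the
lowest index, so the split is deterministic and permutation-covariant.

**PSO** is global-best with linearly decaying inertia (0.9 → 0.4),
`c1 = c2 = 2`, velocities clamped to the box width, positions clipped,
fully seeded.  (γ, σ²) are searched on a log₁₀ grid over [10⁻², 10⁴]² by
default, objective = training-set RMSECV (leak-free); an objective that
scores the prediction set directly is available for fidelity with
historical practice but is flagged as leakage.

**PLS** (univariate-y NIPALS, mean-centred, via scikit-learn) is the linear
baseline.  Its rank is selected by Monte-Carlo cross-validation (default 50
random 80/20 splits, fixed seed) plus an F-test: among candidate ranks, the
smallest whose squared RMSECV ratio to the best rank stays below the F
critical value at `alpha_f = 0.25` with (h, h) degrees of freedom, `h`
being the per-split hold-out count — the usual parsimony convention.  Using
pooled hold-out counts instead would drive the critical value to 1 and
defeat the parsimony test, which is why the per-split count is used.

## The synthetic generator

Real adulteration datasets are rarely deposited, so the generator emulates
them: libraries of nonnegative, peak-normalised, overlapping Gaussian band
profiles (6 oil-like components on a 380–800 nm grid; 4 herb-like
components on a 12,000–4,000 cm⁻¹ grid with bands concentrated below
8,000 cm⁻¹, as in NIR overtone regions), mixture fractions on the simplex
(uniform Dirichlet, or an even 0→100% sweep of the target), and three
corruptions applied to the Beer–Lambert mix `X = F·S`:

* saturation `x ← (1 − e^{−βx})/β`, `β = 3·nonlinearity` (β → 0 linear);
* a per-sample random cubic baseline scaled by `baseline_amp`;
* heteroscedastic noise, sd `= noise_sd · (0.5 + |x|)`.

The UV-Vis profiles are built as a shared three-band absorption plateau
plus one or two narrower seeded marker bands per component, with the marker
variance pinned to half the plateau variance; this keeps every pairwise
profile correlation inside (0.2, 0.95) — overlapping, as chemically related
matrices are, yet distinguishable — robustly across seeds, which fully
random band placement does not.

What the generator does **not** model: scatter effects (no multiplicative
scatter, no Kubelka–Munk), instrument line-shape, wavelength shifts,
temperature effects, or realistic component covariances.  Tests passing on
this substrate show the pipeline's mechanics and its behaviour under the
modelled corruptions; they do not certify performance on real instrument
data.

## The replicated benchmark and what it shows

The default benchmark draws 20 replicate datasets (75 NIR-herb-like
samples each; noise_sd 0.002, baseline_amp 0.01, nonlinearity 0.3), splits
each 50/25 by Kennard–Stone, and scores PLS (MCCV + F-test rank), a single
raw-spectrum LS-SVR, and the K = 5 ensemble on the prediction set.  To keep
the 20-replicate run to a few minutes on one core, (γ, σ²) are tuned once
by PSO (swarm 10, 12 iterations, 5-fold RMSECV objective) on the first
replicate's training set — one pair for the raw model, one for the
ensemble — and reused across replicates.

All three methods calibrate essentially perfectly there (prediction-set
R > 0.98 in every replicate).  The ensemble's median RMSEP, however, is
*larger* than the single model's at these corruption levels.  This is
structural, not a tuning artifact: the spectra are smooth, so the
informative variation lives at frequencies ≈ 0–0.05 cycles/sample, and any
K ≥ 2 decomposition splits that band across modes.  Each sub-model then
sees only part of the composition information, every per-mode RMSECV sits
well above the raw model's, and a weighted average of strictly worse,
error-correlated sub-models cannot beat the raw model — at any (γ, σ²),
α, K, or dc_mode setting we scanned.  Decomposition starts paying once the
raw spectrum is corrupted enough that distance in raw-spectrum space is
dominated by nuisance variation: at noise_sd 0.05 / baseline_amp 0.1 the
ensemble's RMSEP is ~40% below the single model's (the README example),
because the low-frequency sub-model keeps the composition bands while
shedding the noise and the weighting suppresses the rest.  The practical
reading: use the ensemble on noisy, drift-prone measurements; on very clean
spectra a single well-regularised model is already at the noise floor and
the decomposition only discards information.

## Numerical and design notes

* Determinism: every stochastic step (PSO, CV shuffles, generator, random
  omega init) takes an explicit seed; fitted ensembles serialise to
  byte-identical JSON across reruns.
* Degenerate inputs: all-identical samples make Kennard–Stone arbitrary
  (lowest indices, with a warning); non-finite spectra, over-decomposition
  (`K > n/2`), nonpositive kernel widths and rank-exceeding LV requests are
  rejected with typed errors that the CLI maps to exit codes 2/3/4.
* The K-selection and PSO "score the prediction set" variants exist only
  for fidelity with historical practice and are documented as leaky.
* Problem sizes in the tests (signal lengths 64–512 for tone checks, 20–75
  samples for pipeline checks) were chosen as the smallest sizes at which
  the asserted properties are cleanly exhibited.
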