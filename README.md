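# vmdcal

Multiscale ensemble calibration for quantifying adulterants in UV-Vis and
NIR spectra.

Food and herb fraud — diluting rapeseed oil into premium oil blends, cutting
medicinal rhizome powders with cheaper look-alikes — is routinely policed by
optical spectroscopy plus multivariate calibration: measure an absorbance
spectrum, predict the mass fraction of the component of interest.  Single
calibration models (PLS, SVR) see the raw spectrum whole, where composition
bands, baseline drift and noise are entangled.  `vmdcal` implements a
frequency-multiscale ensemble alternative:

1. **Variational mode decomposition (VMD).**  Each spectrum `x` is split into
   `K` narrow-band modes `u_k` with centre frequencies `ω_k` by minimising the
   summed bandwidths `Σ_k ‖∂_t[(δ(t) + j/πt) ∗ u_k(t)] e^{-jω_k t}‖²` subject
   to `Σ_k u_k ≈ x`, solved by ADMM in the frequency domain (Wiener-filter
   mode updates, power-mean frequency updates).
2. **Mode matrices.**  The k-th mode of every sample, sorted by frequency,
   forms a matrix `U_k` with the shape of the training set.
3. **Per-mode sub-models.**  A least-squares SVR (RBF kernel
   `k(x_i, x_j) = exp(-‖x_i − x_j‖²/2σ²)`, solved as one dense linear system
   with regularisation weight γ) is fitted between each `U_k` and the target.
4. **Inverse-fourth-power weighting.**  Predictions combine as
   `ŷ = Σ_k w_k ŷ_k` with `w_k ∝ RMSECV_k⁻⁴`, so sub-models on noisy
   high-frequency modes are suppressed and information-bearing low-frequency
   modes dominate.

The supporting workflow ships alongside: Kennard–Stone sample partitioning,
particle-swarm search for (γ, σ²), a PLS baseline with Monte-Carlo CV +
F-test rank selection, RMSEP / Pearson-R evaluation, and a synthetic
Beer–Lambert mixture-spectra generator so the whole pipeline is testable
without proprietary instrument data.

## Worked example

```python
import numpy as np
from vmdcal import (VMDWMSVR, LSSVR, kennard_stone, make_library,
                    sample_fractions, synthesize, rmsep, pearson_r)

# 75 synthetic NIR-like herb blends; target = mass-% of component 1
lib = make_library("nir_herb_like", seed=0)
design = sample_fractions(75, 4, scheme="dirichlet", seed=11)
X, y = synthesize(lib, design, noise_sd=0.05, baseline_amp=0.1,
                  nonlinearity=0.3, seed=11)

train, test = kennard_stone(X, 50)            # max-min distance split
single = LSSVR(gamma=1e4, sigma2=1433.0).fit(X[train], y[train])
ensemble = VMDWMSVR(K=5, gamma=1e4, sigma2=1433.0).fit(X[train], y[train])

for name, model in [("LSSVR", single), ("VMD-WMSVR", ensemble)]:
    p = model.predict(X[test])
    print(f"{name:10s} RMSEP={rmsep(y[test], p):.3f}  R={pearson_r(y[test], p):.4f}")
print("weights:", np.round(ensemble.weights_, 3))
```

Output:

```
LSSVR      RMSEP=1.404  R=0.9982
VMD-WMSVR  RMSEP=0.870  R=0.9993
weights: [1. 0. 0. 0. 0.]
```

RMSEP is in the units of the target (mass-%), so the ensemble predicts the
adulterant fraction of held-out blends to within about 0.9 percentage points
versus 1.4 for the single model on these heavily corrupted spectra: the
weighting concentrates almost all mass on the low-frequency sub-model, which
sees the composition bands but not the noise.  On very clean spectra the
advantage reverses — see `docs/methods.md` for when decomposition helps and
when it costs.

The same workflow is scriptable from the shell:

```sh
vmdcal simulate --preset nir_herb_like --m 75 --seed 0 --out-x X.csv --out-y y.csv
vmdcal split --spectra X.csv --train-size 50 --out split.csv
vmdcal train --spectra X.csv --targets y.csv --k 5 --gamma 1e4 --sigma2 1433 --out model.json
vmdcal predict --model model.json --spectra X.csv --out pred.csv
vmdcal evaluate --predictions pred.csv --targets y.csv
```

## Layout

| path | contents |
| --- | --- |
| `src/vmdcal/vmd.py` | VMD solver (ADMM, mirrored boundaries) |
| `src/vmdcal/lssvr.py` | least-squares SVR estimator + RMSECV |
| `src/vmdcal/ensemble.py` | mode matrices, weighted ensemble, K scan |
| `src/vmdcal/baselines.py` | PLS + MCCV/F-test rank selection |
| `src/vmdcal/model_selection.py` | Kennard–Stone, PSO, metrics |
| `src/vmdcal/synthetic.py` | mixture-spectra generator |
| `src/vmdcal/benchmark.py` | replicated three-method comparison |
| `src/vmdcal/io.py`, `cli.py`, `experiment.py` | formats, CLI, orchestration |
| `docs/methods.md` | models, assumptions, numerical choices |
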