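"""Mode-matrix recombination, ensemble weighting and the K scan."""

import json

import numpy as np
import pytest

from vmdcal import (
    LSSVR,
    VMDConfig,
    VMDWMSVR,
    build_mode_matrices,
    kennard_stone,
    make_library,
    pearson_r,
    sample_fractions,
    select_K,
    synthesize,
    vmd_decompose,
)
from vmdcal.ensemble import combine_weights
from vmdcal.exceptions import ConfigError, InvalidInputError
from vmdcal.io import save_model


class TestModeMatrices:
    def test_single_sample_rows_equal_modeset(self, small_uvvis):
        X, _ = small_uvvis
        cfg = VMDConfig(K=3)
        stack = build_mode_matrices(X[:1], cfg)
        ms = vmd_decompose(X[0], cfg)
        for k in range(3):
            np.testing.assert_array_equal(stack.U[k][0], ms.modes[k])

    def test_identical_samples_give_identical_rows(self, small_uvvis):
        X, _ = small_uvvis
        Xdup = np.vstack([X[0], X[1], X[0]])
        stack = build_mode_matrices(Xdup, VMDConfig(K=3))
        for Uk in stack.U:
            np.testing.assert_array_equal(Uk[0], Uk[2])

    def test_stack_shapes_match_training_matrix(self, small_uvvis):
        X, _ = small_uvvis
        stack = build_mode_matrices(X[:4], VMDConfig(K=4))
        assert stack.K == 4
        assert all(Uk.shape == X[:4].shape for Uk in stack.U)

    def test_recombined_modes_reconstruct_clean_spectra(self, noiseless_spectra):
        X, _ = noiseless_spectra
        stack = build_mode_matrices(X[:8], VMDConfig(K=5, tau=0.0))
        rec = np.sum(stack.U, axis=0)
        resid = np.linalg.norm(X[:8] - rec, axis=1) / np.linalg.norm(X[:8], axis=1)
        assert np.all(resid <= 0.05)


class TestWeighting:
    @staticmethod
    def _weights_from(errors, power=4.0):
        w = np.asarray(errors, dtype=float) ** (-power)
        return w / w.sum()

    def test_equal_errors_give_uniform_weights(self):
        np.testing.assert_allclose(self._weights_from([2.0, 2.0, 2.0]),
                                   np.full(3, 1 / 3), atol=1e-15)

    def test_inverse_fourth_power_law(self):
        np.testing.assert_allclose(self._weights_from([1.0, 2.0]),
                                   [16 / 17, 1 / 17], atol=1e-15)

    def test_fitted_weights_follow_the_law(self, small_uvvis):
        X, y = small_uvvis
        est = VMDWMSVR(K=3, gamma=1e3, sigma2=50.0, cv=5).fit(X, y)
        np.testing.assert_allclose(
            est.weights_, self._weights_from(est.rmsecv_per_mode_), atol=1e-12
        )
        assert est.weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(est.weights_ >= 0)

    def test_zero_rmsecv_takes_all_weight(self):
        with pytest.warns(UserWarning):
            w = combine_weights(np.array([0.0, 1.0]))
        np.testing.assert_array_equal(w, [1.0, 0.0])

    def test_negative_error_rejected(self):
        with pytest.raises(InvalidInputError):
            combine_weights(np.array([1.0, -0.5]))


class TestPredict:
    def test_weighted_mean_hand_check(self):
        # sub-model predictions [2, 4], weights [0.75, 0.25] -> 2.5
        assert np.dot([0.75, 0.25], [2.0, 4.0]) == pytest.approx(2.5)

    def test_degenerate_weights_select_single_submodel(self, small_uvvis):
        X, y = small_uvvis
        est = VMDWMSVR(K=2, gamma=1e3, sigma2=50.0, cv=5).fit(X[:20], y[:20])
        est.weights_ = np.array([1.0, 0.0])
        stack = build_mode_matrices(X[20:], est._vmd_config())
        np.testing.assert_allclose(
            est.predict(X[20:]), est.submodels_[0].predict(stack.U[0]), atol=1e-12
        )

    def test_row_permutation_permutes_predictions(self, small_uvvis, rng):
        X, y = small_uvvis
        est = VMDWMSVR(K=2, gamma=1e3, sigma2=50.0, cv=5).fit(X[:20], y[:20])
        Xnew = X[20:]
        perm = rng.permutation(len(Xnew))
        np.testing.assert_allclose(
            est.predict(Xnew[perm]), est.predict(Xnew)[perm], atol=1e-12
        )

    def test_k1_ensemble_equals_plain_lssvr_on_smoothed_mode(self, small_uvvis):
        """With one mode the ensemble is LS-SVR on the single mode matrix."""
        X, y = small_uvvis
        est = VMDWMSVR(K=1, tau=0.0, gamma=1e3, sigma2=50.0).fit(X[:20], y[:20])
        tr_stack = build_mode_matrices(X[:20], est._vmd_config())
        te_stack = build_mode_matrices(X[20:], est._vmd_config())
        direct = LSSVR(gamma=1e3, sigma2=50.0).fit(tr_stack.U[0], y[:20])
        np.testing.assert_allclose(
            est.predict(X[20:]), direct.predict(te_stack.U[0]), atol=1e-10
        )

    def test_dimension_mismatch_rejected(self, small_uvvis):
        X, y = small_uvvis
        est = VMDWMSVR(K=2, gamma=1e3, sigma2=50.0, cv=5).fit(X[:15], y[:15])
        with pytest.raises(InvalidInputError):
            est.predict(np.ones((2, 10)))


class TestEndToEnd:
    def test_linear_mixture_prediction_quality(self):
        """Linear 4-component mixtures at 1% noise: prediction-set R >= 0.95."""
        lib = make_library("nir_herb_like", 0)
        design = sample_fractions(60, 4, "dirichlet", seed=0)
        X, y = synthesize(lib, design, noise_sd=0.01, seed=0)
        tr, te = kennard_stone(X, 40)
        est = VMDWMSVR(K=5, gamma=1e3, sigma2=50.0).fit(X[tr], y[tr])
        assert pearson_r(y[te], est.predict(X[te])) >= 0.95

    def test_refit_and_serialisation_deterministic(self, small_uvvis, tmp_path):
        X, y = small_uvvis
        blobs = []
        for run in range(2):
            est = VMDWMSVR(K=2, gamma=1e3, sigma2=50.0, cv=5, random_state=0)
            est.fit(X[:15], y[:15])
            path = tmp_path / f"model_{run}.json"
            save_model(path, est)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]


class TestSelectK:
    def test_singleton_range(self, small_uvvis):
        X, y = small_uvvis
        K, curve = select_K(X[:15], y[:15], [3], cv=3, gamma=1e3, sigma2=50.0)
        assert K == 3 and set(curve) == {3}

    def test_tie_breaks_toward_smaller_k(self):
        curve = dict(zip([2, 3, 4, 5], [5.0, 3.0, 3.0, 7.0]))
        assert min(curve, key=lambda k: (curve[k], k)) == 3

    def test_two_scale_dataset_prefers_interior_k(self):
        """Composition bands plus a high-frequency nuisance tone: the scan
        picks some K >= 2 whose error does not exceed the range endpoints."""
        lib = make_library("uvvis_oil_like", 0)
        design = sample_fractions(30, 6, "dirichlet", seed=3)
        X, y = synthesize(lib, design, noise_sd=0.005, seed=3)
        rng = np.random.default_rng(3)
        t = np.arange(X.shape[1])
        X = X + rng.standard_normal((30, 1)) * 0.05 * np.sin(0.5 * np.pi * t)[None, :]
        K_range = [2, 3, 4]
        K, curve = select_K(X, y, K_range, cv=3, gamma=1e3, sigma2=50.0,
                            random_state=0)
        assert K >= 2
        assert curve[K] <= curve[K_range[0]]
        assert curve[K] <= curve[K_range[-1]]

    def test_empty_range_rejected(self, small_uvvis):
        X, y = small_uvvis
        with pytest.raises(InvalidInputError):
            select_K(X, y, [])

    def test_out_of_band_k_rejected(self, small_uvvis):
        X, y = small_uvvis
        with pytest.raises(ConfigError):
            select_K(X, y, [X.shape[1]])
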