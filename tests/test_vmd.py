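"""Mode decomposition: boundary handling, tone recovery, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmdcal import (
    VMDConfig,
    crop_center,
    mirror_extend,
    reconstruct,
    vmd_decompose,
    vmd_decompose_batch,
)
from vmdcal.exceptions import ConfigError, InvalidInputError
from vmdcal.vmd import ModeSet


class TestMirrorExtension:
    def test_definition(self):
        np.testing.assert_array_equal(
            mirror_extend(np.array([1.0, 2, 3, 4])),
            [2, 1, 1, 2, 3, 4, 4, 3],
        )

    def test_constant_stays_constant(self):
        assert np.all(mirror_extend(np.full(10, 3.7)) == 3.7)

    @given(st.integers(2, 40), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_crop_inverts_extend(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        np.testing.assert_array_equal(crop_center(mirror_extend(x), n), x)

    def test_extended_length_is_doubled(self):
        for n in (2, 5, 17, 64):
            assert mirror_extend(np.zeros(n)).shape == (2 * n,)

    def test_crop_rejects_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            crop_center(np.zeros(10), 4)


def _tone(n, cycles, amp=1.0):
    t = np.arange(n)
    return amp * np.cos(2 * np.pi * cycles * t / n)


class TestDecomposition:
    def test_single_tone_frequency_and_shape(self):
        """A pure cosine is recovered as one mode at its FFT-peak frequency."""
        x = _tone(256, 8)
        oracle_freq = np.argmax(np.abs(np.fft.rfft(x))) / 256
        ms = vmd_decompose(x, VMDConfig(K=1, alpha=2000, tau=0))
        assert abs(ms.omegas[0] - oracle_freq) < 1e-3
        edge = 26  # exclude the 10% boundary region
        c = np.corrcoef(ms.modes[0][edge:-edge], x[edge:-edge])[0, 1]
        assert c > 0.99

    def test_constant_signal_is_a_dc_fixed_point(self):
        x = np.ones(64)
        ms = vmd_decompose(x, VMDConfig(K=1, dc_mode=True))
        assert ms.omegas[0] == 0.0
        assert np.max(np.abs(ms.modes[0] - x)) < 1e-6

    def test_two_tones_separate_against_fft_mask_oracle(self):
        """Each well-separated tone lands in exactly one mode."""
        n = 512
        x = _tone(n, 5) + _tone(n, 60, amp=0.8)
        ms = vmd_decompose(x, VMDConfig(K=2, alpha=2000))
        np.testing.assert_allclose(ms.omegas, [5 / n, 60 / n], atol=2e-3)
        # oracle: ideal band-pass masks split at the spectral midpoint
        spec = np.fft.rfft(x)
        cut = (5 + 60) // 2
        low = np.fft.irfft(np.where(np.arange(len(spec)) <= cut, spec, 0), n)
        high = np.fft.irfft(np.where(np.arange(len(spec)) > cut, spec, 0), n)
        assert np.corrcoef(ms.modes[0], low)[0, 1] > 0.99
        assert np.corrcoef(ms.modes[1], high)[0, 1] > 0.99

    @pytest.mark.parametrize("K", [3, 5, 7])
    def test_modes_reconstruct_clean_spectra(self, noiseless_spectra, K):
        X, _ = noiseless_spectra
        modes, _, _, _ = vmd_decompose_batch(X, VMDConfig(K=K, alpha=2000, tau=0))
        resid = np.linalg.norm(X - modes.sum(axis=1), axis=1)
        assert np.all(resid / np.linalg.norm(X, axis=1) <= 0.05)

    def test_frequencies_sorted_within_unit_band(self, noiseless_spectra):
        X, _ = noiseless_spectra
        _, omegas, _, _ = vmd_decompose_batch(X[:5], VMDConfig(K=4))
        assert np.all(np.diff(omegas, axis=1) >= 0)
        assert np.all((omegas >= 0) & (omegas <= 0.5))

    def test_deterministic_with_random_init(self):
        x = _tone(128, 3) + 0.5 * _tone(128, 20)
        cfg = VMDConfig(K=2, omega_init="random", random_seed=42)
        a = vmd_decompose(x, cfg)
        b = vmd_decompose(x, cfg)
        np.testing.assert_array_equal(a.modes, b.modes)
        np.testing.assert_array_equal(a.omegas, b.omegas)

    def test_fixed_point_is_linear_in_amplitude(self):
        """Scaling the signal scales the modes; the omega trajectory is shared."""
        x = _tone(128, 4) + _tone(128, 30, amp=0.6)
        cfg = VMDConfig(K=2)
        a = vmd_decompose(x, cfg, n_iter_fixed=50)
        b = vmd_decompose(2.5 * x, cfg, n_iter_fixed=50)
        np.testing.assert_allclose(a.omegas, b.omegas, atol=1e-13)
        np.testing.assert_allclose(b.modes, 2.5 * a.modes, rtol=0, atol=1e-9)

    def test_batch_equals_per_sample_bitwise(self, small_uvvis):
        X, _ = small_uvvis
        cfg = VMDConfig(K=3)
        modes, omegas, n_iter, _ = vmd_decompose_batch(X[:6], cfg)
        for i in range(6):
            ms = vmd_decompose(X[i], cfg)
            np.testing.assert_array_equal(ms.modes, modes[i])
            np.testing.assert_array_equal(ms.omegas, omegas[i])
            assert ms.n_iterations == n_iter[i]

    def test_non_finite_input_rejected(self):
        x = np.ones(32)
        x[3] = np.nan
        with pytest.raises(InvalidInputError):
            vmd_decompose(x, VMDConfig(K=1))

    def test_over_decomposition_guard(self):
        with pytest.raises(ConfigError):
            vmd_decompose(np.ones(16), VMDConfig(K=9))

    def test_invalid_config_rejected(self):
        for kwargs in ({"K": 0}, {"K": 1, "alpha": -1.0}, {"K": 1, "tol": 0.0},
                       {"K": 1, "omega_init": "bogus"}):
            with pytest.raises(ConfigError):
                VMDConfig(**kwargs)


class TestReconstruct:
    def test_sum_definition(self):
        ms = ModeSet(modes=np.array([[1.0, 2], [3, 4]]), omegas=np.array([0.0, 0.1]),
                     n_iterations=1, converged=True)
        np.testing.assert_array_equal(reconstruct(ms), [4, 6])

    def test_single_mode_identity(self):
        r = np.array([0.5, -1.0, 2.0])
        ms = ModeSet(modes=r[None, :], omegas=np.array([0.2]),
                     n_iterations=1, converged=True)
        np.testing.assert_array_equal(reconstruct(ms), r)

    def test_empty_rejected(self):
        ms = ModeSet(modes=np.empty((0, 4)), omegas=np.empty(0),
                     n_iterations=0, converged=False)
        with pytest.raises(InvalidInputError):
            reconstruct(ms)
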