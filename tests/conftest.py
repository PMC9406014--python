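import numpy as np
import pytest

from vmdcal import make_library, sample_fractions, synthesize


@pytest.fixture(scope="session")
def oil_library():
    return make_library("uvvis_oil_like", seed=0)


@pytest.fixture(scope="session")
def herb_library():
    return make_library("nir_herb_like", seed=0)


@pytest.fixture(scope="session")
def noiseless_spectra(herb_library):
    """20 clean Beer-Lambert mixture spectra (no noise, baseline or saturation)."""
    design = sample_fractions(20, herb_library.n_components, "dirichlet", seed=0)
    X, y = synthesize(herb_library, design)
    return X, y


@pytest.fixture(scope="session")
def small_uvvis(oil_library):
    """30 mildly noisy UV-Vis-like mixtures for fast end-to-end tests."""
    design = sample_fractions(30, oil_library.n_components, "dirichlet", seed=1)
    X, y = synthesize(oil_library, design, noise_sd=0.002, seed=1)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(0)
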