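import numpy as np
import pytest

from spechvol import SyntheticConfig, fit_pca, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic dataset (14 species, richness {1,2,4,8}, seed 42)."""
    return simulate_experiment(SyntheticConfig())


@pytest.fixture(scope="session")
def default_pca(default_experiment):
    return fit_pca(default_experiment.spectra.to_matrix())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
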