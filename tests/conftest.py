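import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import hybridfba as h


@pytest.fixture(scope="session")
def linear_model():
    return h.make_toy_gem("linear")


@pytest.fixture(scope="session")
def branched_model():
    return h.make_toy_gem("branched")


@pytest.fixture(scope="session")
def cho_mini():
    return h.make_toy_gem("cho-mini")


@pytest.fixture(scope="session")
def cho27():
    return h.make_toy_gem("cho-mini-27")


@pytest.fixture(scope="session")
def default_fixture(cho27):
    """The study fixture: 21 experiments x 27 species, latent dimension 4."""
    spec = h.SyntheticSpec()
    ds, truth = h.simulate_flux_dataset(cho27, spec)
    return ds, truth, spec


@pytest.fixture(scope="session")
def fitted_pca(default_fixture):
    ds, truth, spec = default_fixture
    return h.fit_pca(ds)


@pytest.fixture(scope="session")
def fixture_stats(default_fixture):
    ds, _, _ = default_fixture
    from hybridfba.rates import dataset_statistics
    return dataset_statistics(ds)
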