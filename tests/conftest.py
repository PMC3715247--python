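import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from skinspectra import ExtinctionTable, WienerModel
from skinspectra.fixtures import make_camera_profiles, make_skin_ensemble

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def camera():
    return make_camera_profiles(seed=0)


@pytest.fixture(scope="session")
def table():
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def skin_ensemble():
    return make_skin_ensemble(341, seed=1)


@pytest.fixture(scope="session")
def wiener_model(skin_ensemble, camera):
    return WienerModel.train(skin_ensemble, camera)


@pytest.fixture(scope="session")
def surrogate_conversion(table):
    """Conversion vectors trained on the fast surrogate forward model."""
    from skinspectra.fixtures import surrogate_training_records
    from skinspectra.pipeline import train_conversion_model

    return train_conversion_model(surrogate_training_records(table), table)


@pytest.fixture(scope="session")
def mc_training_grid(table):
    """The 300-state Monte Carlo reflectance grid at 1e4 photons/wavelength.

    Computed once per session; this is the slow fixture backing the
    end-to-end recovery checks.
    """
    from skinspectra.montecarlo import generate_training_grid

    return generate_training_grid(table=table, n_photons=10_000, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
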