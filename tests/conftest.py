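import numpy as np
import pytest

from hsipol.core import SceneGeometry, default_geometry
from hsipol.pipeline import DEFAULT_MODEL
from hsipol.synth import make_cohort


@pytest.fixture(scope="session")
def geometry() -> SceneGeometry:
    return default_geometry()


@pytest.fixture(scope="session")
def native_cohort(geometry):
    """One calibrated single-donor cohort on the native grid (60 cells)."""
    return make_cohort(DEFAULT_MODEL, 1, 30, geometry.wavelengths, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
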