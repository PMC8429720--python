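import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import xspidam as xd


@pytest.fixture(scope="session")
def tables():
    return xd.default_tables()


@pytest.fixture(scope="session")
def detector():
    """The study's detector: 81x81 pixels of 1200 um at 13 cm, 4.96 keV."""
    return xd.build_detector()


@pytest.fixture(scope="session")
def tiny_toy():
    """Small globular particle for fast diffraction/damage checks."""
    return xd.build_toy_protein(60, radius=10.0, seed=5)


@pytest.fixture(scope="session")
def default_pulse():
    return xd.generate_sase_profile(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
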