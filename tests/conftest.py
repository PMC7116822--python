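import numpy as np
import pytest

from mrspec.core import MRSData
from mrspec.model import FitConfig
from mrspec.synth import AxisSpec, default_panel, default_truth, make_basis, make_svs


@pytest.fixture(scope="session")
def axis_spec():
    return AxisSpec(n_points=1024, bandwidth=2000.0,
                    spectrometer_frequency=123.2, ppm_reference=4.65)


@pytest.fixture(scope="session")
def panel_basis(axis_spec):
    return make_basis(default_panel(), axis_spec)


@pytest.fixture()
def fit_config():
    return FitConfig()


@pytest.fixture()
def clean_svs(panel_basis):
    truth = default_truth(seed=0, noise_sd=0.0)
    return make_svs(truth, panel_basis), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_data(rng):
    """A small single-FID dataset with a decaying resonance."""
    t = np.arange(512) / 2000.0
    fid = np.exp((-12.0 + 2j * np.pi * 150.0) * t)
    return MRSData(fid, dwell_time=1 / 2000.0, spectrometer_frequency=123.2)
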