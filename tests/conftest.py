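import numpy as np
import pytest

from ecsastro.ism_calibration import IsmCalibration
from ecsastro.rti_model import DiffusionParams, SourceConfig


@pytest.fixture
def source():
    """Standard protocol: 200 nA / 24 s step on 20 nA bias, r = 100 µm."""
    return SourceConfig()


@pytest.fixture
def tissue_params():
    """Physiological tissue regime."""
    return DiffusionParams(alpha=0.19, lam=1.6, kprime=5e-3,
                           D=1.2e-5, n_transport=0.35)


@pytest.fixture
def free_params():
    return DiffusionParams.free_medium(D=1.2e-5, n_transport=0.35)


@pytest.fixture
def calibration():
    return IsmCalibration(v0=10.0, slope=58.0, interference=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
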