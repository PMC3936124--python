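import numpy as np
import pytest

from pvtsim import DeviceModel, ProtocolConfig, SubjectParams
from pvtsim.presets import device_preset, subject_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return ProtocolConfig()


@pytest.fixture
def reference_device():
    return DeviceModel.reference()


@pytest.fixture
def gaming_device():
    return device_preset("gaming")


@pytest.fixture
def standard_device():
    return device_preset("standard")


@pytest.fixture
def satiated():
    return subject_preset("satiated")


@pytest.fixture
def tsd_subject():
    return subject_preset("tsd85h")


@pytest.fixture
def constant_responder():
    """Noise-free subject emitting a constant 250-ms true RT."""
    return SubjectParams(baseline_mu_ms=250.0, baseline_sigma_ms=0.0,
                         lapse_base_p=0.0, lapse_gain=0.0,
                         false_start_rate_per_s=0.0, s_gain_ms=0.0,
                         c_amplitude_ms=0.0, name="constant250")
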