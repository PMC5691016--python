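import numpy as np
import pytest

from protondosim import beam_preset, detector_preset
from protondosim.beam import sobp_synthesize, pristine_bragg
from protondosim.detectors import ReadoutModel


@pytest.fixture(scope="session")
def spec127():
    return beam_preset("127MeV-Mod0-20mm")


@pytest.fixture(scope="session")
def spec127_mod30():
    return beam_preset("127MeV-Mod30-20mm")


@pytest.fixture(scope="session")
def spec127_8mm():
    return beam_preset("127MeV-Mod0-8mm")


@pytest.fixture(scope="session")
def pristine127(spec127):
    z = np.arange(0.0, 130.0, 0.1)
    return pristine_bragg(spec127, z)


@pytest.fixture(scope="session")
def sobp127_mod30(spec127_mod30):
    z = np.arange(0.0, 130.0, 0.1)
    weights, prof = sobp_synthesize(spec127_mod30, z_grid=z)
    return weights, prof


@pytest.fixture(scope="session")
def diode():
    return detector_preset("PR60020")


@pytest.fixture(scope="session")
def diode_edge():
    return detector_preset("PR60020-edge")


@pytest.fixture(scope="session")
def markus():
    return detector_preset("MarkusN23343")


@pytest.fixture
def readout_noise_free():
    return ReadoutModel(noise_sd=0.0)
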