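import pytest

from dopplerflow.physics import TransducerConfig, VesselGeometry
from dopplerflow.synth import AcquisitionModel, NoiseModel


@pytest.fixture
def transducer():
    return TransducerConfig()


@pytest.fixture
def geometry():
    return VesselGeometry()


@pytest.fixture
def acq():
    return AcquisitionModel()


@pytest.fixture
def no_noise():
    return NoiseModel.none()
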