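import pytest

from resflux import synthetic_data as sd
from resflux.trap_flux import BubbleGas, TrapCalibration


@pytest.fixture(scope="session")
def zero_noise_config():
    return sd.SimConfig(seed=5, noise_sd=sd.zero_noise(), gap_fraction=0.0)


@pytest.fixture(scope="session")
def zero_noise_truth(zero_noise_config):
    drivers = sd.gen_drivers(zero_noise_config)
    return sd.gen_true_flux(drivers, zero_noise_config)


@pytest.fixture(scope="session")
def default_config():
    return sd.SimConfig(seed=7)


@pytest.fixture(scope="session")
def default_truth(default_config):
    drivers = sd.gen_drivers(default_config)
    return sd.gen_true_flux(drivers, default_config)


@pytest.fixture(scope="session")
def calibration():
    return TrapCalibration()


@pytest.fixture(scope="session")
def bubble_gas():
    return BubbleGas()
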