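import numpy as np
import pytest

import dropvisc as dv


@pytest.fixture(scope="session")
def instrument() -> dv.Instrument:
    return dv.default_instrument()


@pytest.fixture
def op100() -> dv.OperatingPoint:
    return dv.OperatingPoint.from_mbar(100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180521)


def noise_free_sensor(**overrides) -> dv.SensorModel:
    """Sensor with all stochastic terms switched off."""
    kwargs = dict(voltage_noise_rms=0.0, passage_time_jitter=0.0, integrated_signal_noise_rms=0.0)
    kwargs.update(overrides)
    return dv.SensorModel(**kwargs)


@pytest.fixture
def quiet_sensor() -> dv.SensorModel:
    return noise_free_sensor()
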