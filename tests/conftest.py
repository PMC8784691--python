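import numpy as np
import pytest

from rvbiomech import kinematics as kin
from rvbiomech import synthetic as syn


@pytest.fixture(scope="session")
def default_material():
    return syn.MaterialSpec(B0=1.2, b1=12.0, b2=7.0, b3=3.0)


@pytest.fixture(scope="session")
def noiseless_records(default_material):
    """Seven-protocol noiseless biaxial experiment, shared across tests."""
    return syn.gen_biaxial_experiment(default_material, seed=0)


@pytest.fixture(scope="session")
def noiseless_tables(noiseless_records):
    return [kin.analyze_record(r) for r in noiseless_records]


@pytest.fixture(scope="session")
def control_waveform():
    return syn.gen_pressure_waveform(syn.WaveformSpec(noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
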