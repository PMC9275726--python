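import numpy as np
import pytest

import esrkit as ek


@pytest.fixture(scope="session")
def constants():
    return ek.PhysicalConstants()


@pytest.fixture(scope="session")
def calibration():
    return ek.CalibrationParams()


@pytest.fixture(scope="session")
def noiseless_spec():
    return ek.SyntheticSpec(n_samples=32, seed=11,
                            noise=ek.NoiseSpec.noiseless())


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    """(truth, cohort) for a 32-sample noiseless synthetic study."""
    return ek.generate_cohort(noiseless_spec)


def make_exp_trace(tau_c=1.0, dt=0.001, duration=5.0, i_min=500.0,
                   delta=2000.0, sample_id="exp"):
    """Single-exponential saturating rise starting exactly at its minimum."""
    t = np.arange(0.0, duration + 1e-12, dt)
    i = i_min + delta * (1.0 - np.exp(-t / tau_c))
    return ek.SyllectogramTrace(sample_id=sample_id, channels=[i], dt=dt,
                                t0_index=[0])


@pytest.fixture
def exp_trace():
    return make_exp_trace()
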