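import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seqmotor as sm

settings.register_profile(
    "suite", derandomize=True, max_examples=20, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: small montage for fast simulations; includes the sensorimotor triplet
#: and frontal channels for blink artifacts
TINY_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "C3", "Cz", "C4",
                 "CP3", "CP4", "P3", "Pz", "P4")


@pytest.fixture(scope="session")
def tiny_montage():
    return sm.standard_montage(TINY_CHANNELS)


@pytest.fixture(scope="session")
def motor_montage():
    return sm.standard_montage(sm.MOTOR_CHANNELS)


def quiet_params(**kw):
    """Deterministic generator settings: no noise, no line, no blinks,
    no keystroke jitter."""
    base = dict(noise_scale=0.0, line_amp=0.0, eog_rate=0.0,
                key_jitter=0.0, key_jitter_max=0.0)
    base.update(kw)
    return sm.SignalModelParams(**base)


@pytest.fixture(scope="session")
def quiet_recording(tiny_montage):
    """Two noiseless, jitter-free blocks (120 trials) at 250 Hz."""
    sched = sm.make_protocol(2, 60, seed=11, key_jitter=0.0,
                             key_jitter_max=0.0, prompt_jitter=0.0)
    return sm.simulate_dataset(sched, quiet_params(), tiny_montage,
                               rate=250.0, seed=11)


@pytest.fixture(scope="session")
def noisy_recording(tiny_montage):
    """One block (60 trials) with the default noise model at 250 Hz."""
    sched = sm.make_protocol(1, 60, seed=7)
    return sm.simulate_dataset(sched, sm.SignalModelParams(), tiny_montage,
                               rate=250.0, seed=7)
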