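import numpy as np
import pytest

from ephyskit.io import (CURRENT_CLAMP, Recording, StimulusStep, Sweep)
from ephyskit.simulate import (NeuronParams, simulate_current_clamp,
                               young_like)


@pytest.fixture(scope="session")
def young_recording():
    """One noisy young-preset recording with its ground truth (seed 0)."""
    return simulate_current_clamp(young_like(), seed=0)


@pytest.fixture(scope="session")
def quiet_recording():
    """A noiseless young-preset recording with its ground truth."""
    from dataclasses import replace
    return simulate_current_clamp(replace(young_like(), sigma=0.0), seed=0)


def make_sweep(samples, dt=0.05, amplitude=0.0, onset=150.0, duration=250.0,
               mode=CURRENT_CLAMP):
    return Sweep(samples=np.asarray(samples, dtype=float), dt=dt,
                 stimulus=StimulusStep(amplitude=amplitude, onset=onset,
                                       duration=duration),
                 mode=mode)


def make_recording(sweeps, cell_id="c0", group="test"):
    return Recording(cell_id=cell_id, animal_id="a0", group=group,
                     sweeps=sweeps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
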