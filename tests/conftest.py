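import numpy as np
import pytest

from meaburst.io import SpikeTrain


def make_train(times, epoch="baseline", duration=1200.0, unit_id="u0",
               electrode_id="e0"):
    return SpikeTrain(unit_id=unit_id, electrode_id=electrode_id, epoch=epoch,
                      spike_times=np.asarray(times, dtype=float),
                      epoch_duration=duration)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_burst_train():
    """10 spikes at uniform 0.05 s ISI: exactly one default-params burst."""
    return make_train(np.arange(10) * 0.05)
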