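import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from neuromea.bursts import BurstCriteria
from neuromea.core import NetworkRecording, SpikeTrain
from neuromea.descriptors import DescriptorConfig


@pytest.fixture
def criteria() -> BurstCriteria:
    return BurstCriteria()


@pytest.fixture
def dcfg() -> DescriptorConfig:
    return DescriptorConfig()


def make_recording(trains_times, window, network_id="net", meta=None):
    trains = tuple(
        SpikeTrain(f"u{k:02d}", np.asarray(t, dtype=float), window)
        for k, t in enumerate(trains_times)
    )
    return NetworkRecording(network_id, trains, meta or {})


@pytest.fixture
def perfect_sync_recording():
    """Ten units with one identical burst in a 60 s window."""
    burst = [10_000.0 + 10.0 * k for k in range(11)]
    return make_recording([burst] * 10, (0.0, 60_000.0), network_id="sync")


@pytest.fixture
def regular_recording():
    """Five-unit, 5 min recording with deterministic regular bursting.

    Each unit bursts every 5 s (8 spikes at 10 ms spacing) with a small
    unit-specific phase offset, plus sparse regular background spikes —
    enough structure for every descriptor to be defined.
    """
    window = (0.0, 300_000.0)
    trains = []
    for u in range(5):
        times = []
        for b in range(60):
            onset = 1000.0 + 5000.0 * b + 7.0 * u
            times.extend(onset + 10.0 * k for k in range(8))
        times.extend(3000.0 + 5000.0 * b + 137.0 * (u + 1) for b in range(59))
        trains.append(sorted(times))
    return make_recording(trains, window, network_id="regular")
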