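"""Core domain types for multielectrode-array (MEA) spike-train analysis.

Conventions used throughout the package:

* Time is measured in **milliseconds** (real numbers) from the start of the
  recording window.
* Every window is half-open, ``[t_start, t_end)``, so bin membership is
  unambiguous.
* A *unit* is the spike activity attributed to one neuron at one electrode;
  spike sorting happens upstream and is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "NetworkRecording",
    "AnalysisWindowPolicy",
    "select_stable_phase",
    "bin_counts",
    "bin_edges",
    "n_complete_bins",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit inside a half-open recording window.

    Parameters
    ----------
    unit_id:
        Identifier of the unit (one neuron at one electrode).
    spike_times:
        Strictly ascending spike times in ms from the window start.
    window:
        ``(t_start, t_end)`` in ms; spikes must lie in ``[t_start, t_end)``.
    electrode_id:
        Optional identifier of the recording electrode.
    """

    unit_id: str
    spike_times: np.ndarray
    window: tuple[float, float]
    electrode_id: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        t0, t1 = float(self.window[0]), float(self.window[1])
        object.__setattr__(self, "window", (t0, t1))
        if not t1 > t0:
            raise ValueError(f"unit {self.unit_id!r}: window length must be > 0")
        if times.ndim != 1:
            raise ValueError(f"unit {self.unit_id!r}: spike_times must be 1-D")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"unit {self.unit_id!r}: spike times must be strictly ascending"
                )
            if times[0] < t0 or times[-1] >= t1:
                raise ValueError(
                    f"unit {self.unit_id!r}: spike times outside window [{t0}, {t1})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration_ms(self) -> float:
        return self.window[1] - self.window[0]

    def isis(self) -> np.ndarray:
        """Interspike intervals (ms); empty for fewer than two spikes."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class NetworkRecording:
    """All spike trains of one cultured network, sharing a single window."""

    network_id: str
    trains: tuple[SpikeTrain, ...]
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        trains = tuple(self.trains)
        object.__setattr__(self, "trains", trains)
        object.__setattr__(self, "meta", dict(self.meta))
        if not trains:
            raise ValueError(f"network {self.network_id!r}: needs at least one train")
        windows = {t.window for t in trains}
        if len(windows) != 1:
            raise ValueError(f"network {self.network_id!r}: trains have mixed windows")
        ids = [t.unit_id for t in trains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"network {self.network_id!r}: duplicate unit_ids")

    @property
    def window(self) -> tuple[float, float]:
        return self.trains[0].window

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def duration_ms(self) -> float:
        return self.window[1] - self.window[0]

    def unit_ids(self) -> list[str]:
        return [t.unit_id for t in self.trains]


@dataclass(frozen=True)
class AnalysisWindowPolicy:
    """Which part of a recording is analyzed and how it is binned.

    Defaults follow common MEA practice for developing cortical cultures:
    the stable activity phase is taken as the final 30 min of the recording,
    summarized in 60 s bins.
    """

    stable_phase_duration: float = 1_800_000.0  # ms, 30 min
    bin_width: float = 60_000.0  # ms, 60 s

    def __post_init__(self) -> None:
        if self.stable_phase_duration <= 0 or self.bin_width <= 0:
            raise ValueError("durations must be positive")
        if self.stable_phase_duration < self.bin_width:
            raise ValueError("stable_phase_duration must be >= bin_width")


def select_stable_phase(
    rec: NetworkRecording, policy: AnalysisWindowPolicy
) -> NetworkRecording:
    """Return the final ``stable_phase_duration`` of a recording.

    Spike times are re-referenced so the returned window is ``[0, D)`` with
    ``D = policy.stable_phase_duration``.  The operation is idempotent.
    """
    t0, t1 = rec.window
    dur = policy.stable_phase_duration
    if (t1 - t0) < dur:
        raise ValueError(
            f"network {rec.network_id!r}: recording of {t1 - t0:.0f} ms is shorter "
            f"than the requested stable phase of {dur:.0f} ms"
        )
    new_t0 = t1 - dur
    trains = []
    for tr in rec.trains:
        keep = tr.spike_times[tr.spike_times >= new_t0] - new_t0
        trains.append(
            SpikeTrain(tr.unit_id, keep, (0.0, dur), electrode_id=tr.electrode_id)
        )
    return NetworkRecording(rec.network_id, tuple(trains), rec.meta)


def n_complete_bins(window: tuple[float, float], bin_width: float) -> int:
    """Number of complete bins of ``bin_width`` inside the window.

    A trailing partial bin is dropped: rate estimates from partial bins are
    biased, and the default 30 min / 60 s layout divides evenly anyway.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # guard against float jitter for windows that divide exactly
    return int(math.floor((window[1] - window[0]) / bin_width + 1e-9))


def bin_edges(window: tuple[float, float], bin_width: float) -> np.ndarray:
    nb = n_complete_bins(window, bin_width)
    return window[0] + bin_width * np.arange(nb + 1)


def bin_counts(train: SpikeTrain, bin_width: float) -> np.ndarray:
    """Spike counts per complete half-open bin covering the train's window."""
    edges = bin_edges(train.window, bin_width)
    if edges.size < 2:
        return np.zeros(0, dtype=np.int64)
    idx = np.searchsorted(edges, train.spike_times, side="right") - 1
    nb = edges.size - 1
    valid = (idx >= 0) & (idx < nb) & (train.spike_times < edges[-1])
    return np.bincount(idx[valid], minlength=nb).astype(np.int64)


def spike_counts_per_bin(
    times: np.ndarray, window: tuple[float, float], bin_width: float
) -> np.ndarray:
    """Like :func:`bin_counts` for a bare time array (internal helper)."""
    edges = bin_edges(window, bin_width)
    if edges.size < 2:
        return np.zeros(0, dtype=np.int64)
    idx = np.searchsorted(edges, np.asarray(times, dtype=float), side="right") - 1
    nb = edges.size - 1
    valid = (idx >= 0) & (idx < nb) & (np.asarray(times) < edges[-1])
    return np.bincount(idx[valid], minlength=nb).astype(np.int64)


def with_meta(rec: NetworkRecording, **meta: object) -> NetworkRecording:
    """Return a copy of the recording with additional metadata entries."""
    merged = dict(rec.meta)
    merged.update(meta)
    return replace(rec, meta=merged)
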