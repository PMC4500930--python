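"""Single-unit burst detection by interspike-interval (ISI) thresholds.

The detector is the classic two-threshold ("max-interval") reading of the
ISI method used by MEA analysis software: a burst is *seeded* by a spike
pair with ISI at most ``max_isi_start``; once open, later spikes are
*appended* while the ISI stays below ``min_isi_end``; an ISI of at least
``min_isi_end`` closes the burst at the last appended spike.  Detected
bursts are then post-processed: consecutive bursts separated by less than
``min_interburst_interval`` are merged (transitively), and only afterwards
are bursts failing ``min_spikes`` or ``min_burst_duration`` discarded.
Merging before filtering prevents a long burst that is split by a single
sparse gap from being thrown away as two sub-threshold fragments.

Boundary semantics, fixed so independent reimplementations can match
bit-exactly: "maximum" thresholds use ``<=``, "minimum" thresholds use
``>=``, and the merge gap uses strict ``<``.  Burst start/end are the first
and last member spike times, with no padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SpikeTrain, bin_edges

__all__ = ["BurstCriteria", "Burst", "detect_bursts", "burst_train_summary"]


@dataclass(frozen=True)
class BurstCriteria:
    """ISI thresholds defining a burst (defaults in ms)."""

    max_isi_start: float = 40.0
    min_isi_end: float = 200.0
    min_interburst_interval: float = 100.0
    min_burst_duration: float = 10.0
    min_spikes: int = 2

    def __post_init__(self) -> None:
        vals = (
            self.max_isi_start,
            self.min_isi_end,
            self.min_interburst_interval,
            self.min_burst_duration,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all ISI thresholds must be positive")
        if self.max_isi_start > self.min_isi_end:
            raise ValueError("max_isi_start must be <= min_isi_end")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")


@dataclass(frozen=True)
class Burst:
    """A contiguous run of one unit's spikes classified as a burst."""

    unit_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.size < 2:
            raise ValueError("a burst needs at least two spikes")

    @property
    def start(self) -> float:
        return float(self.spike_times[0])

    @property
    def end(self) -> float:
        return float(self.spike_times[-1])

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def intra_isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


def detect_bursts(train: SpikeTrain, criteria: BurstCriteria | None = None) -> list[Burst]:
    """Detect all bursts of a spike train under the given ISI criteria.

    Returns bursts in temporal order; every burst's spikes are a contiguous
    run of the train's spikes, bursts are disjoint and separated by at least
    ``min_interburst_interval`` after merging.
    """
    c = criteria or BurstCriteria()
    ts = train.spike_times
    n = ts.size
    if n < 2:
        return []
    isi = np.diff(ts)

    # phase 1: seed + extend
    raw: list[tuple[int, int]] = []  # inclusive spike-index ranges
    i = 0
    while i < n - 1:
        if isi[i] <= c.max_isi_start:
            j = i + 1
            while j < n - 1 and isi[j] < c.min_isi_end:
                j += 1
            raw.append((i, j))
            i = j + 1
        else:
            i += 1

    # phase 2: transitive merge of bursts closer than the interburst minimum
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and (ts[a] - ts[merged[-1][1]]) < c.min_interburst_interval:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    # phase 3: filter by spike count and duration
    out = []
    for a, b in merged:
        n_spk = b - a + 1
        dur = ts[b] - ts[a]
        if n_spk >= c.min_spikes and dur >= c.min_burst_duration:
            out.append(Burst(train.unit_id, ts[a : b + 1]))
    return out


def burst_train_summary(
    bursts: Sequence[Burst], window: tuple[float, float], bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin burst counts (by burst start) and interburst intervals.

    Interburst intervals are the end-to-start gaps between consecutive
    bursts.  Overlapping or unordered bursts indicate an upstream invariant
    breach and are rejected.
    """
    starts = np.array([b.start for b in bursts], dtype=float)
    ends = np.array([b.end for b in bursts], dtype=float)
    if starts.size > 1:
        gaps = starts[1:] - ends[:-1]
        if np.any(gaps < 0):
            raise ValueError("bursts overlap or are out of order")
    else:
        gaps = np.zeros(0)
    edges = bin_edges(window, bin_width)
    nb = edges.size - 1
    if nb <= 0:
        return np.zeros(0, dtype=np.int64), gaps
    idx = np.searchsorted(edges, starts, side="right") - 1
    valid = (idx >= 0) & (idx < nb) & (starts < edges[-1])
    counts = np.bincount(idx[valid], minlength=nb).astype(np.int64)
    return counts, gaps


def detect_bursts_network(
    rec, criteria: BurstCriteria | None = None
) -> dict[str, list[Burst]]:
    """Bursts for every unit of a recording, keyed by unit_id."""
    c = criteria or BurstCriteria()
    return {tr.unit_id: detect_bursts(tr, c) for tr in rec.trains}
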