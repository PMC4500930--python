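"""Independent reference implementations used only by the test suite.

These deliberately take a different route than the package code (segment
splitting and repeated-pass merge closure instead of a single state-machine
scan; plain Python loops instead of vectorized numpy) so that agreement is
evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_bursts(times, criteria) -> list[tuple[int, int]]:
    """Exhaustive burst scan; returns inclusive spike-index ranges.

    Construction: split the train into maximal runs of spikes whose
    consecutive ISIs are all < min_isi_end; within each run, a burst starts
    at the first spike pair with ISI <= max_isi_start (hysteresis: the
    start threshold is tighter than the continuation threshold) and runs to
    the end of the run.  Candidates closer than min_interburst_interval are
    then merged until a fixed point, and finally the spike-count and
    duration floors are applied.
    """
    ts = [float(t) for t in times]
    n = len(ts)
    if n < 2:
        return []
    # maximal runs of consecutive ISIs < min_isi_end
    runs = []
    start = 0
    for i in range(n - 1):
        if ts[i + 1] - ts[i] >= criteria.min_isi_end:
            runs.append((start, i))
            start = i + 1
    runs.append((start, n - 1))

    cands = []
    for a, b in runs:
        for k in range(a, b):
            if ts[k + 1] - ts[k] <= criteria.max_isi_start:
                cands.append((k, b))
                break

    # merge closure by repeated passes
    changed = True
    while changed:
        changed = False
        out = []
        for c in cands:
            if out and ts[c[0]] - ts[out[-1][1]] < criteria.min_interburst_interval:
                out[-1] = (out[-1][0], c[1])
                changed = True
            else:
                out.append(c)
        cands = out

    return [
        (a, b)
        for a, b in cands
        if (b - a + 1) >= criteria.min_spikes
        and (ts[b] - ts[a]) >= criteria.min_burst_duration
    ]


def random_burst_train(rng: np.random.Generator, duration: float = 60_000.0) -> np.ndarray:
    """Mixed Poisson background + planted bursts, with near-threshold ISIs."""
    n_bg = rng.poisson(duration / 1000.0 * rng.uniform(0.3, 4.0))
    times = [rng.uniform(0, duration, n_bg)]
    n_bursts = rng.poisson(8)
    for _ in range(n_bursts):
        onset = rng.uniform(0, duration)
        n_spk = 2 + rng.poisson(rng.uniform(1, 12))
        # ISIs straddling the 40/100/200 ms thresholds to stress boundaries
        isis = rng.choice(
            [5.0, 20.0, 39.0, 40.0, 41.0, 99.0, 100.0, 150.0, 199.0, 201.0],
            size=n_spk - 1,
            p=[0.25, 0.25, 0.08, 0.08, 0.08, 0.06, 0.06, 0.06, 0.04, 0.04],
        ) + rng.uniform(-1.0, 1.0, n_spk - 1)
        times.append(onset + np.concatenate([[0.0], np.cumsum(np.abs(isis))]))
    t = np.unique(np.concatenate(times))
    return t[(t >= 0) & (t < duration * 1.5)]


def naive_spike_rate(rec) -> float:
    """Mean over units of spikes per second over the whole window."""
    dur_s = (rec.window[1] - rec.window[0]) / 1000.0
    return float(np.mean([len(tr.spike_times) / dur_s for tr in rec.trains]))
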