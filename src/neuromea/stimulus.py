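"""Timing model of the pulsed electromagnetic exposure protocol.

The exposure signal is a 150 MHz carrier pulse-modulated at an extremely
low frequency: the modulation cycle of ``1000 / f_mod`` ms is split into an
on-phase of ``duty x cycle`` followed by silence.  The default protocol is
two back-to-back 30 min sessions, 10 Hz then 16 Hz, at 50% duty — giving
100 ms cycles with 50 ms on-phases and 62.5 ms cycles with 31.25 ms
on-phases respectively.

Only the modulation-envelope timing is computable content here; the
carrier is metadata (synthesizing a 150 MHz waveform would add nothing to
the analysis).  Field strength, flux density and hardware control are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StimulusPlan", "cycle_timing", "envelope", "envelope_table"]


@dataclass(frozen=True)
class StimulusPlan:
    carrier_frequency: float = 150e6  # Hz; metadata only
    duty: float = 0.5
    session_duration: float = 1_800_000.0  # ms (30 min per session)
    session_sequence: tuple[float, ...] = (10.0, 16.0)  # modulation Hz

    def __post_init__(self) -> None:
        if not (0.0 < self.duty < 1.0):
            raise ValueError("duty must be in (0, 1)")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")
        if any(f <= 0 for f in self.session_sequence):
            raise ValueError("modulation frequencies must be > 0")


def cycle_timing(
    modulation_frequency: float, duty: float = 0.5
) -> dict[str, float]:
    """Cycle, on-phase and off-phase duration (ms) of one modulation setting."""
    if modulation_frequency <= 0:
        raise ValueError("modulation frequency must be > 0")
    cycle = 1000.0 / modulation_frequency
    on = duty * cycle
    return {"cycle_duration": cycle, "on_phase": on, "off_phase": cycle - on}


def plan_cycle_timings(plan: StimulusPlan) -> list[dict[str, float]]:
    """Cycle timing for each session of the plan, in order."""
    out = []
    for f in plan.session_sequence:
        d = cycle_timing(f, plan.duty)
        d["modulation_frequency"] = f
        out.append(d)
    return out


def envelope(plan: StimulusPlan) -> list[tuple[int, int, float, float]]:
    """Ordered on-intervals ``(session, cycle_index, on_start, on_end)``.

    Times are absolute ms over the concatenated sessions.  A final cycle cut
    short by the session end is emitted truncated rather than dropped, so
    total on-time equals ``duty x total duration`` up to one truncation.
    """
    intervals: list[tuple[int, int, float, float]] = []
    offset = 0.0
    for s, f in enumerate(plan.session_sequence):
        timing = cycle_timing(f, plan.duty)
        cycle, on = timing["cycle_duration"], timing["on_phase"]
        n_cycles = int(np.ceil(plan.session_duration / cycle - 1e-12))
        for k in range(n_cycles):
            start = offset + k * cycle
            end = min(start + on, offset + plan.session_duration)
            if end > start:
                intervals.append((s, k, start, end))
        offset += plan.session_duration
    return intervals


def envelope_table(plan: StimulusPlan) -> pd.DataFrame:
    return pd.DataFrame(
        envelope(plan),
        columns=["session", "cycle_index", "on_start_ms", "on_end_ms"],
    )
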