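#!/usr/bin/env python
"""Document the exposure protocol's modulation-envelope timing.

Prints the analytic cycle timings of the two modulation settings (10 Hz:
100 ms cycle / 50 ms on; 16 Hz: 62.5 ms / 31.25 ms at 50% duty) and writes
the first second of each session's on-interval table; the full two-session
envelope has 46,800 cycles and is regenerated on demand.
"""

from pathlib import Path

from neuromea.stimulus import StimulusPlan, envelope_table, plan_cycle_timings

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    plan = StimulusPlan()
    for t in plan_cycle_timings(plan):
        print(
            f"{t['modulation_frequency']:.0f} Hz: cycle {t['cycle_duration']} ms, "
            f"on {t['on_phase']} ms, off {t['off_phase']} ms"
        )
    df = envelope_table(plan)
    head = df.groupby("session").head(10)
    out = RESULTS / "stimulus_envelope_head.csv"
    head.to_csv(out, index=False)
    on_time = (df.on_end_ms - df.on_start_ms).sum()
    total = plan.session_duration * len(plan.session_sequence)
    print(f"total on-time fraction: {on_time / total:.4f} (duty {plan.duty})")
    print(f"first cycles of each session -> {out}")


if __name__ == "__main__":
    main()
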