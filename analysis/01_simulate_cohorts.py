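#!/usr/bin/env python
"""Simulate control and exposure cohorts at two culture ages.

Generates seeded cohorts of developing cortical networks at a young stage
(14 days in vitro) and a mature stage (28 div, maturation multipliers
applied to both groups), with the exposure group carrying multiplicative
effects on its activity drivers.  Spike tables land under ``scratch/data``
(they are large and fully reproducible from the seed); downstream scripts
read them from there.
"""

from pathlib import Path

from neuromea.io import write_recordings
from neuromea.synth import DIV28_MATURATION, SynthConfig, generate_cohort

BASE_SEED = 20_150_714
N_PER_GROUP = 8
# exposure accelerates development: more spiking/bursting, longer bursts
EXPOSURE = {"background_rate": 1.5, "spikes_per_burst_mean": 1.3, "pop_event_rate": 1.2}

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for div, maturation, seed_offset in ((14, {}, 0), (28, dict(DIV28_MATURATION), 1)):
        cfg = SynthConfig(
            n_units=16, duration=900_000.0, maturation_scale=maturation
        )
        ctrl, treat = generate_cohort(
            cfg, EXPOSURE, N_PER_GROUP, base_seed=BASE_SEED + seed_offset, div=div
        )
        path = OUT / f"spikes_div{div}.csv"
        write_recordings(ctrl + treat, path, format="tabular")
        n_spikes = sum(t.n_spikes for r in ctrl + treat for t in r.trains)
        print(f"div {div}: wrote {len(ctrl) + len(treat)} networks, "
              f"{n_spikes} spikes -> {path}")


if __name__ == "__main__":
    main()
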