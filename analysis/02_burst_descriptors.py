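#!/usr/bin/env python
"""Detect bursts and assemble the 204-feature table for every network.

Reads the simulated cohorts, runs the ISI burst detector (40/200/100/10
ms, 2-spike criteria) and the four-category descriptor engine, and writes
one feature table per culture age under ``results``.
"""

from pathlib import Path

import pandas as pd

from neuromea.bursts import BurstCriteria
from neuromea.descriptors import DescriptorConfig
from neuromea.io import read_recordings
from neuromea.pipeline import analyze_recordings
from neuromea.registry import category_manifest

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    category_manifest().to_csv(RESULTS / "feature_categories.csv", index=False)
    for div in (14, 28):
        recs = read_recordings(DATA / f"spikes_div{div}.csv", format="tabular")
        feats = analyze_recordings(recs, BurstCriteria(), DescriptorConfig())
        out = RESULTS / f"features_div{div}.csv"
        feats.to_csv(out, float_format="%.6g")
        by_group = feats.groupby("group")[["spike_rate", "burst_rate", "burst_duration"]].mean()
        print(f"div {div}: {feats.shape[0]} networks x {feats.shape[1] - 1} features -> {out}")
        print(by_group.round(3).to_string(), "\n")


if __name__ == "__main__":
    main()
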