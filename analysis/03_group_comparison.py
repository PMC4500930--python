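#!/usr/bin/env python
"""Exposure-vs-control comparisons of the twelve named parameters.

For each culture age, reports mean ± SEM per group, the treatment mean as
percent of control, and the pooled-variance unpaired t-test with
significance stars.
"""

from pathlib import Path

import pandas as pd

from neuromea.registry import NAMED_12
from neuromea.stats import comparison_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    for div in (14, 28):
        feats = pd.read_csv(RESULTS / f"features_div{div}.csv", index_col=0)
        fc = feats[feats["group"] == "control"].drop(columns="group")
        ft = feats[feats["group"] == "treatment"].drop(columns="group")
        comp = comparison_table(fc, ft, parameters=NAMED_12)
        out = RESULTS / f"comparisons_div{div}.csv"
        comp.to_csv(out, index=False, float_format="%.6g")
        print(f"div {div} ({len(fc)} vs {len(ft)} networks) -> {out}")
        print(
            comp[["parameter", "pct_of_control", "p", "stars"]]
            .round({"pct_of_control": 1, "p": 4})
            .to_string(index=False),
            "\n",
        )


if __name__ == "__main__":
    main()
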