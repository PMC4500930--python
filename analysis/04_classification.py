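#!/usr/bin/env python
"""Pattern recognition: can the perceptron tell exposure from control?

Leave-one-out cross-validation of the no-hidden-layer Rprop perceptron on
the standardized 204-feature vectors, per culture age, with a χ² test of
the recognition counts against the 50% chance expectation.
"""

from pathlib import Path

import pandas as pd

from neuromea.classify import PerceptronSpec, cross_validate

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    for div in (14, 28):
        feats = pd.read_csv(RESULTS / f"features_div{div}.csv", index_col=0)
        X = feats.drop(columns="group").to_numpy(dtype=float)
        res = cross_validate(X, feats["group"].tolist(), PerceptronSpec(seed=div))
        out = RESULTS / f"recognition_div{div}.csv"
        res.to_frame().to_csv(out, float_format="%.6g")
        print(f"div {div}: {res.folds} recognition -> {out}")
        print(res.to_frame().round(1).to_string())
        print(f"chi2 = {res.chi2_stat:.2f}, p = {res.chi2_p:.4g}\n")


if __name__ == "__main__":
    main()
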