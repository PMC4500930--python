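"""Group summaries, percent-of-control normalization and t-tests.

Treatment effects are summarized per parameter as mean ± SEM per group, the
treatment mean as a percentage of the concurrent control mean, and a
Student's (pooled-variance) unpaired two-sample t-test with the usual
significance stars (*p ≤ 0.05, **p ≤ 0.01, ***p ≤ 0.001).  Welch's test is
available behind a flag.  No multiple-testing correction is applied by
default — comparisons are per-parameter, so across 204 features the
family-wise error is not controlled; a Benjamini–Hochberg helper is
provided for callers who need it.

Morphometry ratios (percent neurons, neurites per neuron, synapses per
neurite, percent GABAergic of neurons) are derived from per-image count
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "compare_groups",
    "comparison_table",
    "stars",
    "benjamini_hochberg",
    "MorphCounts",
    "morph_derive",
    "morph_derive_table",
]


def stars(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    control_mean: float
    control_sem: float
    control_n: int
    treatment_mean: float
    treatment_sem: float
    treatment_n: int
    pct_of_control: float
    t_stat: float
    p_value: float
    stars: str

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "control_mean": self.control_mean,
            "control_sem": self.control_sem,
            "control_n": self.control_n,
            "treatment_mean": self.treatment_mean,
            "treatment_sem": self.treatment_sem,
            "treatment_n": self.treatment_n,
            "pct_of_control": self.pct_of_control,
            "t": self.t_stat,
            "p": self.p_value,
            "stars": self.stars,
        }


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def compare_groups(
    control: Sequence[float],
    treatment: Sequence[float],
    parameter: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-sample t-test with percent-of-control normalization.

    The default is the pooled-variance Student's test; ``welch=True``
    switches to Welch's unequal-variance form.  NaN values are dropped;
    each group must retain at least two finite values.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    c = c[np.isfinite(c)]
    t = t[np.isfinite(t)]
    if c.size < 2 or t.size < 2:
        raise ValueError(
            f"parameter {parameter!r}: need >= 2 finite values per group "
            f"(got {c.size} control, {t.size} treatment)"
        )
    mc, mt = float(np.mean(c)), float(np.mean(t))
    vc, vt = float(np.var(c, ddof=1)), float(np.var(t, ddof=1))
    n1, n2 = c.size, t.size
    if welch:
        se2 = vc / n1 + vt / n2
        if se2 == 0.0:
            t_stat, df = 0.0, float(n1 + n2 - 2)
        else:
            t_stat = (mt - mc) / math.sqrt(se2)
            df = se2**2 / ((vc / n1) ** 2 / (n1 - 1) + (vt / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * vc + (n2 - 1) * vt) / (n1 + n2 - 2)
        df = float(n1 + n2 - 2)
        if sp2 == 0.0:
            t_stat = 0.0 if mt == mc else math.copysign(math.inf, mt - mc)
        else:
            t_stat = (mt - mc) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t_stat), df)) if math.isfinite(t_stat) else 0.0
    pct = 100.0 * mt / mc if mc != 0.0 else math.nan
    return GroupComparison(
        parameter=parameter,
        control_mean=mc,
        control_sem=_sem(c),
        control_n=n1,
        treatment_mean=mt,
        treatment_sem=_sem(t),
        treatment_n=n2,
        pct_of_control=pct,
        t_stat=t_stat,
        p_value=p,
        stars=stars(p),
    )


def comparison_table(
    control: pd.DataFrame,
    treatment: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Compare every requested column of two per-network feature frames.

    Columns without two finite values in each group are skipped (reported
    with NaN statistics) rather than failing the whole table.
    """
    params = list(parameters) if parameters is not None else list(control.columns)
    rows = []
    for p in params:
        try:
            rows.append(
                compare_groups(control[p], treatment[p], parameter=p, welch=welch).to_row()
            )
        except ValueError:
            rows.append({"parameter": p, "p": math.nan, "stars": "ns"})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (off by default in all pipelines; see module doc)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def normality_report(values: Sequence[float]) -> dict[str, float]:
    """Optional Shapiro–Wilk diagnostic (not gating any comparison)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    stat, p = sps.shapiro(x)
    return {"shapiro_w": float(stat), "shapiro_p": float(p)}


# --------------------------------------------------------------------------
# morphometry

@dataclass(frozen=True)
class MorphCounts:
    """Per-image morphology counts from immunostained cultures."""

    image_id: str
    group: str
    div: int
    cells: int
    neurons: int
    neurites: int
    synapses: int
    gaba_neurons: int

    def __post_init__(self) -> None:
        counts = (self.cells, self.neurons, self.neurites, self.synapses, self.gaba_neurons)
        if any(v < 0 for v in counts):
            raise ValueError(f"image {self.image_id!r}: counts must be >= 0")
        if self.neurons > self.cells:
            raise ValueError(f"image {self.image_id!r}: neurons exceed cells")
        if self.gaba_neurons > self.neurons:
            raise ValueError(f"image {self.image_id!r}: GABAergic neurons exceed neurons")


def morph_derive(counts: MorphCounts) -> dict[str, float]:
    """Derived morphology parameters; ratios with zero denominators are NaN.

    ``pct_neurons`` is 0 (not NaN) when there are cells but no neurons.
    """
    pct_neurons = 100.0 * counts.neurons / counts.cells if counts.cells > 0 else math.nan
    npn = counts.neurites / counts.neurons if counts.neurons > 0 else math.nan
    spn = counts.synapses / counts.neurites if counts.neurites > 0 else math.nan
    pct_gaba = 100.0 * counts.gaba_neurons / counts.neurons if counts.neurons > 0 else math.nan
    return {
        "pct_neurons": pct_neurons,
        "neurites_per_neuron": npn,
        "synapses_per_neurite": spn,
        "pct_gaba_of_neurons": pct_gaba,
    }


def morph_derive_table(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`morph_derive` over a MorphCounts table."""
    rows = []
    for _, r in df.iterrows():
        mc = MorphCounts(
            image_id=str(r["image_id"]),
            group=str(r["group"]),
            div=int(r["div"]),
            cells=int(r["cells"]),
            neurons=int(r["neurons"]),
            neurites=int(r["neurites"]),
            synapses=int(r["synapses"]),
            gaba_neurons=int(r["gaba_neurons"]),
        )
        rows.append({**r.to_dict(), **morph_derive(mc)})
    return pd.DataFrame(rows)
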