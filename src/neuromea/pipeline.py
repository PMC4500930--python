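"""End-to-end pipeline: simulate → analyze → compare → classify → report.

One :class:`PipelineConfig` (loadable from YAML) drives the whole flow with
a single seed; two runs with the same config produce byte-identical report
bundles.  The bundle contains per-network 204-feature tables, a
group-comparison table with significance stars, a recognition table with
the χ² p-value, and a plain-text run manifest (versions, seed, config
hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .bursts import BurstCriteria, detect_bursts_network
from .classify import PerceptronSpec, RpropSpec, cross_validate
from .core import AnalysisWindowPolicy, NetworkRecording, select_stable_phase
from .descriptors import DescriptorConfig, assemble_features
from .io import write_recordings
from .registry import NAMED_12, REGISTRY_VERSION, category_manifest, feature_frame
from .stats import comparison_table
from .synth import SynthConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    treatment_multipliers: Mapping[str, float] = field(default_factory=dict)
    n_per_group: int = 8
    div: int = 14
    criteria: BurstCriteria = field(default_factory=BurstCriteria)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    perceptron: PerceptronSpec = field(default_factory=PerceptronSpec)
    policy: AnalysisWindowPolicy | None = None
    seed: int = 0
    write_spikes: bool = False
    compare_parameters: tuple[str, ...] = NAMED_12

    def config_hash(self) -> str:
        payload = json.dumps(_as_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _as_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "synth" in raw:
        kwargs["synth"] = SynthConfig(**raw["synth"])
    if "criteria" in raw:
        kwargs["criteria"] = BurstCriteria(**raw["criteria"])
    if "descriptors" in raw:
        kwargs["descriptors"] = DescriptorConfig(**raw["descriptors"])
    if "perceptron" in raw:
        p = dict(raw["perceptron"])
        if "rprop" in p:
            p["rprop"] = RpropSpec(**p["rprop"])
        kwargs["perceptron"] = PerceptronSpec(**p)
    if "policy" in raw and raw["policy"] is not None:
        kwargs["policy"] = AnalysisWindowPolicy(**raw["policy"])
    for k in ("treatment_multipliers", "n_per_group", "div", "seed", "write_spikes"):
        if k in raw:
            kwargs[k] = raw[k]
    if "compare_parameters" in raw:
        kwargs["compare_parameters"] = tuple(raw["compare_parameters"])
    return PipelineConfig(**kwargs)


def analyze_recordings(
    recs: list[NetworkRecording],
    criteria: BurstCriteria,
    cfg: DescriptorConfig,
    policy: AnalysisWindowPolicy | None = None,
) -> pd.DataFrame:
    """Stable-phase 204-feature table, one row per network."""
    tables = []
    groups = []
    for rec in recs:
        if policy is not None:
            rec = select_stable_phase(rec, policy)
        bursts = detect_bursts_network(rec, criteria)
        tables.append(assemble_features(rec, cfg, bursts_by_unit=bursts))
        groups.append(rec.meta.get("group", ""))
    df = feature_frame(tables)
    df.insert(0, "group", groups)
    df.index.name = "network_id"
    return df


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle under ``outdir``.

    Returns the paths of the written artifacts.  Any stage failure raises
    with the stage name in the message.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- simulate -----------------------------------------------------
    try:
        ctrl, treat = generate_cohort(
            config.synth,
            config.treatment_multipliers,
            config.n_per_group,
            base_seed=config.seed,
            div=config.div,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    if config.write_spikes:
        paths["spikes"] = out / "spikes.csv"
        write_recordings(ctrl + treat, paths["spikes"], format="tabular")

    # --- analyze ------------------------------------------------------
    current = ""
    try:
        feats_rows = []
        for rec in ctrl + treat:
            current = rec.network_id
            feats_rows.append(
                analyze_recordings(
                    [rec], config.criteria, config.descriptors, config.policy
                )
            )
        feats = pd.concat(feats_rows)
    except Exception as exc:
        raise RuntimeError(
            f"stage 'analyze' failed on network {current!r}: {exc}"
        ) from exc
    paths["features"] = out / "features.csv"
    feats.to_csv(paths["features"], float_format="%.10g")
    paths["categories"] = out / "feature_categories.csv"
    category_manifest().to_csv(paths["categories"], index=False)

    # --- compare ------------------------------------------------------
    try:
        fc = feats[feats["group"] == "control"].drop(columns="group")
        ft = feats[feats["group"] == "treatment"].drop(columns="group")
        comp = comparison_table(fc, ft, parameters=config.compare_parameters)
    except Exception as exc:
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc
    paths["comparisons"] = out / "comparisons.csv"
    comp.to_csv(paths["comparisons"], index=False, float_format="%.10g")

    # --- classify -----------------------------------------------------
    try:
        X = feats.drop(columns="group").to_numpy(dtype=float)
        result = cross_validate(X, feats["group"].tolist(), config.perceptron)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
    paths["recognition"] = out / "recognition.csv"
    result.to_frame().to_csv(paths["recognition"], float_format="%.10g")

    # --- report manifest ---------------------------------------------
    manifest = "\n".join(
        [
            f"neuromea {__version__}",
            f"numpy {np.__version__} / scipy {scipy.__version__} / pandas {pd.__version__}",
            f"registry {REGISTRY_VERSION}",
            f"seed {config.seed}",
            f"config_hash {config.config_hash()}",
            f"n_per_group {config.n_per_group}",
            f"chi2_p {result.chi2_p:.10g}",
        ]
    )
    paths["manifest"] = out / "manifest.txt"
    paths["manifest"].write_text(manifest + "\n")
    return paths
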