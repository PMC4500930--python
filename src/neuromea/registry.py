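"""The 204-feature registry describing one network's activity.

The multiparametric description of a network is a fixed, ordered set of 204
named features, partitioned into four categories:

* ``general_activity`` — firing and bursting rates, timing of bursts;
* ``burst_structure`` — the internal composition of bursts;
* ``synchronization`` — coordination across units (population bursts,
  Hamming similarity, across-unit coefficients of variation, CVnet);
* ``oscillation`` — temporal regularity (across-bin SDs and coefficients
  of variation over time, CVtime).

The registry is generated from three building blocks:

1. **Binnable primaries** (44): statistics defined for one unit within one
   time span.  Each is emitted four times: the plain name (its stable-phase
   value), ``_sd`` (SD of the per-bin network mean across 60 s bins,
   category *oscillation*), ``_cvtime`` (mean over units of the per-unit
   coefficient of variation across bins, *oscillation*) and ``_cvnet``
   (coefficient of variation of per-unit values across the network,
   *synchronization*).
2. **Burst-profile primaries** (8): scalars of the onset-aligned,
   kernel-smoothed mean burst rate profile.  Emitted twice: plain
   (*burst_structure*) and ``_cvnet`` (*synchronization*).
3. **Network-level features** (12): population-burst and similarity
   measures that only exist at the network level.

44*4 + 8*2 + 12 = 204.  The composition is an explicit, versioned choice of
this package (``REGISTRY_VERSION``); analyses are only comparable within
one registry version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REGISTRY_VERSION",
    "CATEGORIES",
    "NAMED_12",
    "registry",
    "feature_names",
    "ParameterTable",
    "feature_frame",
]

REGISTRY_VERSION = "neuromea-204-v1"

GENERAL = "general_activity"
BURST = "burst_structure"
SYNC = "synchronization"
OSC = "oscillation"
CATEGORIES = (GENERAL, BURST, SYNC, OSC)

# (name, category of the plain stable-phase value, level)
# level: "unit"  -> computed per unit, network value = mean over units
#        "burst" -> statistic over per-burst scalars pooled network-wide
BINNABLE_PRIMARIES: tuple[tuple[str, str, str], ...] = (
    # firing / ISI distribution
    ("spike_rate", GENERAL, "unit"),
    ("tonic_spike_rate", GENERAL, "unit"),
    ("burst_spike_fraction", GENERAL, "unit"),
    ("spike_contrast", GENERAL, "unit"),
    ("fano_factor", GENERAL, "unit"),
    ("isi_mean", GENERAL, "unit"),
    ("isi_median", GENERAL, "unit"),
    ("isi_cv", GENERAL, "unit"),
    ("isi_p10", GENERAL, "unit"),
    ("isi_p90", GENERAL, "unit"),
    ("log_isi_mean", GENERAL, "unit"),
    ("log_isi_sd", GENERAL, "unit"),
    # burst timing
    ("burst_rate", GENERAL, "unit"),
    ("burst_period", GENERAL, "unit"),
    ("burst_period_median", GENERAL, "unit"),
    ("burst_period_cv", GENERAL, "unit"),
    ("burst_period_min", GENERAL, "unit"),
    ("burst_period_max", GENERAL, "unit"),
    ("burst_duty_fraction", GENERAL, "unit"),
    # burst composition (statistics over per-burst scalars)
    ("burst_duration", BURST, "burst"),
    ("burst_duration_median", BURST, "burst"),
    ("burst_duration_cv", BURST, "burst"),
    ("burst_duration_min", BURST, "burst"),
    ("burst_duration_max", BURST, "burst"),
    ("spikes_in_burst", BURST, "burst"),
    ("spikes_in_burst_median", BURST, "burst"),
    ("spikes_in_burst_cv", BURST, "burst"),
    ("spikes_in_burst_min", BURST, "burst"),
    ("spikes_in_burst_max", BURST, "burst"),
    ("burst_spike_density", BURST, "burst"),
    ("burst_spike_density_median", BURST, "burst"),
    ("burst_spike_density_cv", BURST, "burst"),
    ("burst_spike_rate", BURST, "burst"),
    ("burst_spike_rate_median", BURST, "burst"),
    ("burst_spike_rate_cv", BURST, "burst"),
    ("intra_burst_isi", BURST, "burst"),
    ("intra_burst_isi_median", BURST, "burst"),
    ("intra_burst_isi_cv", BURST, "burst"),
    ("intra_burst_isi_min", BURST, "burst"),
    ("intra_burst_isi_max", BURST, "burst"),
    ("burst_onset_isi", BURST, "burst"),
    ("burst_offset_isi", BURST, "burst"),
    ("burst_isi_trend", BURST, "burst"),
    ("burst_symmetry", BURST, "burst"),
)

PROFILE_PRIMARIES: tuple[str, ...] = (
    "burst_amplitude",
    "burst_area",
    "burst_plateau",
    "burst_rise_time",
    "burst_half_width",
    "burst_profile_duration",
    "burst_profile_skew",
    "burst_peak_mean_ratio",
)

NETWORK_FEATURES: tuple[tuple[str, str], ...] = (
    ("syn_all", SYNC),
    ("syn_share", SYNC),
    ("event_rate", SYNC),
    ("hamming_factor", SYNC),
    ("pop_burst_rate", SYNC),
    ("pop_burst_duration", SYNC),
    ("pop_burst_duration_cv", SYNC),
    ("pop_burst_spikes", SYNC),
    ("pop_burst_period", SYNC),
    ("pop_burst_period_cv", SYNC),
    ("pop_burst_participation_cv", SYNC),
    ("active_unit_fraction", GENERAL),
)

#: The twelve headline parameters, one canonical name each.
NAMED_12 = (
    "spike_rate",
    "burst_rate",
    "spike_contrast",
    "burst_duration",
    "burst_amplitude",
    "burst_spike_density",
    "burst_rate_sd",
    "syn_all",
    "syn_share",
    "burst_rate_cvnet",
    "event_rate",
    "hamming_factor",
)


def registry() -> list[tuple[str, str]]:
    """Ordered ``(feature name, category)`` pairs of the default registry."""
    out: list[tuple[str, str]] = []
    for name, cat, _level in BINNABLE_PRIMARIES:
        out.append((name, cat))
        out.append((f"{name}_sd", OSC))
        out.append((f"{name}_cvtime", OSC))
        out.append((f"{name}_cvnet", SYNC))
    for name in PROFILE_PRIMARIES:
        out.append((name, BURST))
        out.append((f"{name}_cvnet", SYNC))
    out.extend(NETWORK_FEATURES)
    return out


_REGISTRY = registry()
_NAMES = [n for n, _ in _REGISTRY]
assert len(_REGISTRY) == 204, f"registry has {len(_REGISTRY)} entries, expected 204"
assert len(set(_NAMES)) == 204, "registry names are not unique"
assert all(n in _NAMES for n in NAMED_12)


def feature_names() -> list[str]:
    return list(_NAMES)


@dataclass(frozen=True)
class ParameterTable:
    """Ordered 204-feature description of one network.

    Missing values (features undefined on a degenerate recording, e.g.
    burst statistics of a network without bursts) are recorded as NaN, not
    zero, so downstream standardization can impute them explicitly.
    """

    network_id: str
    features: Mapping[str, float]
    categories: Mapping[str, str] = field(default_factory=lambda: dict(_REGISTRY))
    registry_version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        feats = dict(self.features)
        if list(feats) != _NAMES:
            raise ValueError(
                "feature map does not match the registry (names or order differ)"
            )
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "categories", dict(self.categories))

    def __len__(self) -> int:
        return len(self.features)

    def to_series(self) -> pd.Series:
        return pd.Series(self.features, name=self.network_id, dtype=float)

    def values(self) -> np.ndarray:
        return np.array(list(self.features.values()), dtype=float)


def feature_frame(tables: list[ParameterTable]) -> pd.DataFrame:
    """One row per network, one column per registry feature."""
    versions = {t.registry_version for t in tables}
    if len(versions) > 1:
        raise ValueError(f"mixed registry versions: {sorted(versions)}")
    return pd.DataFrame([t.to_series() for t in tables])


def category_manifest() -> pd.DataFrame:
    return pd.DataFrame(_REGISTRY, columns=["feature", "category"])
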