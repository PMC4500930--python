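"""Seeded generator of developing cortical-network spike activity.

The generative model emulates multiwell MEA cultures of differentiating
cortical networks:

* network-wide **population events** arrive as a homogeneous Poisson
  process; each unit joins an event with a fixed participation probability
  and starts a burst at the event time plus Gaussian onset jitter — this is
  the knob controlling synchrony;
* each burst carries a shifted-Poisson spike count (floor of 2 spikes) with
  gamma-distributed intra-burst ISIs;
* units additionally emit independent (non-population) bursts and tonic
  background spikes as Poisson processes.

Defaults are calibrated to reported scales for such cultures at two weeks
in vitro: per-unit burst rates around 6 per minute, burst durations of
roughly 100–500 ms, unit spike rates of 0.5–5 Hz.  The ``DIV28_MATURATION``
multiplier set approximates four weeks in vitro (spiking roughly tripled,
bursting roughly doubled).  Treatment effects are expressed as
multiplicative factors on named generator fields.

Everything is reproducible: per-network random streams derive from one base
seed, so cohorts are identical across runs and independent of generation
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import NetworkRecording, SpikeTrain

__all__ = [
    "SynthConfig",
    "SPIKE_DRIVERS",
    "DIV28_MATURATION",
    "generate_network",
    "generate_cohort",
]

#: Generator fields that directly scale the overall spike rate.
SPIKE_DRIVERS = ("pop_event_rate", "spikes_per_burst_mean", "background_rate")

#: Multiplier set approximating maturation from 14 to 28 days in vitro:
#: population event rate x2 (bursting roughly doubles), spikes per burst
#: x1.5 (with the rate, burst spiking roughly triples), background x3.
DIV28_MATURATION: Mapping[str, float] = {
    "pop_event_rate": 2.0,
    "spikes_per_burst_mean": 1.5,
    "background_rate": 3.0,
}

_MULTIPLIABLE = (
    "pop_event_rate",
    "participation_prob",
    "onset_jitter_sd",
    "spikes_per_burst_mean",
    "background_rate",
    "independent_burst_rate",
    "intra_burst_isi_mean",
)


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one network recording."""

    n_units: int = 24
    duration: float = 1_800_000.0  # ms (30 min)
    pop_event_rate: float = 0.1  # Hz, network-wide population events
    participation_prob: float = 0.8
    onset_jitter_sd: float = 50.0  # ms
    spikes_per_burst_mean: float = 12.0  # shifted Poisson, floor 2
    intra_burst_isi_shape: float = 2.0  # gamma shape
    intra_burst_isi_mean: float = 15.0  # ms
    background_rate: float = 0.3  # Hz per unit
    independent_burst_rate: float = 0.02  # Hz per unit
    maturation_scale: Mapping[str, float] = field(default_factory=dict)
    treatment_multipliers: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.pop_event_rate,
            self.background_rate,
            self.independent_burst_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if not (0.0 <= self.participation_prob <= 1.0):
            raise ValueError("participation_prob must be in [0, 1]")
        if self.spikes_per_burst_mean < 2.0:
            raise ValueError("spikes_per_burst_mean has a floor of 2 spikes")
        if self.n_units < 1 or self.duration <= 0:
            raise ValueError("need n_units >= 1 and duration > 0")
        object.__setattr__(self, "maturation_scale", dict(self.maturation_scale))
        object.__setattr__(self, "treatment_multipliers", dict(self.treatment_multipliers))

    def with_multipliers(self, multipliers: Mapping[str, float]) -> "SynthConfig":
        """Return a config with named fields scaled multiplicatively."""
        changes: dict[str, float] = {}
        for name, factor in multipliers.items():
            if name not in _MULTIPLIABLE:
                raise KeyError(
                    f"{name!r} is not a multipliable generator field "
                    f"(choose from {_MULTIPLIABLE})"
                )
            changes[name] = getattr(self, name) * factor
        if "participation_prob" in changes:
            changes["participation_prob"] = min(changes["participation_prob"], 1.0)
        return replace(self, **changes)

    def effective(self) -> "SynthConfig":
        """Config with maturation and treatment multipliers applied."""
        cfg = self
        if self.maturation_scale:
            cfg = cfg.with_multipliers(self.maturation_scale)
        if self.treatment_multipliers:
            cfg = cfg.with_multipliers(self.treatment_multipliers)
        return replace(cfg, maturation_scale={}, treatment_multipliers={})

    @property
    def expected_unit_burst_rate(self) -> float:
        """Hz; population share plus independent bursts."""
        eff = self.effective()
        return eff.pop_event_rate * eff.participation_prob + eff.independent_burst_rate


def _burst_spikes(
    onsets: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Spike times of all bursts with the given onsets, flattened."""
    nb = onsets.size
    if nb == 0:
        return np.zeros(0)
    counts = 2 + rng.poisson(cfg.spikes_per_burst_mean - 2.0, size=nb)
    n_isis = counts - 1
    total = int(n_isis.sum())
    scale = cfg.intra_burst_isi_mean / cfg.intra_burst_isi_shape
    flat = rng.gamma(cfg.intra_burst_isi_shape, scale, size=total)
    # per-burst cumulative sums without a Python loop
    cs = np.cumsum(flat)
    stops = np.cumsum(n_isis)
    seg_start = stops - n_isis
    base = np.concatenate([[0.0], cs])[seg_start]
    offsets = cs - np.repeat(base, n_isis)
    spikes_from_isis = np.repeat(onsets, n_isis) + offsets
    return np.concatenate([onsets, spikes_from_isis])


def generate_network(
    config: SynthConfig,
    seed: int | np.random.SeedSequence | None = None,
    network_id: str = "net0",
    meta: Mapping[str, object] | None = None,
    return_truth: bool = False,
):
    """Simulate one network recording; reproducible per seed.

    ``seed`` defaults to ``config.seed``.  With ``return_truth=True`` a
    ground-truth side-car dict (population event times, per-unit burst
    onsets) is returned alongside the recording for oracle tests.
    """
    cfg = config.effective()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dur_s = cfg.duration / 1000.0

    n_events = rng.poisson(cfg.pop_event_rate * dur_s)
    event_times = np.sort(rng.uniform(0.0, cfg.duration, size=n_events))

    trains = []
    truth_onsets: dict[str, np.ndarray] = {}
    width = max(2, len(str(cfg.n_units - 1)))
    for u in range(cfg.n_units):
        joins = rng.random(n_events) < cfg.participation_prob
        onsets = event_times[joins]
        if cfg.onset_jitter_sd > 0:
            onsets = onsets + rng.normal(0.0, cfg.onset_jitter_sd, size=onsets.size)
        n_ind = rng.poisson(cfg.independent_burst_rate * dur_s)
        ind_onsets = rng.uniform(0.0, cfg.duration, size=n_ind)
        all_onsets = np.sort(np.concatenate([onsets, ind_onsets]))
        spikes = _burst_spikes(all_onsets, cfg, rng)
        n_bg = rng.poisson(cfg.background_rate * dur_s)
        bg = rng.uniform(0.0, cfg.duration, size=n_bg)
        times = np.concatenate([spikes, bg])
        times = times[(times >= 0.0) & (times < cfg.duration)]
        times = np.unique(times)  # de-duplicate exact collisions
        uid = f"u{u:0{width}d}"
        trains.append(
            SpikeTrain(uid, times, (0.0, cfg.duration), electrode_id=f"e{u:0{width}d}")
        )
        truth_onsets[uid] = all_onsets
    rec = NetworkRecording(network_id, tuple(trains), dict(meta or {}))
    if return_truth:
        return rec, {"event_times": event_times, "burst_onsets": truth_onsets}
    return rec


def generate_cohort(
    control: SynthConfig,
    treatment_multipliers: Mapping[str, float],
    n_per_group: int,
    base_seed: int,
    div: int | None = None,
) -> tuple[list[NetworkRecording], list[NetworkRecording]]:
    """Paired control/treatment cohorts with derived per-network seeds."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    treated = control.with_multipliers(treatment_multipliers)
    children = np.random.SeedSequence(base_seed).spawn(2 * n_per_group)
    ctrl, treat = [], []
    for i in range(n_per_group):
        meta_c = {"group": "control", "div": div, "well": f"c{i:02d}"}
        meta_t = {"group": "treatment", "div": div, "well": f"t{i:02d}"}
        ctrl.append(
            generate_network(control, seed=children[i], network_id=f"ctrl{i:02d}", meta=meta_c)
        )
        treat.append(
            generate_network(
                treated,
                seed=children[n_per_group + i],
                network_id=f"treat{i:02d}",
                meta=meta_t,
            )
        )
    return ctrl, treat
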