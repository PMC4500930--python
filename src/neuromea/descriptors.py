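"""Multiparametric descriptors of network activity.

Computes the four-category description of one network recording — general
activity, burst structure, synchronization and oscillation — from its spike
trains and detected single-unit bursts, and assembles the full 204-feature
:class:`~neuromea.registry.ParameterTable`.

Statistic conventions (documented because the field's verbal definitions
leave them open):

* Sample standard deviations use the n−1 convention everywhere; a
  coefficient of variation (CV) is sd/mean and is NaN when fewer than two
  values exist or the mean is zero.
* Unit-level statistics are averaged over units; statistics of per-burst
  scalars (duration, spikes per burst, ...) are pooled over all bursts of
  the network.
* An interspike interval belongs to the bin that contains its leading
  spike; a burst belongs to the bin that contains its first spike.
* Features that are undefined on a given recording are NaN, never zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bursts import Burst, BurstCriteria, detect_bursts_network
from .core import NetworkRecording, bin_edges, n_complete_bins
from .registry import (
    BINNABLE_PRIMARIES,
    NETWORK_FEATURES,
    PROFILE_PRIMARIES,
    ParameterTable,
    feature_names,
)

__all__ = [
    "DescriptorConfig",
    "PopulationBurst",
    "detect_population_bursts",
    "general_activity",
    "burst_structure",
    "synchronization",
    "oscillation",
    "hamming_factor",
    "cvnet",
    "network_spike_rate",
    "assemble_features",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable constants of the descriptor engine (times in ms)."""

    bin_width: float = 60_000.0
    contrast_segment: float = 500.0
    amplitude_kernel_bandwidth: float = 10.0
    event_window: float = 300.0
    event_unit_fraction: float = 0.5
    hamming_bin: float = 10_000.0
    population_burst_fraction: float = 0.5

    def __post_init__(self) -> None:
        pos = (
            self.bin_width,
            self.contrast_segment,
            self.amplitude_kernel_bandwidth,
            self.event_window,
            self.hamming_bin,
        )
        if any(v <= 0 for v in pos):
            raise ValueError("all durations must be positive")
        for frac in (self.event_unit_fraction, self.population_burst_fraction):
            if not (0.0 < frac <= 1.0):
                raise ValueError("unit fractions must be in (0, 1]")


# --------------------------------------------------------------------------
# elementary statistics

def _sd(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(np.std(x, ddof=1)) if x.size >= 2 else math.nan


def _cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return math.nan
    m = float(np.mean(x))
    if m == 0.0:
        return math.nan
    return float(np.std(x, ddof=1)) / m


def _nanmean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return float(np.mean(x)) if x.size else math.nan



def _nanmean_cols(M: np.ndarray) -> np.ndarray:
    """Column-wise nanmean that is quiet on all-NaN columns."""
    if M.size == 0:
        return np.zeros(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(M, axis=0)

def _stats5(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """mean, median, cv, min, max of a scalar sample (NaN when empty)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return (math.nan,) * 5
    return (
        float(np.mean(x)),
        float(np.median(x)),
        _cv(x),
        float(np.min(x)),
        float(np.max(x)),
    )


# --------------------------------------------------------------------------
# per-burst scalars and the statistics built on them

def _burst_scalars(bursts: Sequence[Burst]) -> dict[str, np.ndarray]:
    dur = np.array([b.duration for b in bursts], dtype=float)
    nsp = np.array([b.n_spikes for b in bursts], dtype=float)
    onset = np.empty(len(bursts))
    offset = np.empty(len(bursts))
    mean_isi = np.empty(len(bursts))
    symmetry = np.empty(len(bursts))
    for k, b in enumerate(bursts):
        isis = b.intra_isis()
        onset[k] = isis[0]
        offset[k] = isis[-1]
        mean_isi[k] = float(np.mean(isis))
        symmetry[k] = (float(np.median(b.spike_times)) - b.start) / b.duration
    with np.errstate(divide="ignore", invalid="ignore"):
        density = 1000.0 / mean_isi  # Hz; mean ISI in ms
        spike_rate = 1000.0 * nsp / dur
    return {
        "duration": dur,
        "n_spikes": nsp,
        "density": density,
        "spike_rate": spike_rate,
        "mean_isi": mean_isi,
        "onset_isi": onset,
        "offset_isi": offset,
        "trend": offset - onset,
        "symmetry": symmetry,
    }


def _burst_level_stats(bursts: Sequence[Burst]) -> dict[str, float]:
    """The 25 burst-composition primaries from a pooled burst list."""
    out: dict[str, float] = {}
    if not bursts:
        sc = {k: np.zeros(0) for k in (
            "duration", "n_spikes", "density", "spike_rate", "mean_isi",
            "onset_isi", "offset_isi", "trend", "symmetry")}
    else:
        sc = _burst_scalars(bursts)
    m, md, cv, mn, mx = _stats5(sc["duration"])
    out.update(
        burst_duration=m, burst_duration_median=md, burst_duration_cv=cv,
        burst_duration_min=mn, burst_duration_max=mx,
    )
    m, md, cv, mn, mx = _stats5(sc["n_spikes"])
    out.update(
        spikes_in_burst=m, spikes_in_burst_median=md, spikes_in_burst_cv=cv,
        spikes_in_burst_min=mn, spikes_in_burst_max=mx,
    )
    m, md, cv, _, _ = _stats5(sc["density"])
    out.update(
        burst_spike_density=m, burst_spike_density_median=md,
        burst_spike_density_cv=cv,
    )
    m, md, cv, _, _ = _stats5(sc["spike_rate"])
    out.update(
        burst_spike_rate=m, burst_spike_rate_median=md, burst_spike_rate_cv=cv,
    )
    m, md, cv, mn, mx = _stats5(sc["mean_isi"])
    out.update(
        intra_burst_isi=m, intra_burst_isi_median=md, intra_burst_isi_cv=cv,
        intra_burst_isi_min=mn, intra_burst_isi_max=mx,
    )
    out["burst_onset_isi"] = _nanmean(sc["onset_isi"])
    out["burst_offset_isi"] = _nanmean(sc["offset_isi"])
    out["burst_isi_trend"] = _nanmean(sc["trend"])
    out["burst_symmetry"] = _nanmean(sc["symmetry"])
    return out


# --------------------------------------------------------------------------
# unit-level primaries over an arbitrary time span

def _segment_counts(times: np.ndarray, start: float, length: float, seg: float) -> np.ndarray:
    nseg = int(math.floor(length / seg + 1e-9))
    if nseg < 1:
        return np.zeros(0, dtype=np.int64)
    edges = start + seg * np.arange(nseg + 1)
    idx = np.searchsorted(edges, times, side="right") - 1
    ok = (idx >= 0) & (idx < nseg) & (times < edges[-1])
    return np.bincount(idx[ok], minlength=nseg).astype(np.int64)


def _contrast(counts: np.ndarray) -> float:
    """Mean neighbour contrast |n_i − n_{i+1}| / (n_i + n_{i+1})."""
    if counts.size < 2:
        return math.nan
    a, b = counts[:-1].astype(float), counts[1:].astype(float)
    s = a + b
    ok = s > 0
    if not ok.any():
        return math.nan
    return float(np.mean(np.abs(a[ok] - b[ok]) / s[ok]))


def _fano(counts: np.ndarray) -> float:
    if counts.size < 2:
        return math.nan
    m = float(np.mean(counts))
    if m == 0.0:
        return math.nan
    return float(np.var(counts, ddof=1)) / m


def _unit_level_stats(
    spikes: np.ndarray,
    isis: np.ndarray,
    bursts: Sequence[Burst],
    span_start: float,
    span_len: float,
    cfg: DescriptorConfig,
) -> dict[str, float]:
    """The 19 unit-level primaries for one unit within one time span."""
    span_s = span_len / 1000.0
    n = spikes.size
    out: dict[str, float] = {}
    out["spike_rate"] = n / span_s
    burst_spikes = sum(b.n_spikes for b in bursts)
    out["tonic_spike_rate"] = max(n - burst_spikes, 0) / span_s
    out["burst_spike_fraction"] = (burst_spikes / n) if n > 0 else math.nan
    seg_counts = _segment_counts(spikes, span_start, span_len, cfg.contrast_segment)
    out["spike_contrast"] = _contrast(seg_counts)
    out["fano_factor"] = _fano(seg_counts)
    if isis.size:
        out["isi_mean"] = float(np.mean(isis))
        out["isi_median"] = float(np.median(isis))
        out["isi_cv"] = _cv(isis)
        out["isi_p10"] = float(np.percentile(isis, 10))
        out["isi_p90"] = float(np.percentile(isis, 90))
        logs = np.log(isis)
        out["log_isi_mean"] = float(np.mean(logs))
        out["log_isi_sd"] = _sd(logs)
    else:
        for k in ("isi_mean", "isi_median", "isi_cv", "isi_p10", "isi_p90",
                  "log_isi_mean", "log_isi_sd"):
            out[k] = math.nan
    out["burst_rate"] = len(bursts) / span_s
    if len(bursts) >= 2:
        starts = np.array([b.start for b in bursts])
        ends = np.array([b.end for b in bursts])
        gaps = starts[1:] - ends[:-1]
        m, md, cv, mn, mx = _stats5(gaps)
    else:
        m = md = cv = mn = mx = math.nan
    out.update(
        burst_period=m, burst_period_median=md, burst_period_cv=cv,
        burst_period_min=mn, burst_period_max=mx,
    )
    out["burst_duty_fraction"] = sum(b.duration for b in bursts) / span_len
    return out


_UNIT_LEVEL = [n for n, _c, lvl in BINNABLE_PRIMARIES if lvl == "unit"]
_BURST_LEVEL = [n for n, _c, lvl in BINNABLE_PRIMARIES if lvl == "burst"]
_ALL_PRIMARIES = [n for n, _c, _l in BINNABLE_PRIMARIES]


def _per_bin_matrix(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig,
) -> dict[str, np.ndarray]:
    """All 44 binnable primaries per unit and complete 60 s bin."""
    edges = bin_edges(rec.window, cfg.bin_width)
    nb = edges.size - 1
    nu = rec.n_units
    mats = {name: np.full((nu, nb), np.nan) for name in _ALL_PRIMARIES}
    for u, tr in enumerate(rec.trains):
        ts = tr.spike_times
        isi = np.diff(ts)
        bursts = bursts_by_unit[tr.unit_id]
        bstarts = np.array([b.start for b in bursts])
        spike_lo = np.searchsorted(ts, edges[:-1], side="left")
        spike_hi = np.searchsorted(ts, edges[1:], side="left")
        b_lo = np.searchsorted(bstarts, edges[:-1], side="left")
        b_hi = np.searchsorted(bstarts, edges[1:], side="left")
        for b in range(nb):
            spikes = ts[spike_lo[b] : spike_hi[b]]
            # ISIs whose leading spike falls in this bin
            isis = isi[spike_lo[b] : min(spike_hi[b], isi.size)]
            bl = bursts[b_lo[b] : b_hi[b]]
            row = _unit_level_stats(
                spikes, isis, bl, edges[b], cfg.bin_width, cfg
            )
            row.update(_burst_level_stats(bl))
            for name, val in row.items():
                mats[name][u, b] = val
    return mats


# --------------------------------------------------------------------------
# burst rate profile (amplitude / area / plateau family)

_PROFILE_DT = 1.0  # ms grid
_PROFILE_MAX_OFFSET = 3000.0  # ms; spikes later than this after onset are ignored


def _profile_scalars(profile: np.ndarray, t0: float) -> dict[str, float]:
    """Shape scalars of one onset-aligned rate profile (grid origin t0 ms)."""
    if profile.size == 0 or not np.any(profile > 0):
        return {name: math.nan for name in PROFILE_PRIMARIES}
    p = int(np.argmax(profile))
    amp = float(profile[p])
    area = float(np.sum(profile)) * _PROFILE_DT / 1000.0  # spikes per burst

    def _contig_width(level: float) -> tuple[int, int]:
        above = profile >= level
        lo = p
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = p
        while hi < profile.size - 1 and above[hi + 1]:
            hi += 1
        return lo, hi

    lo9, hi9 = _contig_width(0.9 * amp)
    lo5, hi5 = _contig_width(0.5 * amp)
    lo1, hi1 = _contig_width(0.1 * amp)
    support_ms = (hi1 - lo1 + 1) * _PROFILE_DT
    before = float(np.sum(profile[:p]))
    after = float(np.sum(profile[p + 1 :]))
    total = before + after + amp
    mean_rate = float(np.sum(profile[lo1 : hi1 + 1])) / (hi1 - lo1 + 1)
    return {
        "burst_amplitude": amp,
        "burst_area": area,
        "burst_plateau": (hi9 - lo9 + 1) * _PROFILE_DT,
        "burst_rise_time": t0 + p * _PROFILE_DT,
        "burst_half_width": (hi5 - lo5 + 1) * _PROFILE_DT,
        "burst_profile_duration": support_ms,
        "burst_profile_skew": (after - before) / total if total > 0 else math.nan,
        "burst_peak_mean_ratio": amp / mean_rate if mean_rate > 0 else math.nan,
    }


def burst_profiles(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig,
) -> tuple[float, np.ndarray]:
    """Per-unit mean onset-aligned burst rate profiles (spikes/s).

    Returns ``(t0, profiles)`` where ``profiles`` has one row per unit (NaN
    rows for units without bursts) on a 1 ms grid starting at ``t0`` ms
    relative to burst onset.
    """
    bw = cfg.amplitude_kernel_bandwidth
    pad = 4.0 * bw
    max_dur = 0.0
    for bl in bursts_by_unit.values():
        for b in bl:
            max_dur = max(max_dur, min(b.duration, _PROFILE_MAX_OFFSET))
    t0 = -pad
    t1 = max_dur + pad
    npts = max(int(math.ceil((t1 - t0) / _PROFILE_DT)), 1)
    grid_edges = t0 + _PROFILE_DT * np.arange(npts + 1)
    profiles = np.full((rec.n_units, npts), np.nan)
    sigma = bw / _PROFILE_DT
    for u, tr in enumerate(rec.trains):
        bl = bursts_by_unit[tr.unit_id]
        if not bl:
            continue
        acc = np.zeros(npts)
        for b in bl:
            offs = b.spike_times - b.start
            offs = offs[offs <= _PROFILE_MAX_OFFSET]
            hist, _ = np.histogram(offs, bins=grid_edges)
            acc += hist
        counts_per_ms = acc / len(bl)
        smoothed = gaussian_filter1d(counts_per_ms, sigma=sigma, mode="constant")
        profiles[u] = smoothed * 1000.0  # spikes/s
    return t0, profiles


# --------------------------------------------------------------------------
# population bursts and synchrony

@dataclass(frozen=True)
class PopulationBurst:
    """Near-simultaneous bursting across a required fraction of units."""

    interval: tuple[float, float]
    member_bursts: tuple[tuple[str, Burst], ...]
    participating_units: frozenset[str]
    center: float
    n_units_total: int

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def participation(self) -> float:
        return len(self.participating_units) / self.n_units_total

    @property
    def n_spikes(self) -> int:
        return int(sum(b.n_spikes for _u, b in self.member_bursts))


def detect_population_bursts(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig,
    fraction: float | None = None,
    window_ms: float | None = None,
) -> list[PopulationBurst]:
    """Detect population bursts with a sliding-window coincidence count.

    ``B(t)`` is the number of units with a burst overlapping the window
    ``[t, t + w)``; a population burst is a maximal region with
    ``B(t)/N >= fraction`` (overlapping regions merge).  The same detector
    at fraction 0.5 and window 300 ms defines the events behind
    ``event_rate``.
    """
    frac = cfg.population_burst_fraction if fraction is None else fraction
    w = cfg.event_window if window_ms is None else window_ms
    N = rec.n_units
    threshold = max(int(math.ceil(frac * N - 1e-9)), 1)

    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for tr in rec.trains:
        bl = bursts_by_unit[tr.unit_id]
        if not bl:
            continue
        s = np.array([b.start for b in bl]) - w
        e = np.array([b.end for b in bl])
        # merge this unit's coverage intervals so it counts at most once
        ms, me = [s[0]], [e[0]]
        for k in range(1, s.size):
            if s[k] <= me[-1]:
                me[-1] = max(me[-1], e[k])
            else:
                ms.append(s[k])
                me.append(e[k])
        starts.append(np.array(ms))
        ends.append(np.array(me))
    if not starts:
        return []
    ev_t = np.concatenate(starts + ends)
    ev_d = np.concatenate(
        [np.ones(a.size, dtype=int) for a in starts]
        + [-np.ones(a.size, dtype=int) for a in ends]
    )
    order = np.lexsort((ev_d, ev_t))  # time asc; ends (-1) before starts (+1)
    ev_t, ev_d = ev_t[order], ev_d[order]
    count = 0
    regions: list[tuple[float, float]] = []
    open_t = None
    for t, d in zip(ev_t, ev_d):
        count += d
        if open_t is None and count >= threshold:
            open_t = t
        elif open_t is not None and count < threshold:
            regions.append((open_t, t))
            open_t = None
    if open_t is not None:
        regions.append((open_t, ev_t[-1]))

    win0, win1 = rec.window
    intervals: list[tuple[float, float]] = []
    for t0, t1 in regions:
        lo = max(t0, win0)
        hi = min(t1 + w, win1)
        if intervals and lo <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
        else:
            intervals.append((lo, hi))

    out: list[PopulationBurst] = []
    for lo, hi in intervals:
        members: list[tuple[str, Burst]] = []
        for tr in rec.trains:
            for b in bursts_by_unit[tr.unit_id]:
                if b.start <= hi and b.end >= lo:
                    members.append((tr.unit_id, b))
        if not members:
            continue
        mids = np.array([b.midpoint for _u, b in members])
        wts = np.array([b.n_spikes for _u, b in members], dtype=float)
        center = float(np.average(mids, weights=wts))
        out.append(
            PopulationBurst(
                interval=(lo, hi),
                member_bursts=tuple(members),
                participating_units=frozenset(u for u, _b in members),
                center=center,
                n_units_total=N,
            )
        )
    return out


def hamming_factor(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig,
) -> float:
    """Mean pairwise similarity of binary per-bin burst-occupancy vectors.

    Each unit is reduced to a {0,1} vector over ``hamming_bin`` bins (1 if
    any burst overlaps the bin); the factor is the mean over unit pairs of
    the fraction of agreeing bins: 1 − hamming distance / number of bins.
    """
    if rec.n_units < 2:
        return math.nan
    nb = n_complete_bins(rec.window, cfg.hamming_bin)
    if nb < 1:
        return math.nan
    edges = rec.window[0] + cfg.hamming_bin * np.arange(nb + 1)
    M = np.zeros((rec.n_units, nb))
    for u, tr in enumerate(rec.trains):
        for b in bursts_by_unit[tr.unit_id]:
            lo = int(np.searchsorted(edges, b.start, side="right")) - 1
            hi = int(np.searchsorted(edges, b.end, side="right")) - 1
            lo = max(lo, 0)
            hi = min(hi, nb - 1)
            if hi >= lo:
                M[u, lo : hi + 1] = 1.0
    agree = M @ M.T + (1.0 - M) @ (1.0 - M).T
    iu = np.triu_indices(rec.n_units, k=1)
    return float(np.mean(agree[iu]) / nb)


def cvnet(per_unit_values: np.ndarray) -> float:
    """Coefficient of variation of a per-unit feature across the network."""
    return _cv(np.asarray(per_unit_values, dtype=float))


# --------------------------------------------------------------------------
# the four category operations

def _unit_whole_stats(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig,
) -> dict[str, np.ndarray]:
    """Per-unit stable-phase values of all 44 binnable primaries."""
    vals = {name: np.full(rec.n_units, np.nan) for name in _ALL_PRIMARIES}
    t0, t1 = rec.window
    for u, tr in enumerate(rec.trains):
        bl = bursts_by_unit[tr.unit_id]
        row = _unit_level_stats(tr.spike_times, tr.isis(), bl, t0, t1 - t0, cfg)
        row.update(_burst_level_stats(bl))
        for name, v in row.items():
            vals[name][u] = v
    return vals


def network_spike_rate(rec: NetworkRecording) -> float:
    """Spike rate (Hz): spikes per second per unit, averaged over units.

    Equals the ``spike_rate`` registry entry (the per-bin average collapses
    to the whole-window rate when complete bins tile the window), but needs
    no burst detection — convenient for rate-only screens.
    """
    dur_s = rec.duration_ms / 1000.0
    return float(np.mean([tr.n_spikes / dur_s for tr in rec.trains]))


def general_activity(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig | None = None,
) -> dict[str, float]:
    """Spike rate (Hz), burst rate (Hz), spike contrast, burst period (ms)."""
    cfg = cfg or DescriptorConfig()
    vals = _unit_whole_stats(rec, bursts_by_unit, cfg)
    return {
        "spike_rate": _nanmean(vals["spike_rate"]),
        "burst_rate": _nanmean(vals["burst_rate"]),
        "spike_contrast": _nanmean(vals["spike_contrast"]),
        "burst_period": _nanmean(vals["burst_period"]),
    }


def burst_structure(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig | None = None,
) -> dict[str, float]:
    """Pooled burst-composition scalars plus the profile family."""
    cfg = cfg or DescriptorConfig()
    all_bursts = [b for bl in bursts_by_unit.values() for b in bl]
    pooled = _burst_level_stats(all_bursts)
    t0, profiles = burst_profiles(rec, bursts_by_unit, cfg)
    mean_profile = (
        _nanmean_cols(profiles) if np.any(~np.isnan(profiles)) else np.zeros(0)
    )
    prof = _profile_scalars(np.nan_to_num(mean_profile, nan=0.0), t0)
    return {
        "burst_duration": pooled["burst_duration"],
        "burst_amplitude": prof["burst_amplitude"],
        "burst_spike_density": pooled["burst_spike_density"],
        "burst_area": prof["burst_area"],
        "burst_plateau": prof["burst_plateau"],
        "spikes_in_burst": pooled["spikes_in_burst"],
    }


def synchronization(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig | None = None,
) -> dict[str, float]:
    """Population-burst synchrony measures and the Hamming factor."""
    cfg = cfg or DescriptorConfig()
    pbs = detect_population_bursts(rec, bursts_by_unit, cfg)
    dur_s = rec.duration_ms / 1000.0
    if pbs:
        syn_all = float(
            np.mean(
                [
                    np.mean([abs(b.midpoint - pb.center) for _u, b in pb.member_bursts])
                    for pb in pbs
                ]
            )
        )
        syn_share = float(np.mean([pb.participation for pb in pbs]))
    else:
        syn_all = math.nan
        syn_share = math.nan
    if (
        cfg.event_unit_fraction == cfg.population_burst_fraction
    ):
        events = pbs
    else:
        events = detect_population_bursts(
            rec, bursts_by_unit, cfg, fraction=cfg.event_unit_fraction
        )
    return {
        "syn_all": syn_all,
        "syn_share": syn_share,
        "event_rate": len(events) / dur_s,
        "hamming_factor": hamming_factor(rec, bursts_by_unit, cfg),
    }


def oscillation(
    rec: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    cfg: DescriptorConfig | None = None,
) -> dict[str, float]:
    """Across-bin SD and CVtime of the primary rate parameters.

    Higher values mean less regular general activity or burst structure.
    Requires at least two complete bins; otherwise all values are NaN.
    """
    cfg = cfg or DescriptorConfig()
    mats = _per_bin_matrix(rec, bursts_by_unit, cfg)
    out: dict[str, float] = {}
    for name in ("spike_rate", "burst_rate", "burst_duration", "spike_contrast"):
        M = mats[name]
        net_per_bin = _nanmean_cols(M)
        out[f"{name}_sd"] = _sd(net_per_bin)
        out[f"{name}_cvtime"] = _nanmean(
            np.array([_cv(M[u]) for u in range(M.shape[0])])
        )
    return out


# --------------------------------------------------------------------------
# full table assembly

def assemble_features(
    rec: NetworkRecording,
    cfg: DescriptorConfig | None = None,
    criteria: BurstCriteria | None = None,
    bursts_by_unit: dict[str, list[Burst]] | None = None,
) -> ParameterTable:
    """Compute the full 204-feature registry table for one recording.

    Deterministic: two identical recordings yield identical tables.
    Degenerate recordings yield NaN for undefined features.
    """
    cfg = cfg or DescriptorConfig()
    if bursts_by_unit is None:
        bursts_by_unit = detect_bursts_network(rec, criteria or BurstCriteria())

    unit_vals = _unit_whole_stats(rec, bursts_by_unit, cfg)
    all_bursts = [b for bl in bursts_by_unit.values() for b in bl]
    pooled = _burst_level_stats(all_bursts)
    mats = _per_bin_matrix(rec, bursts_by_unit, cfg)

    feats: dict[str, float] = {}
    for name, _cat, level in BINNABLE_PRIMARIES:
        if level == "unit":
            feats[name] = _nanmean(unit_vals[name])
        else:
            feats[name] = pooled[name]
        M = mats[name]
        net_per_bin = _nanmean_cols(M)
        feats[f"{name}_sd"] = _sd(net_per_bin)
        feats[f"{name}_cvtime"] = _nanmean(
            np.array([_cv(M[u]) for u in range(M.shape[0])])
        )
        feats[f"{name}_cvnet"] = cvnet(unit_vals[name])

    # burst profile family: network value from the unit-mean profile,
    # CVnet across per-unit profile scalars
    t0, profiles = burst_profiles(rec, bursts_by_unit, cfg)
    have = ~np.all(np.isnan(profiles), axis=1)
    if have.any():
        mean_profile = _nanmean_cols(profiles[have])
        net_prof = _profile_scalars(mean_profile, t0)
        per_unit_prof = {name: np.full(rec.n_units, np.nan) for name in PROFILE_PRIMARIES}
        for u in np.flatnonzero(have):
            sc = _profile_scalars(profiles[u], t0)
            for name in PROFILE_PRIMARIES:
                per_unit_prof[name][u] = sc[name]
    else:
        net_prof = {name: math.nan for name in PROFILE_PRIMARIES}
        per_unit_prof = {name: np.full(rec.n_units, np.nan) for name in PROFILE_PRIMARIES}
    for name in PROFILE_PRIMARIES:
        feats[name] = net_prof[name]
        feats[f"{name}_cvnet"] = cvnet(per_unit_prof[name])

    # network-level synchrony block
    sync = synchronization(rec, bursts_by_unit, cfg)
    feats["syn_all"] = sync["syn_all"]
    feats["syn_share"] = sync["syn_share"]
    feats["event_rate"] = sync["event_rate"]
    feats["hamming_factor"] = sync["hamming_factor"]

    pbs = detect_population_bursts(rec, bursts_by_unit, cfg)
    dur_s = rec.duration_ms / 1000.0
    feats["pop_burst_rate"] = len(pbs) / dur_s
    if pbs:
        pdur = np.array([pb.duration for pb in pbs])
        feats["pop_burst_duration"] = float(np.mean(pdur))
        feats["pop_burst_duration_cv"] = _cv(pdur)
        feats["pop_burst_spikes"] = float(np.mean([pb.n_spikes for pb in pbs]))
        if len(pbs) >= 2:
            gaps = np.array(
                [pbs[k + 1].interval[0] - pbs[k].interval[1] for k in range(len(pbs) - 1)]
            )
            feats["pop_burst_period"] = float(np.mean(gaps))
            feats["pop_burst_period_cv"] = _cv(gaps)
        else:
            feats["pop_burst_period"] = math.nan
            feats["pop_burst_period_cv"] = math.nan
        feats["pop_burst_participation_cv"] = _cv(
            np.array([pb.participation for pb in pbs])
        )
    else:
        for k in (
            "pop_burst_duration", "pop_burst_duration_cv", "pop_burst_spikes",
            "pop_burst_period", "pop_burst_period_cv", "pop_burst_participation_cv",
        ):
            feats[k] = math.nan
    feats["active_unit_fraction"] = float(
        np.mean([tr.n_spikes > 0 for tr in rec.trains])
    )

    ordered = {name: feats[name] for name in feature_names()}
    return ParameterTable(network_id=rec.network_id, features=ordered)
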