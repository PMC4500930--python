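import math

import numpy as np
import pytest

from neuromea.bursts import Burst, detect_bursts_network
from neuromea.descriptors import (
    DescriptorConfig,
    _burst_level_stats,
    assemble_features,
    burst_structure,
    cvnet,
    detect_population_bursts,
    general_activity,
    hamming_factor,
    oscillation,
    synchronization,
)
from neuromea.registry import CATEGORIES, NAMED_12, feature_names, registry

from conftest import make_recording


class TestGeneralActivity:
    def test_uniform_unit_rate_1hz(self, dcfg):
        times = np.arange(0.0, 300_000.0, 1000.0)  # 1 spike/s for 5 min
        rec = make_recording([times], (0.0, 300_000.0))
        ga = general_activity(rec, detect_bursts_network(rec), dcfg)
        assert ga["spike_rate"] == pytest.approx(1.0)

    def test_spike_rate_averages_over_trains(self, dcfg):
        quiet = np.array([])
        busy = np.arange(0.0, 300_000.0, 500.0)  # 2 Hz
        rec = make_recording([quiet, busy], (0.0, 300_000.0))
        ga = general_activity(rec, detect_bursts_network(rec), dcfg)
        assert ga["spike_rate"] == pytest.approx(1.0)

    def test_spike_rate_matches_recount_on_synthetic(self, dcfg):
        from neuromea.synth import SynthConfig, generate_network
        from oracles import naive_spike_rate

        rec = generate_network(SynthConfig(duration=300_000.0), seed=9)
        ga = general_activity(rec, detect_bursts_network(rec), dcfg)
        assert ga["spike_rate"] == pytest.approx(naive_spike_rate(rec), rel=1e-12)


class TestBurstStructure:
    def test_four_spike_burst_closed_form(self):
        """Burst {0,10,20,30} ms: duration 30 ms, mean ISI 10 ms -> 100 Hz."""
        stats = _burst_level_stats([Burst("u", np.array([0.0, 10.0, 20.0, 30.0]))])
        assert stats["burst_duration"] == pytest.approx(30.0)
        assert stats["burst_spike_density"] == pytest.approx(100.0)
        assert stats["spikes_in_burst"] == pytest.approx(4.0)

    def test_mean_of_two_burst_durations(self):
        stats = _burst_level_stats(
            [
                Burst("u", np.array([0.0, 20.0])),
                Burst("u", np.array([1000.0, 1040.0])),
            ]
        )
        assert stats["burst_duration"] == pytest.approx(30.0)

    def test_density_monotone_in_count_and_duration(self):
        base = _burst_level_stats([Burst("u", np.linspace(0.0, 90.0, 10))])
        more_spikes = _burst_level_stats([Burst("u", np.linspace(0.0, 90.0, 20))])
        shorter = _burst_level_stats([Burst("u", np.linspace(0.0, 45.0, 10))])
        assert more_spikes["burst_spike_density"] > base["burst_spike_density"]
        assert shorter["burst_spike_density"] > base["burst_spike_density"]

    def test_no_bursts_gives_missing_not_zero(self, dcfg):
        rec = make_recording([[100.0, 50_000.0]], (0.0, 60_000.0))
        bs = burst_structure(rec, detect_bursts_network(rec), dcfg)
        assert all(math.isnan(v) for v in bs.values())

    def test_profile_against_direct_kde_oracle(self, dcfg):
        """Amplitude/area of the smoothed profile match a direct Gaussian-sum
        evaluation on regularly spaced spikes."""
        spikes = np.arange(0.0, 80.0, 10.0)  # 8 spikes
        trains = [np.concatenate([spikes + 5000.0 * b for b in range(10)])]
        rec = make_recording(trains, (0.0, 60_000.0))
        bs = burst_structure(rec, detect_bursts_network(rec), dcfg)

        sigma = dcfg.amplitude_kernel_bandwidth
        grid = np.arange(-4 * sigma, 80.0 + 4 * sigma, 0.1)
        dens = np.zeros_like(grid)
        for s in spikes:
            dens += np.exp(-0.5 * ((grid - s) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        oracle_amp = 1000.0 * dens.max()
        oracle_area = np.trapezoid(dens, grid)
        assert bs["burst_amplitude"] == pytest.approx(oracle_amp, rel=0.02)
        assert bs["burst_area"] == pytest.approx(oracle_area, rel=0.02)
        assert bs["burst_area"] == pytest.approx(8.0, rel=0.02)  # spikes per burst


class TestSynchronization:
    def test_perfect_synchrony(self, perfect_sync_recording, dcfg):
        rec = perfect_sync_recording
        sync = synchronization(rec, detect_bursts_network(rec), dcfg)
        assert sync["event_rate"] == pytest.approx(1.0 / 60.0)
        assert sync["syn_share"] == pytest.approx(1.0)
        assert sync["hamming_factor"] == pytest.approx(1.0)
        assert sync["syn_all"] == pytest.approx(0.0, abs=1e-12)

    def test_subthreshold_participation_gives_no_events(self, dcfg):
        burst = [10_000.0 + 10.0 * k for k in range(11)]
        lone = [40_000.0]
        rec = make_recording([burst] * 4 + [lone] * 6, (0.0, 60_000.0))
        sync = synchronization(rec, detect_bursts_network(rec), dcfg)
        assert sync["event_rate"] == 0.0

    def test_raising_event_fraction_never_raises_event_rate(self, dcfg):
        rng = np.random.default_rng(0)
        trains = []
        for _u in range(10):
            onsets = np.sort(rng.uniform(0, 590_000.0, 40))
            trains.append(np.sort(np.concatenate([onsets + d for d in (0.0, 15.0, 30.0)])))
        rec = make_recording(trains, (0.0, 600_000.0))
        bursts = detect_bursts_network(rec)
        rates = []
        for frac in (0.3, 0.5, 0.7, 0.9):
            pbs = detect_population_bursts(rec, bursts, dcfg, fraction=frac)
            rates.append(len(pbs))
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_hamming_independent_occupancy_near_half(self, dcfg):
        """Independent units with p(bin occupied)=0.5 agree on ~50% of bins."""
        rng = np.random.default_rng(123)
        nb = 60  # 10 s bins over 10 min
        trains = []
        for _u in range(12):
            occupied = rng.random(nb) < 0.5
            t = [10_000.0 * b + 100.0 + 10.0 * k for b in range(nb) if occupied[b] for k in range(3)]
            trains.append(t if t else [5.0, 12.0, 19.0])
        rec = make_recording(trains, (0.0, 600_000.0))
        hf = hamming_factor(rec, detect_bursts_network(rec), dcfg)
        # binomial 3-sigma interval for the mean over 66 pairs x 60 bins
        assert abs(hf - 0.5) < 3 * math.sqrt(0.25 / (66 * 60)) * 6  # conservative: pairs correlated
        assert 0.0 <= hf <= 1.0

    def test_cvnet_zero_for_identical_units(self):
        assert cvnet(np.array([3.0, 3.0, 3.0])) == pytest.approx(0.0)


class TestOscillation:
    def test_constant_per_bin_series_cvtime_zero(self, dcfg):
        times = np.arange(500.0, 300_000.0, 1000.0)  # identical rate per bin
        rec = make_recording([times], (0.0, 300_000.0))
        osc = oscillation(rec, detect_bursts_network(rec), dcfg)
        assert osc["spike_rate_cvtime"] == pytest.approx(0.0)

    def test_two_point_sd_convention(self, dcfg):
        # 60 spikes in bin 1, 180 in bin 2 -> rates 1 and 3 Hz, sd = sqrt(2)
        t1 = np.linspace(0.0, 59_999.0, 60)
        t2 = np.linspace(60_000.0, 119_999.0, 180)
        rec = make_recording([np.concatenate([t1, t2])], (0.0, 120_000.0))
        osc = oscillation(rec, detect_bursts_network(rec), dcfg)
        assert osc["spike_rate_sd"] == pytest.approx(np.std([1.0, 3.0], ddof=1))

    def test_single_bin_is_missing(self, dcfg):
        rec = make_recording([[100.0, 200.0]], (0.0, 60_000.0))
        osc = oscillation(rec, detect_bursts_network(rec), dcfg)
        assert math.isnan(osc["spike_rate_sd"])


class TestAssemble:
    def test_registry_contract(self, regular_recording, dcfg):
        tab = assemble_features(regular_recording, dcfg)
        assert len(tab) == 204
        assert list(tab.features) == feature_names()
        assert set(tab.categories.values()) == set(CATEGORIES)
        for name in NAMED_12:
            assert name in tab.features

    def test_deterministic(self, regular_recording, dcfg):
        a = assemble_features(regular_recording, dcfg)
        b = assemble_features(regular_recording, dcfg)
        assert a.features == b.features

    def test_named_parameters_match_standalone_ops(self, regular_recording, dcfg):
        rec = regular_recording
        bursts = detect_bursts_network(rec)
        tab = assemble_features(rec, dcfg, bursts_by_unit=bursts).features
        ga = general_activity(rec, bursts, dcfg)
        bs = burst_structure(rec, bursts, dcfg)
        sync = synchronization(rec, bursts, dcfg)
        osc = oscillation(rec, bursts, dcfg)
        assert tab["spike_rate"] == pytest.approx(ga["spike_rate"], rel=1e-12)
        assert tab["burst_rate"] == pytest.approx(ga["burst_rate"], rel=1e-12)
        assert tab["spike_contrast"] == pytest.approx(ga["spike_contrast"], rel=1e-12)
        assert tab["burst_duration"] == pytest.approx(bs["burst_duration"], rel=1e-12)
        assert tab["burst_amplitude"] == pytest.approx(bs["burst_amplitude"], rel=1e-12)
        assert tab["burst_spike_density"] == pytest.approx(bs["burst_spike_density"], rel=1e-12)
        assert tab["syn_all"] == pytest.approx(sync["syn_all"], rel=1e-12)
        assert tab["syn_share"] == pytest.approx(sync["syn_share"], rel=1e-12)
        assert tab["event_rate"] == pytest.approx(sync["event_rate"], rel=1e-12)
        assert tab["hamming_factor"] == pytest.approx(sync["hamming_factor"], rel=1e-12)
        assert tab["burst_rate_sd"] == pytest.approx(osc["burst_rate_sd"], rel=1e-12)

    def test_invariant_under_unit_relabeling(self, dcfg):
        rng = np.random.default_rng(5)
        trains = [np.sort(rng.uniform(0, 120_000.0, rng.integers(50, 200))) for _ in range(6)]
        window = (0.0, 120_000.0)
        rec_a = make_recording(trains, window)
        from neuromea.core import NetworkRecording, SpikeTrain

        shuffled = tuple(
            SpikeTrain(f"z{k}", t, window) for k, t in enumerate(reversed(trains))
        )
        rec_b = NetworkRecording("net", shuffled)
        va = assemble_features(rec_a, dcfg).values()
        vb = assemble_features(rec_b, dcfg).values()
        np.testing.assert_allclose(va, vb, rtol=1e-10, equal_nan=True)

    def test_degenerate_recording_has_explicit_missing(self, dcfg):
        rec = make_recording([[100.0], []], (0.0, 120_000.0))
        tab = assemble_features(rec, dcfg)
        assert len(tab) == 204
        assert math.isnan(tab.features["burst_duration"])
        assert tab.features["spike_rate"] == pytest.approx(1.0 / 120.0 / 2)


def test_registry_category_partition():
    reg = registry()
    assert len(reg) == 204
    counts = {c: 0 for c in CATEGORIES}
    for _n, c in reg:
        counts[c] += 1
    assert sum(counts.values()) == 204
    assert all(v > 0 for v in counts.values())
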