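import numpy as np
import pytest

from neuromea.bursts import detect_bursts_network
from neuromea.core import NetworkRecording
from neuromea.descriptors import DescriptorConfig, synchronization
from neuromea.synth import (
    DIV28_MATURATION,
    SPIKE_DRIVERS,
    SynthConfig,
    generate_cohort,
    generate_network,
)


class TestGenerate:
    def test_all_rates_zero_gives_empty_trains(self):
        cfg = SynthConfig(
            pop_event_rate=0.0, background_rate=0.0, independent_burst_rate=0.0,
            duration=60_000.0,
        )
        rec = generate_network(cfg, seed=0)
        assert all(t.n_spikes == 0 for t in rec.trains)

    def test_deterministic_per_seed(self):
        cfg = SynthConfig(duration=120_000.0)
        a = generate_network(cfg, seed=42)
        b = generate_network(cfg, seed=42)
        for ta, tb in zip(a.trains, b.trains):
            np.testing.assert_array_equal(ta.spike_times, tb.spike_times)

    def test_output_satisfies_core_invariants(self):
        # NetworkRecording/SpikeTrain constructors enforce the invariants;
        # construction succeeding over several seeds is the test
        for seed in range(5):
            rec = generate_network(SynthConfig(duration=120_000.0), seed=seed)
            assert isinstance(rec, NetworkRecording)
            for t in rec.trains:
                assert np.all(np.diff(t.spike_times) > 0)

    def test_burst_rate_matches_analytic_expectation(self):
        """Detected per-unit burst rate within 3 SE of p_event x participation."""
        cfg = SynthConfig(
            pop_event_rate=0.15, participation_prob=0.9, background_rate=0.0,
            independent_burst_rate=0.0, duration=1_800_000.0,
        )
        rec = generate_network(cfg, seed=123)
        bursts = detect_bursts_network(rec)
        n_bursts = sum(len(b) for b in bursts.values())
        dur_s = 1800.0
        expected = 0.15 * 0.9 * dur_s * cfg.n_units
        # events Poisson, joins binomial: var ~ rate*participation per unit-s
        se = np.sqrt(expected)
        assert abs(n_bursts - expected) < 3 * se + 0.02 * expected  # small merge slack

    def test_perfect_synchrony_construction(self):
        cfg = SynthConfig(
            participation_prob=1.0, onset_jitter_sd=0.0, background_rate=0.0,
            independent_burst_rate=0.0, duration=600_000.0, pop_event_rate=0.05,
        )
        rec = generate_network(cfg, seed=7)
        sync = synchronization(rec, detect_bursts_network(rec), DescriptorConfig())
        assert sync["syn_share"] == pytest.approx(1.0)
        assert sync["hamming_factor"] > 0.97

    def test_jitter_monotonically_degrades_synchrony(self):
        hams = []
        for jitter in (0.0, 100.0, 1000.0):
            vals = []
            for seed in range(3):
                cfg = SynthConfig(
                    onset_jitter_sd=jitter, background_rate=0.0,
                    independent_burst_rate=0.0, duration=300_000.0,
                )
                rec = generate_network(cfg, seed=seed)
                sync = synchronization(rec, detect_bursts_network(rec), DescriptorConfig())
                vals.append(sync["hamming_factor"])
            hams.append(np.mean(vals))
        assert hams[0] > hams[1] > hams[2]

    def test_ground_truth_sidecar(self):
        cfg = SynthConfig(duration=120_000.0)
        rec, truth = generate_network(cfg, seed=3, return_truth=True)
        assert set(truth["burst_onsets"]) == set(rec.unit_ids())
        assert truth["event_times"].size > 0

    def test_maturation_scale_triples_spike_rate(self):
        young = SynthConfig(duration=600_000.0)
        old = SynthConfig(duration=600_000.0, maturation_scale=dict(DIV28_MATURATION))
        ry = generate_network(young, seed=5)
        ro = generate_network(old, seed=6)
        rate = lambda r: np.mean([t.n_spikes / 600.0 for t in r.trains])
        assert rate(ro) / rate(ry) == pytest.approx(3.0, rel=0.15)


class TestCohort:
    def test_same_base_seed_identical(self):
        cfg = SynthConfig(duration=60_000.0, n_units=8)
        c1, t1 = generate_cohort(cfg, {"background_rate": 1.5}, 3, base_seed=9)
        c2, t2 = generate_cohort(cfg, {"background_rate": 1.5}, 3, base_seed=9)
        for a, b in zip(c1 + t1, c2 + t2):
            for ta, tb in zip(a.trains, b.trains):
                np.testing.assert_array_equal(ta.spike_times, tb.spike_times)

    def test_unit_multipliers_give_exchangeable_groups(self):
        from neuromea.stats import compare_groups

        rejections = 0
        for s in range(10):
            c, t = generate_cohort(
                SynthConfig(duration=120_000.0, n_units=8), {}, 4, base_seed=s
            )
            rate = lambda r: np.mean([tr.n_spikes for tr in r.trains])
            r = compare_groups([rate(x) for x in c], [rate(x) for x in t])
            rejections += r.p_value <= 0.05
        assert rejections <= 3  # chance-level rejections only

    def test_unknown_multiplier_field_rejected(self):
        with pytest.raises(KeyError):
            SynthConfig().with_multipliers({"not_a_field": 2.0})

    def test_spike_drivers_are_multipliable(self):
        cfg = SynthConfig().with_multipliers({k: 1.5 for k in SPIKE_DRIVERS})
        assert cfg.pop_event_rate == pytest.approx(0.15)
        assert cfg.background_rate == pytest.approx(0.45)
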