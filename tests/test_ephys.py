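"""Spike-train analytics: rates, binning, ISIs, quality filtering, network
bursts and evoked latencies."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mechanoephys.ephys import (BurstSet, EpochSet, SpikeTrain,
                                binned_firing_rate, detect_network_bursts,
                                epoch_firing_rates, evoked_spike_latency,
                                isi_distribution, mean_firing_rate,
                                percent_rate_change, unit_quality_filter)
from mechanoephys.synthetic import SynthConfig, gen_spike_population


def train(times, span=(0.0, 100.0), uid="u"):
    return SpikeTrain(uid, np.asarray(times, dtype=float), span)


class TestSpikeTrainInvariants:
    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            train([2.0, 1.0])

    def test_duplicates_at_resolution_rejected(self):
        with pytest.raises(ValueError):
            train([1.0, 1.0])

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            train([150.0])


class TestRates:
    def test_count_over_window(self):
        t = train(np.linspace(1, 5.5, 10))
        assert mean_firing_rate(t, (0.75, 5.75)) == pytest.approx(2.0)

    def test_empty_train_zero(self):
        assert mean_firing_rate(train([]), (0.0, 10.0)) == 0.0

    def test_zero_length_window_errors(self):
        with pytest.raises(ValueError):
            mean_firing_rate(train([]), (5.0, 5.0))

    def test_poisson_rate_within_three_se(self):
        cfg = SynthConfig(seed=4, base_rate=10.0, burst_model=None, n_units=1,
                          duration=100.0)
        trains, _, _ = gen_spike_population(cfg)
        r = mean_firing_rate(trains[0], (0.0, 100.0))
        assert abs(r - 10.0) < 3 * np.sqrt(10.0 / 100.0)

    def test_rate_estimator_unbiased_over_seeds(self):
        rates = []
        for seed in range(200):
            cfg = SynthConfig(seed=seed, base_rate=5.0, burst_model=None,
                              n_units=1, duration=50.0)
            trains, _, _ = gen_spike_population(cfg)
            rates.append(mean_firing_rate(trains[0], (0.0, 50.0)))
        se = np.sqrt(5.0 / 50.0) / np.sqrt(200)
        assert abs(np.mean(rates) - 5.0) < 3 * se


class TestBinnedRates:
    def test_simple_binning(self):
        t = train([1.0, 31.0, 61.0], span=(0.0, 90.0))
        edges, rates = binned_firing_rate(t, 30.0)
        np.testing.assert_allclose(rates * 30.0, [1, 1, 1])

    def test_edge_spike_goes_right(self):
        t = train([30.0], span=(0.0, 90.0))
        edges, rates = binned_firing_rate(t, 30.0)
        np.testing.assert_allclose(rates * 30.0, [0, 1, 0])

    @given(st.lists(st.floats(min_value=1e-3, max_value=99.99), min_size=0,
                    max_size=60),
           st.floats(min_value=0.5, max_value=40.0))
    def test_conservation(self, times, bin_width):
        ticks = np.unique(np.round(np.asarray(times) * 20000).astype(np.int64))
        t = train(ticks / 20000.0) if ticks.size else train([])
        _, rates = binned_firing_rate(t, bin_width)
        assert int(round(float(np.sum(rates)) * bin_width)) == len(t)


class TestEpochRates:
    def test_uniform_train(self):
        t = train(np.arange(0.25, 100, 0.5))
        ep = EpochSet(before=(0.0, 30.0), during=(30.0, 60.0), after=(60.0, 90.0))
        b, d, a = epoch_firing_rates(t, ep)
        assert (b, d, a) == (2.0, 2.0, 2.0)

    def test_silent_during(self):
        t = train([1.0, 2.0, 70.0])
        ep = EpochSet(before=(0.0, 30.0), during=(30.0, 60.0), after=(60.0, 90.0))
        assert epoch_firing_rates(t, ep)[1] == 0.0

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError):
            EpochSet(before=(0.0, 40.0), during=(30.0, 60.0), after=(60.0, 90.0))


class TestPercentChange:
    @pytest.mark.parametrize("ref,new,expected",
                             [(2.0, 2.5, 25.0), (2.0, 2.0, 0.0), (2.0, 1.0, -50.0)])
    def test_values(self, ref, new, expected):
        assert percent_rate_change(ref, new) == pytest.approx(expected)

    def test_zero_reference_undefined(self):
        with pytest.raises(ValueError):
            percent_rate_change(0.0, 1.0)


class TestISI:
    def test_simple_intervals(self):
        np.testing.assert_allclose(isi_distribution(train([0.5, 1.5, 3.5])),
                                   [1.0, 2.0])

    def test_regular_train(self):
        iv = isi_distribution(train(np.arange(0.5, 50, 0.5)))
        np.testing.assert_allclose(iv, 0.5)

    def test_single_spike_warns_empty(self):
        with pytest.warns(UserWarning):
            assert isi_distribution(train([1.0])).size == 0

    def test_poisson_intervals_exponential(self):
        from scipy import stats
        cfg = SynthConfig(seed=8, base_rate=20.0, burst_model=None, n_units=1,
                          duration=200.0)
        trains, _, _ = gen_spike_population(cfg)
        iv = isi_distribution(trains[0])
        _, p = stats.kstest(iv, "expon", args=(0, 1.0 / 20.0))
        assert p > 0.01


class TestQualityFilter:
    template = -200.0 * np.exp(-((np.arange(80) - 40) ** 2) / 18.0)

    def test_clean_unit_passes(self):
        t = train(np.arange(1, 50, 0.5))
        q = unit_quality_filter(t, self.template, noise_sd=10.0)
        assert q.isi_violation_ratio == 0.0
        assert q.snr == pytest.approx(20.0, rel=0.01)
        assert q.passes

    def test_violation_ratio_above_half_fails(self):
        # 6 of 10 intervals below the 2 ms refractory period
        times = 1.0 + np.concatenate([[0.0], np.cumsum([0.001] * 6 + [0.5] * 4)])
        q = unit_quality_filter(train(times), self.template, noise_sd=10.0)
        assert q.isi_violation_ratio == pytest.approx(0.6)
        assert not q.passes

    def test_snr_just_below_threshold_fails(self):
        t = train(np.arange(1, 50, 0.5))
        q = unit_quality_filter(t, self.template, noise_sd=200.0 / 4.9)
        assert q.snr < 5.0 and not q.passes

    def test_monotone_in_noise(self):
        t = train(np.arange(1, 50, 0.5))
        passed = [unit_quality_filter(t, self.template, noise_sd=ns).passes
                  for ns in (10.0, 30.0, 50.0, 100.0)]
        # once failed, never passes again at higher noise
        assert passed == sorted(passed, reverse=True)


class TestNetworkBursts:
    def test_constructed_single_burst(self):
        rng = np.random.default_rng(0)
        trains = []
        for u in range(10):
            quiet = rng.uniform(0, 100, rng.poisson(0.1 * 100))
            loud = rng.uniform(10, 11, rng.poisson(50.0))
            t = np.unique(np.round(np.sort(np.concatenate([quiet, loud]))
                                   * 20000).astype(np.int64)) / 20000.0
            trains.append(SpikeTrain(f"u{u}", t, (0.0, 100.0)))
        bs = detect_network_bursts(trains)
        assert len(bs) == 1
        s, e = bs.bursts[0]
        assert s == pytest.approx(10.0, abs=0.1)
        assert e == pytest.approx(11.0, abs=0.1)

    def test_homogeneous_population_rarely_bursts(self):
        # false-positive check at a 5x threshold
        hits = 0
        for seed in range(40):
            cfg = SynthConfig(seed=seed, burst_model=None, duration=100.0)
            trains, _, _ = gen_spike_population(cfg)
            if len(detect_network_bursts(trains, rate_threshold=5.0)):
                hits += 1
        assert hits <= 2  # <= 5 % of seeds

    def test_empty_population(self):
        assert len(detect_network_bursts([])) == 0
        silent = [train([], span=(0.0, 10.0))]
        assert len(detect_network_bursts(silent)) == 0

    def test_round_trip_overlap(self):
        # generator -> detector Jaccard over a couple of seeds
        for seed in (0, 1):
            cfg = SynthConfig(seed=seed, duration=200.0)
            trains, bursts, _ = gen_spike_population(cfg)
            det = detect_network_bursts(trains)
            grid = np.linspace(0, 200, 200001)
            a = np.zeros(grid.size, bool)
            b = np.zeros(grid.size, bool)
            for s, e in bursts.bursts:
                a[(grid >= s) & (grid <= e)] = True
            for s, e in det.bursts:
                b[(grid >= s) & (grid <= e)] = True
            jac = (a & b).sum() / max((a | b).sum(), 1)
            assert jac >= 0.95


class TestEvokedLatency:
    def test_first_spike_in_window(self):
        t = train([2.130, 2.4], span=(0.0, 10.0))
        assert evoked_spike_latency(2.0, t) == pytest.approx(0.130)

    def test_none_when_no_spike(self):
        t = train([3.0], span=(0.0, 10.0))
        assert evoked_spike_latency(2.0, t, search_window=0.5) is None

    def test_contact_sample_excluded(self):
        t = train([2.0, 2.2], span=(0.0, 10.0))
        assert evoked_spike_latency(2.0, t) == pytest.approx(0.2)

    def test_exact_recovery_without_background(self):
        from mechanoephys.mechanics import MechStimulus
        from mechanoephys.synthetic import StimulusEffect
        stims = tuple(MechStimulus(kind="transient", setpoint_force=200.0,
                                   approach_speed=10.0, contact_on=5.0 + 3.0 * i,
                                   contact_off=5.5 + 3.0 * i) for i in range(20))
        cfg = SynthConfig(seed=0, base_rate=0.0, burst_model=None, n_units=1,
                          duration=70.0, stimulus_schedule=stims,
                          stimulus_effects=tuple(
                              StimulusEffect(evoked_latency_mean=0.130,
                                             evoked_latency_sd=0.05)
                              for _ in stims))
        trains, _, truth = gen_spike_population(cfg)
        for i, stim in enumerate(stims):
            lat = evoked_spike_latency(stim.contact_on, trains[0])
            assert lat == pytest.approx(truth["evoked_latencies"][i]["unit000"],
                                        abs=1.0 / 20000.0)


class TestBurstSet:
    def test_ibis_are_gaps(self):
        bs = BurstSet([(1.0, 2.0), (5.0, 6.0), (8.0, 9.0)])
        assert bs.ibis == [(2.0, 5.0), (6.0, 8.0)]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            BurstSet([(1.0, 3.0), (2.0, 4.0)])
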