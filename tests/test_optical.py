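"""Calcium-trace analysis and soma morphometry."""

import numpy as np
import pytest

from mechanoephys.ephys import SpikeTrain
from mechanoephys.mechanics import MechStimulus
from mechanoephys.optical import (CalciumTrace, SomaOutline,
                                  align_response_window, classify_responder,
                                  compute_dff, detect_ca_peaks, fit_decay_tau,
                                  response_onset, soma_diameter_change)
from mechanoephys.synthetic import SynthConfig, gen_calcium_trace

FPS = 45.0


def trace_from(y, fps=FPS):
    y = np.asarray(y, dtype=float)
    return CalciumTrace(np.arange(y.size) / fps, y, fps)


def brute_force_peaks(trace, window=3.0):
    """Oracle: every frame tested against all frames within ±window/2."""
    t, y = trace.frame_times, trace.dff
    peaks = []
    for i in range(1, len(y) - 1):
        others = [y[j] for j in range(len(y))
                  if j != i and abs(t[j] - t[i]) <= window / 2.0]
        if others and all(y[i] > v for v in others):
            peaks.append(i)
    return peaks


class TestDff:
    def test_constant_trace_zero(self):
        t = np.arange(100) / FPS
        trace = compute_dff(t, np.full(100, 500.0), FPS)
        np.testing.assert_array_equal(trace.dff, 0.0)

    def test_doubling_gives_unity(self):
        t = np.arange(100) / FPS
        intensity = np.full(100, 300.0)
        intensity[50] = 600.0
        trace = compute_dff(t, intensity, FPS, stim_time=t[40])
        assert trace.dff[50] == pytest.approx(1.0, rel=1e-6)

    def test_non_positive_intensity_rejected(self):
        t = np.arange(100) / FPS
        with pytest.raises(ValueError):
            compute_dff(t, np.zeros(100), FPS)

    def test_round_trip_with_generator(self):
        cfg = SynthConfig(seed=0, ca_noise_sd=0.0)
        tr = SpikeTrain("u", np.array([3.0]), (0.0, 40.0))
        trace, _ = gen_calcium_trace(tr, cfg)
        i0 = 700.0
        intensity = i0 * (1.0 + trace.dff)
        back = compute_dff(trace.frame_times, intensity, FPS, stim_time=2.9)
        np.testing.assert_allclose(back.dff, trace.dff, atol=1e-12)


class TestPeakDetection:
    def test_single_bump(self):
        t = np.arange(400) / FPS
        y = np.exp(-((t - 4.0) ** 2) / 0.5)
        trace = trace_from(y)
        peaks = detect_ca_peaks(trace)
        assert peaks == brute_force_peaks(trace)
        assert len(peaks) == 1
        assert t[peaks[0]] == pytest.approx(4.0, abs=1.0 / FPS)

    def test_two_bumps_five_seconds_apart(self):
        t = np.arange(600) / FPS
        y = np.exp(-((t - 3.0) ** 2) / 0.3) + 0.8 * np.exp(-((t - 8.0) ** 2) / 0.3)
        trace = trace_from(y)
        peaks = detect_ca_peaks(trace, window=3.0)
        assert peaks == brute_force_peaks(trace, 3.0)
        assert len(peaks) == 2

    def test_monotone_trace_no_peaks(self):
        trace = trace_from(np.linspace(0, 1, 300))
        assert detect_ca_peaks(trace) == []

    def test_matches_oracle_on_noise(self):
        rng = np.random.default_rng(2)
        trace = trace_from(rng.normal(0, 1, 200))
        assert detect_ca_peaks(trace) == brute_force_peaks(trace)

    def test_window_must_exceed_frame_interval(self):
        with pytest.raises(ValueError):
            detect_ca_peaks(trace_from(np.zeros(10)), window=0.001)


class TestOnset:
    def test_linear_ramp_ten_percent(self):
        t = np.arange(0, 10.0 + 1e-9, 1.0 / FPS)
        y = t / 10.0
        trace = CalciumTrace(t, y, FPS)
        onset, flagged = response_onset(trace, len(y) - 1)
        assert not flagged
        assert onset == pytest.approx(1.0, abs=1.0 / FPS)

    def test_step_onset_at_step(self):
        t = np.arange(300) / FPS
        y = np.where(t >= 4.0, 1.0, 0.0)
        trace = CalciumTrace(t, y, FPS)
        onset, _ = response_onset(trace, int(np.argmax(y > 0)) + 5)
        assert onset == pytest.approx(4.0, abs=1.0 / FPS)

    def test_generator_onset_recovered(self):
        cfg = SynthConfig(seed=0, ca_noise_sd=0.0)
        tr = SpikeTrain("u", np.array([5.0]), (0.0, 60.0))
        trace, truth = gen_calcium_trace(tr, cfg)
        peak = int(np.argmax(trace.dff))
        onset, flagged = response_onset(trace, peak)
        assert not flagged
        assert onset == pytest.approx(truth["onset_times"][0], abs=1.0 / FPS)

    def test_never_below_threshold_flagged(self):
        trace = trace_from(np.linspace(0.5, 1.0, 100))
        onset, flagged = response_onset(trace, 99)
        assert flagged and onset == trace.frame_times[0]


class TestAlignment:
    def test_time_rezeroed(self):
        t = np.arange(0, 20, 1.0 / FPS)
        trace = CalciumTrace(t, np.zeros_like(t), FPS)
        win, truncated = align_response_window(trace, t0=5.0)
        assert not truncated
        assert np.isclose(win.frame_times, 0.0).any()
        assert win.frame_times[0] >= -2.5 and win.frame_times[-1] <= 10.0

    def test_window_frame_budget(self):
        t = np.arange(0, 20, 1.0 / FPS)
        trace = CalciumTrace(t, np.zeros_like(t), FPS)
        win, _ = align_response_window(trace, t0=5.0)
        assert len(win) <= int(np.ceil(12.5 * FPS))

    def test_truncation_flagged(self):
        t = np.arange(0, 20, 1.0 / FPS)
        trace = CalciumTrace(t, np.zeros_like(t), FPS)
        with pytest.warns(UserWarning):
            win, truncated = align_response_window(trace, t0=1.0)
        assert truncated


class TestDecayFit:
    def test_exact_exponential(self):
        t = np.arange(0, 120, 1.0 / FPS)
        y = np.exp(-t / 26.2)
        trace = CalciumTrace(t, y, FPS)
        tau = fit_decay_tau(trace, 0)
        assert tau == pytest.approx(26.2, rel=1e-6)

    def test_scale_invariance(self):
        t = np.arange(0, 120, 1.0 / FPS)
        trace1 = CalciumTrace(t, np.exp(-t / 26.2), FPS)
        trace2 = CalciumTrace(t, 7.3 * np.exp(-t / 26.2), FPS)
        assert fit_decay_tau(trace1, 0) == pytest.approx(fit_decay_tau(trace2, 0),
                                                         rel=1e-9)

    def test_flat_tail_missing(self):
        t = np.arange(0, 30, 1.0 / FPS)
        trace = CalciumTrace(t, np.ones_like(t), FPS)
        with pytest.warns(UserWarning):
            assert fit_decay_tau(trace, 0) is None

    def test_recovery_under_noise(self):
        # relative error < 2 % at noise sd = 5 % of peak, over replicates
        rng = np.random.default_rng(6)
        t = np.arange(0, 120, 1.0 / FPS)
        clean = np.exp(-t / 26.2)
        errs = []
        for _ in range(100):
            trace = CalciumTrace(t, clean + rng.normal(0, 0.05, t.size), FPS)
            tau = fit_decay_tau(trace, 0)
            errs.append(abs(tau - 26.2) / 26.2)
        assert np.median(errs) < 0.02


class TestResponder:
    stim = MechStimulus(kind="transient", setpoint_force=200.0,
                        approach_speed=10.0, contact_on=10.0, contact_off=10.5)

    def test_flat_trace_not_responded(self):
        t = np.arange(0, 40, 1.0 / FPS)
        trace = CalciumTrace(t, np.zeros_like(t), FPS)
        assert not classify_responder(trace, self.stim).responded

    def test_large_transient_responded(self):
        cfg = SynthConfig(seed=0, ca_noise_sd=0.005)
        tr = SpikeTrain("u", np.array([10.6]), (0.0, 60.0))
        trace, _ = gen_calcium_trace(tr, cfg)
        resp = classify_responder(trace, self.stim)
        assert resp.responded
        assert resp.onset_time <= resp.peak_time

    def test_cohort_fraction_recovered(self):
        # 87 of 100 cells given transients -> 87 % responder fraction
        responded = 0
        for i in range(100):
            cfg = SynthConfig(seed=100 + i, ca_noise_sd=0.005)
            spikes = np.array([10.6]) if i < 87 else np.empty(0)
            tr = SpikeTrain("u", spikes, (0.0, 40.0))
            trace, _ = gen_calcium_trace(tr, cfg, duration=40.0)
            if classify_responder(trace, self.stim).responded:
                responded += 1
        assert responded == 87

    def test_no_baseline_errors(self):
        t = np.arange(0, 5, 1.0 / FPS)
        trace = CalciumTrace(t + 20.0, np.zeros_like(t), FPS)
        with pytest.raises(ValueError, match="baseline"):
            classify_responder(trace, self.stim)


def regular_polygon(n, radius, center=(0.0, 0.0), phase=0.0):
    ang = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


class TestSomaDiameter:
    def test_circle_growth(self):
        before = SomaOutline(regular_polygon(64, 5.0), "before")
        during = SomaOutline(regular_polygon(64, 7.0), "during")
        assert soma_diameter_change(before, during) == pytest.approx(4.0, rel=1e-3)

    def test_identical_outlines_zero(self):
        poly = SomaOutline(regular_polygon(32, 5.0), "before")
        assert soma_diameter_change(poly, poly) == pytest.approx(0.0, abs=1e-12)

    def test_square_widened_along_one_axis(self):
        sq = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        wide = np.array([[0.0, 0.0], [14.0, 0.0], [14.0, 10.0], [0.0, 10.0]])
        change = soma_diameter_change(SomaOutline(sq, "before"),
                                      SomaOutline(wide, "during"))
        assert change == pytest.approx(4.0, rel=1e-6)

    def test_rigid_motion_invariance(self):
        sq = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        wide = np.array([[0.0, 0.0], [14.0, 0.0], [14.0, 10.0], [0.0, 10.0]])
        base = soma_diameter_change(SomaOutline(sq, "before"),
                                    SomaOutline(wide, "during"))
        phi = np.deg2rad(30.0)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        shift = np.array([100.0, -50.0])
        moved = soma_diameter_change(SomaOutline(sq @ R.T + shift, "before"),
                                     SomaOutline(wide @ R.T + shift, "during"))
        assert moved == pytest.approx(base, abs=5e-3)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            SomaOutline(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), "before")
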