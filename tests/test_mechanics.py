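"""Force-curve processing: baselines, contact detection, indentation,
cutoff filtering, Hertz fitting and cycle aggregation."""

import numpy as np
import pytest

from mechanoephys.mechanics import (ContactNotFoundError, apply_depth_cutoff,
                                    classify_curve_epoch, compute_indentation,
                                    cycle_stiffness, detect_contact_point,
                                    estimate_baseline, estimate_stiffness,
                                    fit_hertz_sphere, hertz_force_nN,
                                    nominal_pressure, HertzFitResult)
from mechanoephys.synthetic import SegmentPlan, SynthConfig, gen_force_curve

from conftest import make_curve


class TestHertzForwardModel:
    def test_reference_point_750nm(self):
        # closed form at the depth cutoff for a 1 kPa, 2.5 µm bead contact
        assert hertz_force_nN(750.0, 1000.0, 2.5, 0.5) == pytest.approx(1.826, abs=5e-4)

    def test_zero_at_contact(self):
        assert hertz_force_nN(0.0, 1000.0, 2.5, 0.5) == 0.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            hertz_force_nN(100.0, 1000.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            hertz_force_nN(100.0, 1000.0, 2.5, 1.0)


class TestBaseline:
    def test_flat_baseline_is_zero(self):
        z = np.linspace(0, 1, 200)
        curve = make_curve(z, np.zeros_like(z))
        assert estimate_baseline(curve) == (0.0, 0.0)

    def test_gaussian_noise_sd_recovered(self):
        # 5 pN injected noise; sd of the sample sd is ~ sigma/sqrt(2n)
        rng = np.random.default_rng(42)
        n = 40000
        z = np.linspace(0, 10, n)
        sigma_nN = 0.005
        d = rng.normal(0.0, sigma_nN / 0.02, n)  # deflection nm at k=0.02
        curve = make_curve(z, d)
        _, sd = estimate_baseline(curve, baseline_fraction=0.25)
        assert sd == pytest.approx(sigma_nN, rel=0.05)

    def test_too_few_samples_errors(self):
        z = np.linspace(0, 1, 30)
        curve = make_curve(z, np.zeros_like(z))
        with pytest.raises(ValueError, match="insufficient baseline"):
            estimate_baseline(curve, baseline_fraction=0.3)


class TestContactPoint:
    def test_noiseless_recovery_within_two_samples(self):
        cfg = SynthConfig(seed=0, force_noise_sd=0.0)
        plan = SegmentPlan.for_depth(cfg, depth_nm=900.0, baseline_um=1.0)
        curve, truth = gen_force_curve(cfg, plan)
        dz = cfg.approach_speed / cfg.afm_sampling  # µm per sample
        cp = detect_contact_point(curve)
        assert abs(cp.z_contact - truth["z_contact"]) <= 2 * dz

    def test_all_zero_curve_has_no_contact(self):
        z = np.linspace(0, 1, 200)
        curve = make_curve(z, np.zeros_like(z))
        with pytest.raises(ContactNotFoundError):
            detect_contact_point(curve)

    def test_isolated_noise_spike_not_contact(self):
        # a 6-sigma excursion that returns to baseline must not anchor the
        # contact point: the crossing has to persist to the end of approach
        rng = np.random.default_rng(7)
        n = 2000
        z = np.linspace(0, 2, n)
        sigma_nN = 0.01
        d = rng.normal(0, sigma_nN / 0.02, n)
        spike_at = 900
        d[spike_at] += 8 * sigma_nN / 0.02
        ramp_from = 1500
        d[ramp_from:] += np.linspace(0, 100, n - ramp_from)
        curve = make_curve(z, d)
        cp = detect_contact_point(curve)
        assert cp.z_contact > z[spike_at + 10]

    def test_flagged_when_crossing_near_end(self):
        n = 2000
        z = np.linspace(0, 2, n)
        d = np.zeros(n)
        d[-40:] = np.linspace(0, 50, 40)
        curve = make_curve(z, d)
        cp = detect_contact_point(curve)
        assert cp.needs_review


class TestIndentation:
    def test_zero_at_contact_and_rigid_limit(self):
        # rigid surface: deflection tracks piezo one-to-one past contact
        n = 1000
        z = np.linspace(0, 2, n)
        z0 = 1.0
        d = np.where(z > z0, (z - z0) * 1000.0, 0.0)
        curve = make_curve(z, d)
        delta, force = compute_indentation(curve, z0)
        assert delta[0] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(delta, 0.0, atol=1e-6)

    def test_matches_generator_ground_truth(self):
        cfg = SynthConfig(seed=0, force_noise_sd=0.0)
        plan = SegmentPlan.for_depth(cfg, depth_nm=900.0)
        curve, truth = gen_force_curve(cfg, plan)
        delta, force = compute_indentation(curve, truth["z_contact"])
        # independent oracle: closed-form force at the recovered indentation
        expected = hertz_force_nN(delta, cfg.E_true, cfg.bead_radius,
                                  cfg.poisson_ratio)
        np.testing.assert_allclose(force, expected, atol=1e-6)

    def test_outside_range_errors(self):
        z = np.linspace(0, 1, 100)
        curve = make_curve(z, np.zeros_like(z))
        with pytest.raises(ValueError):
            compute_indentation(curve, 5.0)


class TestDepthCutoff:
    def test_all_below_cutoff_unchanged(self):
        delta = np.linspace(0, 700, 71)
        force = delta**1.5
        f, d, n = apply_depth_cutoff(force, delta, 750.0)
        assert n == 0 and d.size == 71

    def test_uniform_span_count(self):
        # 151 samples spanning 0..1500 nm in 10 nm steps: 76 satisfy δ <= 750
        delta = np.linspace(0, 1500, 151)
        force = np.ones_like(delta)
        f, d, n = apply_depth_cutoff(force, delta, 750.0)
        assert d.size == 76
        assert n == 75

    def test_zero_cutoff_keeps_contact_sample(self):
        delta = np.linspace(0, 1500, 151)
        f, d, n = apply_depth_cutoff(delta.copy(), delta, 0.0)
        assert d.size == 1 and d[0] == 0.0


class TestHertzFit:
    def make_samples(self, E=1000.0, n=100, depth=750.0):
        delta = np.linspace(depth / n, depth, n)
        return hertz_force_nN(delta, E, 2.5, 0.5), delta

    def test_noiseless_recovery(self):
        force, delta = self.make_samples()
        fit = fit_hertz_sphere(force, delta, R=2.5, nu=0.5)
        assert fit.usable
        assert fit.E_apparent == pytest.approx(1000.0, rel=1e-3)

    @pytest.mark.parametrize("refine", [False, True])
    def test_scale_equivariance_exact(self, refine):
        force, delta = self.make_samples()
        f1 = fit_hertz_sphere(force, delta, R=2.5, nu=0.5, refine_contact=refine)
        f2 = fit_hertz_sphere(2 * force, delta, R=2.5, nu=0.5, refine_contact=refine)
        assert f2.E_apparent == pytest.approx(2 * f1.E_apparent, rel=1e-9)

    def test_too_few_samples_unusable(self):
        force, delta = self.make_samples(n=8)
        fit = fit_hertz_sphere(force, delta, R=2.5, nu=0.5)
        assert not fit.usable

    def test_refinement_recovers_shifted_contact(self):
        # indentation systematically 100 nm short (late-detected contact)
        force, delta = self.make_samples()
        shifted = delta - 100.0
        keep = shifted > 0
        plain = fit_hertz_sphere(force[keep], shifted[keep], R=2.5, nu=0.5)
        refined = fit_hertz_sphere(force[keep], shifted[keep], R=2.5, nu=0.5,
                                   refine_contact=True)
        assert abs(plain.E_apparent - 1000) / 1000 > 0.1
        assert refined.E_apparent == pytest.approx(1000.0, rel=1e-3)
        assert refined.contact_offset_nm == pytest.approx(-100.0, abs=1.0)

    def test_cutoff_monotonicity(self):
        force, delta = self.make_samples(depth=1200.0)
        n_prev = None
        for cutoff in (1200.0, 900.0, 750.0, 400.0):
            f, d, _ = apply_depth_cutoff(force, delta, cutoff)
            fit = fit_hertz_sphere(f, d, R=2.5, nu=0.5)
            if n_prev is not None:
                assert fit.n_points_fit <= n_prev
            n_prev = fit.n_points_fit


class TestCycleAggregation:
    @staticmethod
    def fit(E):
        return HertzFitResult(E_apparent=E, z_contact=0.0, baseline_mean=0.0,
                              baseline_sd=0.0, n_points_fit=50,
                              max_indentation_used=750.0, residual_rms=0.0,
                              usable=True)

    def test_identical_fits(self):
        m = cycle_stiffness([self.fit(1000.0)] * 5)
        assert (m.E_mean, m.E_sd, m.n_curves) == (1000.0, 0.0, 5)

    def test_sample_sd(self):
        m = cycle_stiffness([self.fit(E) for E in (1000.0, 2000.0, 3000.0)])
        assert m.E_mean == pytest.approx(2000.0)
        assert m.E_sd == pytest.approx(1000.0)  # sample sd, ddof=1

    def test_minimum_three_curves(self):
        with pytest.raises(ValueError, match="insufficient curves"):
            cycle_stiffness([self.fit(1000.0)] * 2)


class TestEpochClassification:
    @pytest.mark.parametrize("t,expected", [
        (10.5, "burst"), (5.0, "ibi"), (10.0, "burst"), (11.0, "burst"),
        (11.0001, "ibi")])
    def test_closed_interval_convention(self, t, expected):
        assert classify_curve_epoch(t, [(10.0, 11.0)]) == expected


class TestNominalPressure:
    def test_bead_cross_section(self):
        res = nominal_pressure(200.0, R=2.5)
        assert res.pressure_kPa == pytest.approx(10.19, abs=0.01)
        assert res.area_model == "bead_cross_section"

    def test_effective_area_reproduces_5kPa(self):
        res = nominal_pressure(200.0, effective_area=40.0)
        assert res.pressure_kPa == pytest.approx(5.0)
        assert res.area_model == "effective_area"

    def test_zero_force(self):
        assert nominal_pressure(0.0, R=2.5).pressure_kPa == 0.0

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            nominal_pressure(100.0, effective_area=-1.0)


class TestEndToEndRecovery:
    def test_full_chain_noiseless(self):
        cfg = SynthConfig(seed=0, force_noise_sd=0.0)
        plan = SegmentPlan.for_depth(cfg, depth_nm=900.0)
        curve, _ = gen_force_curve(cfg, plan)
        fit = estimate_stiffness(curve)
        assert fit.usable
        assert fit.E_apparent == pytest.approx(1000.0, rel=1e-3)

    def test_contact_error_grows_with_noise(self):
        # graceful degradation: median contact error is monotone in noise sd
        errors = []
        for noise in (0.0, 20e-12, 100e-12):
            errs = []
            cfg = SynthConfig(seed=5, force_noise_sd=noise)
            plan = SegmentPlan.for_depth(cfg, depth_nm=900.0)
            rng = np.random.default_rng(11)
            for _ in range(10):
                curve, truth = gen_force_curve(cfg, plan, rng=rng)
                cp = detect_contact_point(curve)
                errs.append(abs(cp.z_contact - truth["z_contact"]))
            errors.append(np.median(errs))
        assert errors[0] <= errors[1] <= errors[2]
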