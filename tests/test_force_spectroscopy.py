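"""Force-spectroscopy pipeline: calibration, contact, decomposition, TLS."""

import numpy as np
import pytest
from scipy import stats

from gridmech import force_spectroscopy as fs
from gridmech.synthetic_data import GeneratorConfig, gen_calibration_curve, gen_force_curve
from gridmech.types import ForceCurve


def closed_form_tls_slope(x, y):
    """Independent oracle: TLS slope from the second moments (angle form,
    well-conditioned near zero slope)."""
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy, sxy = xc @ xc, yc @ yc, xc @ yc
    return np.tan(0.5 * np.arctan2(2 * sxy, sxx - syy))


class TestCalibrateSensitivity:
    def test_recovers_configured_sensitivity(self, quiet_cfg):
        s = fs.calibrate_sensitivity(gen_calibration_curve(quiet_cfg))
        assert s == pytest.approx(25.97, rel=1e-6)

    def test_unit_sensitivity(self, quiet_cfg):
        cfg = GeneratorConfig(**{**quiet_cfg.__dict__, "sensitivity": 1.0})
        assert fs.calibrate_sensitivity(gen_calibration_curve(cfg)) == pytest.approx(1.0, rel=1e-6)

    def test_noisy_curve_within_two_percent(self):
        cfg = GeneratorConfig(seed=21, noise_sd=0.2, periodic_noise=[])
        s = fs.calibrate_sensitivity(gen_calibration_curve(cfg))
        assert s == pytest.approx(25.97, rel=0.02)

    def test_requires_volt_channel(self, quiet_cfg):
        with pytest.raises(ValueError, match="volts"):
            fs.calibrate_sensitivity(gen_force_curve(quiet_cfg))

    def test_compliant_surface_warns_against_nominal(self, quiet_cfg):
        # deflection lags piezo on a soft film -> apparent nm/V too high
        soft = gen_force_curve(quiet_cfg)
        fake = ForceCurve(time=soft.time, piezo=soft.piezo, signal=soft.deflection / 25.97)
        with pytest.warns(UserWarning, match="compliance"):
            fs.calibrate_sensitivity(fake, nominal_sensitivity=25.97)


class TestToDeflection:
    def test_applies_sensitivity(self, quiet_cfg):
        curve = gen_calibration_curve(quiet_cfg)
        out = fs.to_deflection(curve, 25.97)
        np.testing.assert_allclose(out.deflection, 25.97 * curve.signal)
        assert out.meta["sensitivity"] == 25.97

    @pytest.mark.parametrize("volts,s,expected", [(1.0, 25.97, 25.97), (0.0, 25.97, 0.0), (2.0, 10.0, 20.0)])
    def test_point_values(self, volts, s, expected):
        curve = ForceCurve(time=[0, 1], piezo=[0, 1], signal=[volts, volts])
        assert fs.to_deflection(curve, s).deflection[0] == pytest.approx(expected)

    def test_rejects_already_converted(self, quiet_cfg):
        curve = gen_force_curve(quiet_cfg)
        with pytest.raises(ValueError, match="already"):
            fs.to_deflection(curve, 25.97)


class TestDetectContact:
    def test_exact_on_noise_free_curve(self, quiet_cfg):
        curve = gen_force_curve(quiet_cfg)
        assert fs.detect_contact(curve) == curve.meta["contact_index"]

    def test_all_baseline_curve_errors(self):
        curve = ForceCurve(time=np.linspace(0, 1, 100), piezo=np.linspace(0, 100, 100),
                           deflection=np.zeros(100))
        with pytest.raises(ValueError, match="no contact"):
            fs.detect_contact(curve)

    def test_noisy_curve_within_run_length_of_truth(self):
        # fast ramp: deflection rises quickly, detection lag below the
        # sustained-run window
        cfg = GeneratorConfig(seed=13, loading_rate=1000.0, noise_sd=0.1, periodic_noise=[])
        curve = gen_force_curve(cfg)
        found = fs.detect_contact(curve)
        assert abs(found - curve.meta["contact_index"]) <= fs.CONTACT_RUN_LENGTH


class TestDecompose:
    def test_definitional_subtraction(self):
        curve = ForceCurve(
            time=np.arange(102) * 1e-3,
            piezo=np.concatenate([[0.0], np.linspace(0, 100, 101)]),
            deflection=np.concatenate([[0.0], np.linspace(0, 77.20, 101)]),
        )
        delta, force = fs.decompose(curve, 0.251, contact=1)
        assert delta[-1] == pytest.approx(22.80)
        assert force[-1] == pytest.approx(0.251 * 77.20)

    def test_rigid_curve_has_zero_film_deformation(self):
        # exact identity when deflection tracks piezo one-for-one
        z = np.linspace(0, 100, 200)
        curve = ForceCurve(time=np.arange(200) * 1e-3, piezo=z, deflection=z.copy())
        delta, _ = fs.decompose(curve, 0.251, contact=0)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_generated_rigid_curve_offset_below_one_piezo_step(self, quiet_cfg):
        """Zeroing at the detected contact sample leaves at most a constant
        sub-step offset, which cancels in the slope."""
        import math

        cfg = GeneratorConfig(**{**quiet_cfg.__dict__, "film_k": math.inf})
        curve = gen_force_curve(cfg)
        step = cfg.loading_rate / cfg.sampling_rate
        delta, _ = fs.decompose(curve, 0.251, curve.meta["contact_index"])
        assert np.ptp(delta) <= 1e-9  # constant
        assert np.max(np.abs(delta)) <= step + 1e-9

    def test_force_is_kc_times_deflection(self):
        curve = ForceCurve(
            time=np.arange(3) * 1e-3,
            piezo=np.array([0.0, 50.0, 100.0]),
            deflection=np.array([0.0, 25.97 / 2, 25.97]),
        )
        _, force = fs.decompose(curve, 0.251, contact=0)
        assert force[-1] == pytest.approx(6.52, abs=0.005)

    def test_nonpositive_kc_rejected(self, quiet_cfg):
        curve = gen_force_curve(quiet_cfg)
        with pytest.raises(ValueError, match="cantilever_k"):
            fs.decompose(curve, 0.0, 10)


class TestFitTLS:
    def test_noise_free_line(self):
        delta = np.array([0.0, 10.0, 20.0])
        force = np.array([0.0, 8.5, 17.0])
        fit = fs.fit_tls(delta, force, min_points=3)
        assert fit.k_f == pytest.approx(0.850, abs=1e-12)

    def test_matches_closed_form_moment_solution(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(20, 80))
            x = rng.normal(size=n) * rng.uniform(0.5, 5.0)
            y = rng.uniform(-2.0, 2.0) * x + rng.normal(size=n)
            fit = fs.fit_tls(x, y, min_points=3)
            assert fit.k_f == pytest.approx(closed_form_tls_slope(x, y), rel=1e-10)

    def test_isotropic_noise_slope_converges_to_one(self):
        rng = np.random.default_rng(3)
        n = 200_000
        x = rng.uniform(-10, 10, n)
        pts = np.column_stack([x, x]) + rng.normal(0, 1.0, (n, 2))
        fit = fs.fit_tls(pts[:, 0], pts[:, 1])
        assert fit.k_f == pytest.approx(1.0, abs=0.01)

    def test_generator_round_trip_noise_free(self, quiet_cfg):
        fit = fs.estimate_film_stiffness(gen_force_curve(quiet_cfg), 0.251)
        assert fit.k_f == pytest.approx(0.85, rel=1e-9)

    def test_degenerate_scatter_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fs.fit_tls(np.zeros(30), np.zeros(30))

    def test_negative_slope_flagged_not_silent(self):
        x = np.linspace(0, 10, 30)
        fit = fs.fit_tls(x, -0.5 * x)
        assert not fit.valid
        assert any("slope" in f for f in fit.flags)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fs.fit_tls(np.arange(5.0), np.arange(5.0))


class TestSummarize:
    def _fit(self, k, rate):
        return fs.SpringFit(k_f=k, slope_ci=0.0, contact_index=0, n_points=100,
                            residual_rms=0.0, loading_rate=rate)

    def test_identical_groups_give_t0_p1(self):
        fits = [self._fit(0.85, 100.0) for _ in range(6)] + [self._fit(0.85, 1000.0) for _ in range(6)]
        s = fs.summarize(fits)
        assert s.t_statistic == 0.0
        assert s.p_value == 1.0

    def test_hand_arithmetic_mean_sd(self):
        fits = [self._fit(k, 100.0) for k in (0.6, 0.8, 1.0)]
        s = fs.summarize(fits)
        assert s.mean == pytest.approx(0.8)
        assert s.sd == pytest.approx(0.2)
        assert s.t_statistic is None  # single group: no test

    def test_null_rejection_rate_near_alpha(self):
        """Groups drawn from the same distribution reject at ~5% (1000 reps)."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            fits = [self._fit(k, 100.0) for k in rng.normal(0.85, 0.23, 6)]
            fits += [self._fit(k, 1000.0) for k in rng.normal(0.85, 0.23, 6)]
            rejections += fs.summarize(fits).p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_mean_invariant_under_group_swap_t_antisymmetric(self):
        a = [self._fit(k, 100.0) for k in (0.6, 0.7, 0.9)]
        b = [self._fit(k, 1000.0) for k in (0.8, 0.95, 1.05)]
        s1 = fs.summarize(a + b)
        swapped = [self._fit(f.k_f, 1000.0) for f in a] + [self._fit(f.k_f, 100.0) for f in b]
        s2 = fs.summarize(swapped)
        assert s1.mean == pytest.approx(s2.mean)
        assert s1.t_statistic == pytest.approx(-s2.t_statistic)
        assert s1.p_value == pytest.approx(s2.p_value)

    def test_loading_rate_label_does_not_change_estimate(self, quiet_cfg):
        """The estimator never uses the rate tag: same samples, same k_f."""
        c1 = gen_force_curve(quiet_cfg)
        c2 = ForceCurve(time=c1.time, piezo=c1.piezo, deflection=c1.deflection,
                        loading_rate=1000.0)
        f1 = fs.estimate_film_stiffness(c1, 0.251)
        f2 = fs.estimate_film_stiffness(c2, 0.251)
        assert f1.k_f == f2.k_f


class TestNoiseSpectrum:
    def test_injected_60hz_reported_on_grid(self):
        cfg = GeneratorConfig(seed=5, noise_sd=0.05, periodic_noise=[(60.0, 0.3)])
        sp = fs.noise_spectrum(gen_force_curve(cfg))
        df = sp.frequencies[1] - sp.frequencies[0]
        assert any(abs(p - 60.0) <= df for p in sp.peaks)

    def test_both_mains_harmonics_reported(self):
        cfg = GeneratorConfig(seed=5, noise_sd=0.05, periodic_noise=[(60.0, 0.3), (300.0, 0.3)])
        sp = fs.noise_spectrum(gen_force_curve(cfg))
        df = sp.frequencies[1] - sp.frequencies[0]
        assert any(abs(p - 60.0) <= df for p in sp.peaks)
        assert any(abs(p - 300.0) <= df for p in sp.peaks)

    def test_white_noise_rarely_yields_peaks(self):
        false_seeds = 0
        for seed in range(40):
            cfg = GeneratorConfig(seed=seed, noise_sd=0.3, periodic_noise=[])
            sp = fs.noise_spectrum(gen_force_curve(cfg))
            false_seeds += len(sp.peaks) > 0
        assert false_seeds / 40 <= 0.05

    def test_non_uniform_time_base_rejected(self):
        t = np.concatenate([np.linspace(0, 0.5, 50), np.linspace(0.6, 2.0, 50)])
        curve = ForceCurve(time=t, piezo=np.linspace(0, 100, 100), deflection=np.zeros(100))
        with pytest.raises(ValueError, match="non-uniform"):
            fs.noise_spectrum(curve)


def test_round_trip_recovery_under_moderate_noise():
    """Median recovered k_f over 20 seeds stays within 5% of the true 0.85."""
    ks = []
    for seed in range(20):
        cfg = GeneratorConfig(seed=seed, noise_sd=0.3)
        ks.append(fs.estimate_film_stiffness(gen_force_curve(cfg), 0.251).k_f)
    assert np.median(ks) == pytest.approx(0.85, rel=0.05)
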