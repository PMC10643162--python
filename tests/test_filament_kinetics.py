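"""Filament traces: pause handling, velocities, aging fit, derived rates."""

import numpy as np
import pytest
from scipy import stats

from backdoorflux.filament_kinetics import (
    DepolFit,
    FilamentTrace,
    VelocityProfile,
    average_traces,
    barbed_end_release_rate,
    detect_pauses,
    filament_age,
    fit_depol_model,
    instantaneous_velocity,
    lower_bound_k_release,
    select_windows,
)
from backdoorflux.synthetic_data import (
    FilamentSimConfig,
    PauseModel,
    gen_filament_traces,
)


def linear_trace(slope=-5.0, L0=5000.0, n=200, dt=5.0, depol_start=0.0):
    t = np.arange(n) * dt
    return FilamentTrace(time=t, length=np.maximum(L0 + slope * t, 0.0),
                         depol_start=depol_start)


class TestDetectPauses:
    def test_injected_plateau_found_and_truncated(self):
        t = np.arange(0, 600, 5.0)
        length = 5000.0 - 5.0 * t
        plateau = (t >= 200) & (t < 230)  # 30-s stall
        length[plateau] = length[t == 200][0]
        length[t >= 230] += 150.0  # resume from the stalled length
        tr = FilamentTrace(time=t, length=length, depol_start=0.0)
        pauses, trunc = detect_pauses(tr)
        assert len(pauses) == 1
        assert pauses[0].start == pytest.approx(200.0, abs=5.0)
        assert trunc.time[-1] <= pauses[0].start + 5.0

    def test_monotone_decrease_is_pause_free(self):
        pauses, trunc = detect_pauses(linear_trace())
        assert pauses == []
        assert len(trunc.time) == 200

    def test_cohort_pause_onsets_follow_logistic_cdf(self):
        pm = PauseModel(onset_loc=150.0, onset_scale=30.0, duration=80.0)
        cfg = FilamentSimConfig(n_filaments=200, pause_model=pm, seed=21)
        onsets = []
        for tr in gen_filament_traces(cfg):
            pauses, _ = detect_pauses(tr)
            if pauses:
                onsets.append(pauses[0].start)
        assert len(onsets) > 100
        res = stats.kstest(
            onsets, stats.logistic(loc=150.0, scale=30.0).cdf
        )
        assert res.pvalue > 0.05


class TestAverageTraces:
    def test_identical_traces_average_to_themselves(self):
        trs = [linear_trace() for _ in range(3)]
        t, mean, sd, n = average_traces(trs)
        assert np.allclose(mean, trs[0].length)
        assert np.allclose(sd, 0.0)
        assert np.all(n == 3)

    def test_unequal_lengths_use_active_traces(self):
        a = linear_trace(n=100)
        b = linear_trace(n=50)
        t, mean, sd, n = average_traces([a, b])
        assert len(t) == 100
        assert np.all(n[:50] == 2)
        assert np.all(n[50:] == 1)


class TestInstantaneousVelocity:
    def test_linear_trace_gives_constant_velocity(self):
        tr = linear_trace(slope=-5.0)
        prof = instantaneous_velocity(tr.time, tr.length)
        assert np.allclose(prof.inv_v, 1.0 / 5.0)
        assert np.allclose(prof.sd, 0.0)

    def test_quadratic_trace_matches_analytic_derivative(self):
        # centered linear regression of a quadratic is exact at the
        # window center, so the only error is float roundoff
        t = np.arange(0, 300, 5.0)
        length = 5000.0 - 2.0 * t - 0.004 * t**2
        prof = instantaneous_velocity(t, length, window_sizes=[17])
        v_true = 2.0 + 0.008 * prof.t
        assert np.allclose(1.0 / prof.inv_v, v_true, rtol=1e-9)

    def test_short_segment_rejected(self):
        tr = linear_trace(n=20)
        with pytest.raises(ValueError, match="window"):
            instantaneous_velocity(tr.time, tr.length)


class TestFilamentAge:
    def test_arithmetic_example(self):
        tau = filament_age(np.array([0.0, 10.0]),
                           np.array([1000.0, 900.0]), v_pol=50.0)
        assert tau[0] == 0.0
        assert tau[1] == pytest.approx(12.0)

    def test_constant_velocity_closed_form(self):
        d, v_pol = 4.0, 16.0
        t = np.arange(0, 500, 5.0)
        tau = filament_age(t, 8000.0 - d * t, v_pol)
        assert np.allclose(tau, t * (1.0 + d / v_pol))

    def test_growing_length_rejected(self):
        with pytest.raises(ValueError):
            filament_age(np.array([0.0, 5.0]), np.array([10.0, 20.0]), 10.0)


class TestFitDepolModel:
    def test_exact_closed_form_recovery(self):
        tau = np.linspace(0, 600, 120)
        y = 0.4 * np.exp(-0.006 * tau) + 0.1
        prof = VelocityProfile(tau=tau, inv_v=y, sd=np.zeros_like(y),
                               window_sizes=(17,))
        fit = fit_depol_model(prof)
        assert fit.a == pytest.approx(0.4, rel=1e-6)
        assert fit.b == pytest.approx(0.006, rel=1e-6)
        assert fit.c == pytest.approx(0.1, rel=1e-6)
        assert fit.v_depol_ADP == pytest.approx(10.0, rel=1e-6)
        assert fit.v_depol_ADPPi == pytest.approx(2.0, rel=1e-6)

    def test_flat_profile_flagged(self):
        tau = np.linspace(0, 600, 120)
        y = np.full_like(tau, 0.08)
        prof = VelocityProfile(tau=tau, inv_v=y, sd=np.zeros_like(y),
                               window_sizes=(17,))
        fit = fit_depol_model(prof)
        assert fit.flat
        assert fit.c == pytest.approx(0.08, rel=1e-3)

    def test_all_adp_cohort_is_flat(self):
        cfg = FilamentSimConfig(k_release_core=1e6, n_filaments=50, seed=5)
        trs = gen_filament_traces(cfg)
        t, mean, _, _ = average_traces(trs)
        prof = instantaneous_velocity(t, mean)
        prof.tau = filament_age(prof.t, np.interp(prof.t, t, mean), cfg.v_pol)
        fit = fit_depol_model(prof)
        assert fit.a < 0.05 * fit.c


class TestBarbedEndRate:
    def test_direct_evaluation(self):
        assert barbed_end_release_rate(10.0, 2.0, 0.2) == pytest.approx(2.25)

    def test_zero_numerator(self):
        assert barbed_end_release_rate(10.0, 0.2, 0.2) == 0.0

    def test_swapping_velocities_flips_sign(self):
        a = barbed_end_release_rate(10.0, 2.0, 0.2)
        b = barbed_end_release_rate(2.0, 10.0, 0.2)
        assert a * b < 0

    def test_equal_velocities_rejected(self):
        with pytest.raises(ZeroDivisionError):
            barbed_end_release_rate(5.0, 5.0)


def _flat_profile(c=1 / 14.71, sd=0.003, tau0=80.0):
    tau = np.linspace(tau0, 600, 100)
    y = np.full_like(tau, c)
    return VelocityProfile(tau=tau, inv_v=y, sd=np.full_like(tau, sd),
                           window_sizes=(17,))


class TestLowerBound:
    WT = DepolFit(a=0.45, b=0.006, c=1 / 6.7)

    def test_planted_fast_release_bounded_from_above(self):
        # a cohort generated at k = 0.2 looks flat at 5-s frames, so the
        # inferred detectability bound must not exceed the planted rate
        cfg = FilamentSimConfig(k_release_core=0.2, v_depol_ADP=14.71,
                                n_filaments=45, seed=8)
        trs = gen_filament_traces(cfg)
        t, mean, _, _ = average_traces(trs)
        prof = instantaneous_velocity(t, mean)
        prof.tau = filament_age(prof.t, np.interp(prof.t, t, mean), cfg.v_pol)
        fit = fit_depol_model(prof)
        assert fit.flat
        res = lower_bound_k_release(prof, fit, self.WT, assumption="1x")
        assert 0.0 < res.bound <= 0.2

    def test_noiseless_profile_degenerates_to_infinite_bound(self):
        prof = _flat_profile(sd=0.0)
        fit = DepolFit(a=0.0, b=1e-5, c=1 / 14.71, flat=True)
        res = lower_bound_k_release(prof, fit, self.WT)
        assert np.isinf(res.bound) and res.degenerate

    def test_bound_grows_with_sampling_rate(self):
        fit = DepolFit(a=0.0, b=1e-5, c=1 / 14.71, flat=True)
        bounds = [
            lower_bound_k_release(_flat_profile(tau0=tau0), fit, self.WT).bound
            for tau0 in (160.0, 80.0, 40.0, 20.0)
        ]
        assert np.all(np.diff(bounds) > 0)

    def test_refuses_resolvable_transient(self):
        prof = _flat_profile()
        fit = DepolFit(a=0.3, b=0.01, c=0.1, flat=False)
        with pytest.raises(ValueError, match="transient"):
            lower_bound_k_release(prof, fit, self.WT)


class TestSyntheticCohorts:
    def test_all_adp_mean_slope_matches_v_depol(self):
        cfg = FilamentSimConfig(k_release_core=1e6, n_filaments=50, seed=12)
        trs = gen_filament_traces(cfg)
        t, mean, _, n = average_traces(trs)
        keep = n == cfg.n_filaments
        slope = np.polyfit(t[keep], mean[keep], 1)[0]
        assert -slope == pytest.approx(cfg.v_depol_ADP, rel=0.05)

    def test_fixed_seed_reproducible(self):
        a = gen_filament_traces(FilamentSimConfig(n_filaments=3, seed=2))
        b = gen_filament_traces(FilamentSimConfig(n_filaments=3, seed=2))
        for x, y in zip(a, b):
            assert np.array_equal(x.length, y.length)

    def test_window_selection_report_admits_defaults(self):
        cfg = FilamentSimConfig(n_filaments=100, seed=3)
        trs = gen_filament_traces(cfg)
        t, mean, _, _ = average_traces(trs)
        report = select_windows(t, mean, cfg.v_pol)
        assert set(report) == {17, 19, 21, 23, 25, 27, 29}
        assert any(v["admissible"] for v in report.values())
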