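"""Core simulator: analytic superposition, the saturable-elimination ODE,
daily means, single-dose metrics and steady state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import ssridose as sd
from ssridose.exceptions import (
    ConvergenceError,
    DegenerateKineticsError,
    HorizonError,
    ValidationError,
)


def _ode_oracle(params, schedule, times):
    """Independent route: integrate the linear model as an ODE with an
    explicit depot state (the implementation uses the closed form)."""
    ka, ke, v = params.absorption_rate, params.elimination_rate, params.volume
    impulses = {}
    for ev in schedule.events:
        impulses[ev.time] = impulses.get(ev.time, 0.0) + ev.amount * 1000.0 / v
    edges = sorted({times[0], times[-1], *impulses})
    y = np.array([0.0, 0.0])
    out = np.zeros_like(times)
    written = np.zeros(times.shape, bool)
    for a, b in zip(edges, edges[1:]):
        if a in impulses:
            y[0] += impulses[a]
        m = (times >= a) & (times <= b) & ~written
        t_eval = times[m]
        probe = np.append(t_eval, b) if (t_eval.size == 0 or t_eval[-1] < b) else t_eval
        sol = solve_ivp(
            lambda t, y: [-ka * y[0], ka * y[0] - ke * y[1]],
            (a, b), y, t_eval=probe, rtol=1e-10, atol=1e-12, method="LSODA",
        )
        out[m] = sol.y[1][: t_eval.size]
        written[m] = True
        y = sol.y[:, -1].copy()
    return out


class TestLinearSimulator:
    def test_empty_schedule_is_identically_zero(self, sample_linear):
        prof = sd.simulate_linear(sample_linear, sd.DoseSchedule.empty(), 48.0)
        assert np.all(prof.concentrations == 0.0)

    def test_no_dose_means_zero_at_t0(self, sample_linear):
        prof = sd.simulate_linear(sample_linear, sd.DoseSchedule.single(50.0), 48.0)
        assert prof.concentrations[0] == 0.0
        assert np.all(prof.concentrations >= 0.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        volume=st.floats(100, 2000),
        t_half=st.floats(5, 60),
        ka_ratio=st.floats(2.0, 30.0),
        dose=st.floats(5, 200),
    )
    def test_matches_independent_ode_integration(self, volume, t_half, ka_ratio, dose):
        ke = np.log(2) / t_half
        params = sd.LinearPKParams(volume=volume, absorption_rate=ka_ratio * ke,
                                   elimination_rate=ke)
        schedule = sd.DoseSchedule.once_daily([dose, dose * 1.5, dose * 0.5])
        prof = sd.simulate_linear(params, schedule, 96.0, resolution=0.5)
        oracle = _ode_oracle(params, schedule, prof.times)
        scale = oracle.max()
        assert np.max(np.abs(prof.concentrations - oracle)) < 1e-6 * scale

    def test_dose_doubling_doubles_concentration(self, sample_linear):
        m1 = sd.regimen_daily_means(sample_linear, 40.0, 24, 8)
        m2 = sd.regimen_daily_means(sample_linear, 80.0, 24, 8)
        np.testing.assert_allclose(m2, 2.0 * m1, rtol=1e-12)

    def test_daily_means_nondecreasing_under_constant_dosing(self, sample_linear):
        means = sd.regimen_daily_means(sample_linear, 50.0, 24, 20)
        assert np.all(np.diff(means) > -1e-12)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(DegenerateKineticsError):
            sd.LinearPKParams(volume=100, absorption_rate=0.1, elimination_rate=0.1)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValidationError):
            sd.LinearPKParams(volume=-5, absorption_rate=0.5, elimination_rate=0.1)
        with pytest.raises(ValidationError):
            sd.MMPKParams(volume=100, absorption_rate=0.5, vmax=0.0, km=100)


class TestMMSimulator:
    def test_empty_schedule_is_identically_zero(self, fluoxetine_params):
        prof = sd.simulate_mm(fluoxetine_params, sd.DoseSchedule.empty(), 48.0)
        assert np.all(prof.concentrations == 0.0)

    def test_linear_limit(self):
        """With Km pushed far above any concentration and Vm/Km held at
        ke, saturable elimination degenerates to first order."""
        ke, ka, v, dose = 0.03, 0.5, 1000.0, 40.0
        km = 1e6 * (dose * 1000.0 / v)
        lin = sd.LinearPKParams(volume=v, absorption_rate=ka, elimination_rate=ke)
        mm = sd.MMPKParams(volume=v, absorption_rate=ka, vmax=ke * km, km=km)
        sched = sd.DoseSchedule.once_daily(dose, 5)
        pl = sd.simulate_linear(lin, sched, 120.0)
        pm = sd.simulate_mm(mm, sched, 120.0)
        m = pl.concentrations > 1e-3 * pl.concentrations.max()
        rel = np.abs(pm.concentrations[m] - pl.concentrations[m]) / pl.concentrations[m]
        assert rel.max() < 1e-3

    def test_accumulation_is_superlinear_in_dose(self, fluoxetine_params):
        """Saturable elimination accumulates more than proportionally."""
        m1 = sd.regimen_daily_means(fluoxetine_params, 40.0, 24, 10)
        m2 = sd.regimen_daily_means(fluoxetine_params, 80.0, 24, 10)
        assert m2[-1] / m1[-1] > 2.05

    def test_daily_means_nondecreasing_under_constant_dosing(self, fluoxetine_params):
        means = sd.regimen_daily_means(fluoxetine_params, 40.0, 24, 15)
        assert np.all(np.diff(means) > 0)

    def test_published_regimen_daily_means(self, fluoxetine_params):
        """40 mg once daily with the published constants reproduces the
        published day-1 and day-30 daily means (30.8 / 149.0 ng/ml)."""
        means = sd.regimen_daily_means(fluoxetine_params, 40.0, 24, 30)
        assert means[0] == pytest.approx(30.8, rel=0.03)
        assert means[29] == pytest.approx(149.0, rel=0.03)

    def test_horizon_must_cover_doses(self, fluoxetine_params):
        with pytest.raises(ValidationError):
            sd.simulate_mm(fluoxetine_params, sd.DoseSchedule.once_daily(40, 10), 48.0)


class TestDailyMean:
    def test_constant_profile(self):
        t = np.linspace(0, 72, 721)
        prof = sd.ConcentrationProfile(times=t, concentrations=np.full_like(t, 7.5))
        for day in (1, 2, 3):
            assert sd.daily_mean(prof, day) == pytest.approx(7.5, rel=1e-12)

    def test_triangular_profile_hand_quadrature(self):
        """Rise 0->12 ng/ml over 12 h, fall back to 0 by 24 h: the area is
        12*12 = 144 ng/ml*h, so the daily mean is 6 ng/ml."""
        t = np.linspace(0, 24, 241)
        c = np.where(t <= 12, t, 24 - t)
        prof = sd.ConcentrationProfile(times=t, concentrations=c)
        assert sd.daily_mean(prof, 1) == pytest.approx(6.0, rel=1e-12)

    def test_window_outside_grid_raises(self):
        t = np.linspace(0, 24, 241)
        prof = sd.ConcentrationProfile(times=t, concentrations=np.ones_like(t))
        with pytest.raises(HorizonError):
            sd.daily_mean(prof, 2)


class TestSingleDoseMetrics:
    def test_monotone_bolus_profile_peaks_at_first_point(self):
        t = np.linspace(0, 100, 1001)
        lam = 0.05
        prof = sd.ConcentrationProfile(times=t, concentrations=50 * np.exp(-lam * t))
        cmax, tmax, t_half = sd.single_dose_metrics(prof)
        assert cmax == pytest.approx(50.0)
        assert tmax == 0.0
        assert t_half == pytest.approx(np.log(2) / lam, rel=1e-9)

    def test_linear_drug_recovers_elimination_half_life(self):
        params = sd.LinearPKParams(volume=500, absorption_rate=5.0,
                                   elimination_rate=np.log(2) / 20.0)
        prof = sd.single_dose_profile(params, 30.0)
        _, _, t_half = sd.single_dose_metrics(prof)
        assert t_half == pytest.approx(20.0, rel=1e-6)

    def test_published_fluoxetine_triple(self, fluoxetine_params):
        """One 40 mg dose: Cmax ~ 35 ng/ml, Tmax ~ 7 h, terminal
        t1/2 ~ 48 h (the published single-dose observables)."""
        prof = sd.single_dose_profile(fluoxetine_params, 40.0)
        cmax, tmax, t_half = sd.single_dose_metrics(prof)
        assert cmax == pytest.approx(35.0, rel=0.05)
        assert tmax == pytest.approx(7.0, rel=0.05)
        assert t_half == pytest.approx(48.0, rel=0.05)

    def test_short_horizon_raises(self, fluoxetine_params):
        prof = sd.simulate_mm(fluoxetine_params, sd.DoseSchedule.single(40.0), 24.0)
        with pytest.raises(HorizonError):
            sd.single_dose_metrics(prof)


class TestSteadyState:
    def test_zero_dose(self, sample_linear):
        css, day = sd.steady_state_cave(sample_linear, 0.0)
        assert css == 0.0 and day == 1

    def test_linear_css_matches_auc_over_interval(self, sample_linear):
        """At steady state the daily mean equals the single-dose AUC
        divided by the interval: (D/V)/(ke*24)."""
        css, _ = sd.steady_state_cave(sample_linear, 51.0, 24)
        ke, v = sample_linear.elimination_rate, sample_linear.volume
        expected = 51.0 * 1000.0 / v / (ke * 24.0)
        assert css == pytest.approx(expected, rel=2e-3)

    def test_published_fluoxetine_css(self, fluoxetine_params):
        css, day = sd.steady_state_cave(fluoxetine_params, 40.0, 24)
        assert css == pytest.approx(149.0, rel=0.03)
        assert day <= 30

    def test_nonconvergence_carries_last_value(self, fluoxetine_params):
        with pytest.raises(ConvergenceError) as err:
            sd.steady_state_cave(fluoxetine_params, 40.0, 24,
                                 tolerance=1e-9, max_days=10)
        assert err.value.last_value is not None
        assert err.value.last_value > 0

    def test_tolerance_domain(self, sample_linear):
        with pytest.raises(ValidationError):
            sd.steady_state_cave(sample_linear, 40.0, 24, tolerance=0.5)


class TestProfileValidation:
    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValidationError):
            sd.ConcentrationProfile(times=np.array([0.0, 2.0, 1.0]),
                                    concentrations=np.zeros(3))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            sd.ConcentrationProfile(times=np.array([0.0, 1.0]),
                                    concentrations=np.array([0.0, -1.0]))

    def test_resolution_bound(self, sample_linear):
        with pytest.raises(ValidationError):
            sd.simulate_linear(sample_linear, sd.DoseSchedule.empty(), 24.0,
                               resolution=1.0)
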