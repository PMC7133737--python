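"""Non-compartmental analysis estimators against closed-form oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

import pbpkit as pk
from pbpkit.model import ConcentrationTimeProfile
from pbpkit.nca import (
    LN2,
    ExtrapolationUnavailableWarning,
    InsufficientDataError,
    NoTerminalPhaseError,
)


def profile(times, concs, **kw):
    return ConcentrationTimeProfile(
        compartment="plasma",
        times_hr=np.asarray(times, dtype=float),
        concentrations_ng_ml=np.asarray(concs, dtype=float),
        **kw,
    )


class TestTerminalSlope:
    def test_exact_exponential_recovers_ke_exactly(self):
        t = np.linspace(0.0, 10.0, 51)
        fit = pk.terminal_slope(profile(t, np.exp(-t)))
        assert fit.ke_per_hr == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.t_half_hr == pytest.approx(LN2, rel=1e-12)

    def test_long_half_life_matches_reported_rate_constant(self):
        # terminal half-life 91.13 hr -> ke = 0.0076 1/hr to 2 s.f.
        t = pk.default_output_grid(0.0, 24.0, 0.05)
        fit = pk.terminal_slope(profile(t, 10.0 * np.exp(-LN2 / 91.13 * t)))
        assert fit.ke_per_hr == pytest.approx(0.0076, rel=1e-2)

    def test_matches_brute_force_regression_on_selected_window(self):
        rng = np.random.default_rng(11)
        t = pk.default_output_grid(0.0, 24.0, 1.0)
        c = 50.0 * np.exp(-0.2 * t) * rng.lognormal(0.0, 0.1, t.size)
        fit = pk.terminal_slope(profile(t, c))
        # independent oracle: plain least squares over the same points
        tt, yy = t[-fit.n_points :], np.log(c[-fit.n_points :])
        slope = np.polyfit(tt, yy, 1)[0]
        assert fit.ke_per_hr == pytest.approx(-slope, rel=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            pk.terminal_slope(profile([0.0, 1.0, 2.0], [10.0, 5.0, 2.5]))

    def test_rising_tail_has_no_terminal_phase(self):
        t = np.arange(10.0)
        c = [1.0, 10.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 8.5, 9.0]
        with pytest.raises(NoTerminalPhaseError):
            pk.terminal_slope(profile(t, c))


class TestAUC:
    def test_constant_concentration_unit_area(self):
        with pytest.warns(ExtrapolationUnavailableWarning):
            res = pk.auc(profile([0.0, 0.5, 1.0], [1.0, 1.0, 1.0]))
        assert res.auc_0_t_ng_hr_ml == pytest.approx(1.0)

    def test_exact_exponential_extrapolates_to_c0_over_ke(self):
        t = np.linspace(0.0, 10.0, 201)
        res = pk.auc(profile(t, np.exp(-t)), ke_per_hr=1.0)
        assert res.auc_0_inf_ng_hr_ml == pytest.approx(1.0, rel=1e-9)
        # log-down trapezoid is exact on an exponential
        assert res.auc_0_t_ng_hr_ml == pytest.approx(1.0 - np.exp(-10.0), rel=1e-12)

    def test_hand_computed_log_down_trapezoid(self):
        # segments 10->5 and 5->2.5 over 1 hr each: (10-5)/ln2 + (5-2.5)/ln2
        with pytest.warns(ExtrapolationUnavailableWarning):
            res = pk.auc(profile([0.0, 1.0, 2.0], [10.0, 5.0, 2.5]))
        assert res.auc_0_t_ng_hr_ml == pytest.approx(7.5 / np.log(2.0), rel=1e-12)

    def test_aumc_matches_quadrature_oracle(self):
        t = np.linspace(0.0, 20.0, 4001)
        c = 5.0 * np.exp(-2.0 * t) + 1.0 * np.exp(-0.1 * t)
        res = pk.auc(profile(t, c), ke_per_hr=0.1)
        oracle, _ = quad(lambda x: x * (5.0 * np.exp(-2.0 * x) + np.exp(-0.1 * x)), 0, 20)
        assert res.aumc_0_t_ng_hr2_ml == pytest.approx(oracle, rel=1e-6)

    def test_missing_ke_with_positive_tail_warns(self):
        with pytest.warns(ExtrapolationUnavailableWarning):
            res = pk.auc(profile([0.0, 1.0, 2.0], [10.0, 5.0, 2.5]))
        assert res.auc_0_inf_ng_hr_ml is None

    def test_grid_refinement_is_second_order(self):
        # mixed rising/falling profile so neither rule is exact
        f = lambda x: 100.0 * x * np.exp(-0.5 * x)
        truth, _ = quad(f, 0.0, 24.0)
        errors = []
        for step in (2.0, 1.0, 0.5):
            t = pk.default_output_grid(0.0, 24.0, step)
            with pytest.warns(ExtrapolationUnavailableWarning):
                errors.append(abs(pk.auc(profile(t, f(t))).auc_0_t_ng_hr_ml - truth))
        assert errors[0] > errors[1] > errors[2]
        # halving the step shrinks the error ~4x
        assert errors[0] / errors[1] > 2.5
        assert errors[1] / errors[2] > 2.5


class TestPkSummary:
    def test_identity_ring_on_biexponential(self):
        t = np.linspace(0.0, 48.0, 961)
        c = 5.0 * np.exp(-2.0 * t) + 1.0 * np.exp(-0.1 * t)
        s = pk.pk_summary(profile(t, c), dose_mg_per_kg=0.1)
        dose_ng_per_kg = 0.1e6
        assert s.t_half_hr * s.ke_per_hr == pytest.approx(LN2, rel=1e-12)
        assert s.cl_ml_min_kg * 60.0 * s.auc_0_inf_ng_hr_ml == pytest.approx(
            dose_ng_per_kg, rel=1e-9
        )
        assert s.vd_l_kg * 1000.0 * s.ke_per_hr == pytest.approx(
            s.cl_ml_min_kg * 60.0, rel=1e-9
        )
        assert s.mrt_hr * s.auc_0_inf_ng_hr_ml == pytest.approx(
            s.aumc_0_inf_ng_hr2_ml, rel=1e-9
        )
        assert s.auc_0_inf_ng_hr_ml >= s.auc_0_t_ng_hr_ml
        assert 0.0 <= s.extrapolated_fraction < 1.0

    def test_reported_volume_of_distribution_consistency(self):
        # mono-exponential tuned so AUC = dose/CL at CL = 4.58 ml/min/kg,
        # t1/2 = 104.58 hr  ->  Vd = CL*t1/2/ln2 = 41.5 L/kg (3 s.f.)
        ke = LN2 / 104.58
        auc_target = 0.1e6 / (4.58 * 60.0)
        c0 = auc_target * ke
        t = pk.default_output_grid(0.0, 600.0, 0.5)
        s = pk.pk_summary(profile(t, c0 * np.exp(-ke * t)), dose_mg_per_kg=0.1)
        assert s.vd_l_kg == pytest.approx(41.5, abs=0.05)
        assert s.cl_ml_min_kg == pytest.approx(4.58, rel=1e-3)

    def test_cmax_reporting_convention_skips_time_zero(self):
        t = pk.default_output_grid(0.0, 5.0, 0.5)
        c = 10.0 * np.exp(-0.3 * t)
        s = pk.pk_summary(profile(t, c), dose_mg_per_kg=0.1)
        assert s.tmax_hr == 0.5  # first positive grid time, not t = 0
        s_all = pk.pk_summary(profile(t, c), dose_mg_per_kg=0.1, exclude_time_zero=False)
        assert s_all.tmax_hr == 0.0

    def test_all_zero_profile_raises(self):
        with pytest.raises(InsufficientDataError):
            pk.pk_summary(profile(np.arange(5.0), np.zeros(5)), dose_mg_per_kg=0.1)

    def test_nonpositive_dose_rejected(self):
        t = np.linspace(0.0, 5.0, 20)
        with pytest.raises(ValueError):
            pk.pk_summary(profile(t, np.exp(-t)), dose_mg_per_kg=0.0)
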