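"""Growth model evaluation, parameter recovery and group divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenokit import (GrowthModel, compare_groups, evaluate, fit_control,
                      fit_salt, simulate_growth)
from phenokit.growth import GrowthDomainError, GrowthFitError

CONTROL = (29.7391, 1.0830)
SALT = (5.7849, 1.2998)


class TestEvaluate:
    def test_area_zero_at_germination(self):
        assert evaluate(GrowthModel(*CONTROL), -21) == 0.0

    def test_area_at_treatment_start_matches_arithmetic(self):
        # independent one-line arithmetic of the exponential-minus-one form
        expected = 29.7391 * (1.0830 ** 21 - 1.0)
        assert evaluate(GrowthModel(*CONTROL), 0) == pytest.approx(expected, rel=1e-12)

    def test_null_salt_term_reduces_to_control(self):
        ctrl = GrowthModel(*CONTROL)
        salt = GrowthModel(*CONTROL, a2=0.0)
        days = np.arange(-21, 15)
        np.testing.assert_allclose(evaluate(salt, days), evaluate(ctrl, days))

    def test_pre_germination_day_rejected(self):
        with pytest.raises(GrowthDomainError, match="-22"):
            evaluate(GrowthModel(*CONTROL), -22)

    def test_as_printed_salt_exponent_goes_negative(self):
        # clocking the salt term from germination drives the curve negative
        model = GrowthModel(*CONTROL, *SALT, salt_term_offset=21.0)
        with pytest.raises(GrowthDomainError, match="negative area"):
            evaluate(model, np.arange(0, 15))

    def test_continuity_at_breakpoint_default_offset(self):
        model = GrowthModel(*CONTROL, *SALT)
        left = evaluate(model, 0.0)
        right = evaluate(model, np.nextafter(0.0, 1.0))
        assert abs(left - right) < 1e-9


class TestFitControl:
    def test_recovers_printed_parameters_noiselessly(self):
        table = simulate_growth(GrowthModel(*CONTROL), (-21, 14))
        fit = fit_control(table)
        assert fit.converged
        assert fit.model.a1 == pytest.approx(CONTROL[0], rel=1e-3)
        assert fit.model.r1 == pytest.approx(CONTROL[1], rel=1e-3)
        assert fit.rss <= 1e-8 * float((table["area_cm2"] ** 2).sum())

    def test_all_zero_data_gives_zero_amplitude_flagged(self):
        fit = fit_control((np.arange(-21, 15), np.zeros(36)))
        assert fit.model.a1 == 0.0
        assert fit.flags.get("r1_identifiable") is False

    def test_too_few_days_rejected(self):
        with pytest.raises(GrowthFitError):
            fit_control(([0, 1], [1.0, 2.0]))

    def test_noisy_recovery_median_error_below_one_percent(self):
        errs = []
        for seed in range(20):
            table = simulate_growth(GrowthModel(*CONTROL), (-21, 14),
                                    noise_sd=1.0, seed=seed)
            fit = fit_control(table)
            errs.append(abs(fit.model.r1 - CONTROL[1]) / CONTROL[1])
        assert np.median(errs) <= 0.01

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a1=st.floats(1.0, 100.0), r1=st.floats(1.01, 1.5))
    def test_recovery_property_noiseless(self, a1, r1):
        table = simulate_growth(GrowthModel(a1, r1), (-21, 14))
        fit = fit_control(table)
        assert fit.model.a1 == pytest.approx(a1, rel=1e-3)
        assert fit.model.r1 == pytest.approx(r1, rel=1e-3)

    def test_objective_never_worse_than_truth(self):
        truth = GrowthModel(*CONTROL)
        for seed in range(5):
            table = simulate_growth(truth, (-21, 14), noise_sd=2.0, seed=seed)
            fit = fit_control(table)
            resid = table["area_cm2"].to_numpy() - evaluate(
                truth, table["day"].to_numpy())
            assert fit.rss <= float(resid @ resid) + 1e-9


class TestFitSalt:
    def _salt_table(self):
        return simulate_growth(GrowthModel(*CONTROL, *SALT), (-21, 14))

    def test_recovers_salt_term_with_control_fixed(self):
        fit = fit_salt(self._salt_table(), control_params=CONTROL)
        assert fit.model.a2 == pytest.approx(SALT[0], rel=1e-3)
        assert fit.model.r2 == pytest.approx(SALT[1], rel=1e-3)

    def test_null_salt_effect_estimated_as_zero(self):
        table = simulate_growth(GrowthModel(*CONTROL), (-21, 14))
        fit = fit_salt(table, control_params=CONTROL)
        assert fit.model.a2 <= 1e-6

    def test_all_rows_pre_breakpoint_is_an_error(self):
        table = simulate_growth(GrowthModel(*CONTROL), (-21, 0))
        with pytest.raises(GrowthFitError, match="pre-breakpoint"):
            fit_salt(table, control_params=CONTROL)

    def test_joint_free_fit_matches_fixed_control_optimum(self):
        table = self._salt_table()
        fixed = fit_salt(table, control_params=CONTROL)
        free = fit_salt(table)
        assert free.model.a2 == pytest.approx(fixed.model.a2, rel=1e-2)
        assert free.model.r2 == pytest.approx(fixed.model.r2, rel=1e-2)
        assert free.rss <= fixed.rss + 1e-9


class TestCompareGroups:
    def _fits(self):
        ctrl = fit_control(simulate_growth(GrowthModel(*CONTROL), (-21, 14)))
        salt = fit_salt(simulate_growth(GrowthModel(*CONTROL, *SALT), (-21, 14)),
                        control_params=(ctrl.model.a1, ctrl.model.r1))
        return ctrl, salt

    def test_identical_models_never_diverge(self):
        ctrl = fit_control(simulate_growth(GrowthModel(*CONTROL), (-21, 14)))
        assert compare_groups(ctrl, ctrl) is None

    def test_divergence_day_matches_brute_force_scan(self):
        ctrl, salt = self._fits()
        # exhaustive integer-day oracle on the printed parameter values
        oracle = None
        for day in range(1, 15):
            c = CONTROL[0] * (CONTROL[1] ** (day + 21) - 1)
            s = c - SALT[0] * (SALT[1] ** day - 1)
            if (c - s) > 0.05 * c:
                oracle = day
                break
        assert oracle == 4
        assert compare_groups(ctrl, salt, threshold=0.05) == oracle

    def test_zero_threshold_diverges_immediately(self):
        ctrl, salt = self._fits()
        assert compare_groups(ctrl, salt, threshold=0.0) == 1
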