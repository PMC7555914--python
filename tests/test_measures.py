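"""Measure algebra: predictive values, ratios, objectives, risk, calculator."""

import math

import numpy as np
import pytest

from damu import (
    LossSpec,
    MeasureBoundaryWarning,
    dam_table,
    objective_measures,
    oda,
    predictive_values,
    ratio_measures,
    risk,
)
from damu.measures import evaluate


class TestPredictiveValues:
    @pytest.mark.parametrize(
        "se, sp, v, ppv, npv",
        [
            (0.8, 0.8, 0.5, 0.8, 0.8),           # symmetric
            (1.0, 1.0, 0.3, 1.0, 1.0),           # perfect test
            (0.8346, 0.9881, 0.067,
             0.8346 * 0.067 / (0.8346 * 0.067 + 0.0119 * 0.933),
             0.9881 * 0.933 / (0.9881 * 0.933 + 0.1654 * 0.067)),
        ],
    )
    def test_values(self, se, sp, v, ppv, npv):
        got = predictive_values(se, sp, v)
        assert got == pytest.approx((ppv, npv), rel=1e-12)

    def test_zero_over_zero_is_nan_with_warning(self):
        with pytest.warns(MeasureBoundaryWarning):
            ppv, _ = predictive_values(0.0, 1.0, 0.5)
        assert math.isnan(ppv)
        with pytest.warns(MeasureBoundaryWarning):
            _, npv = predictive_values(1.0, 0.0, 0.5)
        assert math.isnan(npv)

    def test_ppv_increasing_npv_decreasing_in_prevalence(self):
        v = np.linspace(0.01, 0.99, 99)
        ppv, npv = predictive_values(0.85, 0.9, v)
        assert np.all(np.diff(ppv) > 0)
        assert np.all(np.diff(npv) < 0)


class TestRatioMeasures:
    def test_direct_arithmetic(self):
        dor, lrp, lrn = ratio_measures(0.8, 0.9)
        assert (dor, lrp, lrn) == pytest.approx((36.0, 8.0, 2.0 / 9.0), rel=1e-12)

    def test_uninformative_test(self):
        assert ratio_measures(0.5, 0.5) == pytest.approx((1.0, 1.0, 1.0))

    def test_boundary_conventions(self):
        dor, lrp, lrn = ratio_measures(1.0, 0.9)
        assert math.isinf(dor) and lrn == 0.0
        dor, lrp, _ = ratio_measures(0.9, 1.0)
        assert math.isinf(dor) and math.isinf(lrp)

    def test_indeterminate_is_nan_with_warning(self):
        with pytest.warns(MeasureBoundaryWarning):
            dor, _, lrn = ratio_measures(1.0, 0.0)
        assert math.isnan(dor) and math.isnan(lrn)

    def test_dor_equals_ratio_of_likelihood_ratios(self):
        rng = np.random.default_rng(7)
        se = rng.uniform(0.05, 0.95, 200)
        sp = rng.uniform(0.05, 0.95, 200)
        dor, lrp, lrn = ratio_measures(se, sp)
        assert np.max(np.abs(dor / (lrp / lrn) - 1.0)) <= 1e-12


class TestObjectivesAndRisk:
    @pytest.mark.parametrize(
        "se, sp, j, ed, cz",
        [
            (1.0, 1.0, 1.0, 0.0, 1.0),
            (0.5, 0.5, 0.0, math.sqrt(0.5), 0.25),
            (0.8, 0.9, 0.7, math.sqrt(0.05), 0.72),
        ],
    )
    def test_objective_measures(self, se, sp, j, ed, cz):
        assert objective_measures(se, sp) == pytest.approx((j, ed, cz), rel=1e-14)

    def test_oda(self):
        assert oda(1.0, 1.0, 0.3) == 1.0
        assert oda(0.8, 0.9, 0.0) == pytest.approx(0.9)
        assert oda(0.8346, 0.9881, 0.067) == pytest.approx(0.9778, abs=5e-4)

    def test_risk_procedure_loss_only(self):
        assert risk(0.3, 0.9, 0.2, LossSpec(1, 0, 0, 0, 0)) == 1.0

    def test_risk_no_misclassification_terms(self):
        loss = LossSpec(2.0, 3.0, 5.0, 7.0, 11.0)
        v = 0.25
        assert risk(1.0, 1.0, v, loss) == pytest.approx(2.0 + 3.0 * (1 - v) + 7.0 * v)

    def test_risk_case_study_arithmetic(self):
        loss = LossSpec(1, 0, 100, 0, 76)
        expected = 1 + 100 * 0.067 * (1 - 0.8346) + 76 * 0.933 * (1 - 0.9881)
        assert risk(0.8346, 0.9881, 0.067, loss) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.95, abs=0.01)

    def test_risk_misclassification_complements_oda(self, unit_loss):
        # loss (0,0,1,0,1): R = v(1-Se) + (1-v)(1-Sp) = 1 - ODA
        rng = np.random.default_rng(3)
        se, sp, v = rng.uniform(0, 1, (3, 100))
        assert np.allclose(risk(se, sp, v, unit_loss), 1.0 - oda(se, sp, v), atol=1e-14)

    def test_loss_spec_rejects_non_finite(self):
        with pytest.raises(ValueError, match="l_fn"):
            LossSpec(1.0, 0.0, math.inf, 0.0, 1.0)


class TestDamTable:
    def test_case_study_row(self, test1, loss):
        t = dam_table(2.26, test1, loss)
        assert t.se == pytest.approx(0.835, abs=5e-4)
        assert t.sp == pytest.approx(0.988, abs=5e-4)
        assert t.j == t.se + t.sp - 1.0
        assert t.cz == t.se * t.sp
        assert t.ed == pytest.approx(math.hypot(1 - t.se, 1 - t.sp), rel=1e-15)
        assert t.dor == pytest.approx(t.lr_pos / t.lr_neg, rel=1e-12)

    def test_equal_populations_chance_line(self, equal_pops):
        t = dam_table(1.3, equal_pops, None)
        assert t.j == pytest.approx(0.0, abs=1e-14)
        assert t.dor == pytest.approx(1.0, rel=1e-12)
        assert t.oda == pytest.approx(t.se * 0.3 + t.sp * 0.7, rel=1e-14)
        assert math.isnan(t.r)  # no loss supplied

    def test_boundary_limits(self, test1, loss):
        with pytest.warns(MeasureBoundaryWarning):  # LR+ hits 0/0
            t = dam_table(np.inf, test1, loss)
        assert (t.se, t.sp) == (0.0, 1.0)
        assert t.npv == pytest.approx(1.0 - test1.pop.v, rel=1e-12)

    def test_prevalence_invariance_of_conditional_measures(self, cfg, loss):
        from damu import PopulationPair, TestModel

        base = cfg.pop
        vals = []
        for v in (0.01, 0.3, 0.8):
            m = TestModel(PopulationPair(base.mu_d, base.sigma_d, base.mu_nd,
                                         base.sigma_nd, v), cfg.u_a)
            t = dam_table(2.0, m, loss)
            vals.append((t.dor, t.lr_pos, t.lr_neg, t.j, t.ed, t.cz))
        assert np.allclose(vals[0], vals[1], rtol=1e-14)
        assert np.allclose(vals[0], vals[2], rtol=1e-14)


class TestEvaluateDispatcher:
    def test_unknown_measure(self):
        with pytest.raises(ValueError, match="unknown measure"):
            evaluate("acc", 0.5, 0.5)

    def test_missing_prevalence(self):
        with pytest.raises(ValueError, match="prevalence"):
            evaluate("ppv", 0.5, 0.5)

    def test_risk_without_loss_is_nan(self):
        assert math.isnan(evaluate("r", 0.5, 0.5, v=0.1, loss=None))
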