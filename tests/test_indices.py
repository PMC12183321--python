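"""Metabolic index arithmetic, surrogates and threshold classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucopheno.curves import CPEPTIDE_GRID, AnalyteSeries
from glucopheno.indices import (
    Thresholds,
    body_fat_percent,
    classify_measures,
    disposition_index,
    hepatic_ir_index,
    incretin_effect,
    polygenic_score,
    surrogate_markers,
)
from glucopheno.kinetics import SecretionSeries


def _isr(rates, times=None):
    times = np.arange(0.0, 181.0, 15.0) if times is None else times
    rates = np.asarray(rates, float)
    return SecretionSeries(times, rates, 0.0, np.empty(0), 0.0)


def _cpep(values):
    return AnalyteSeries("p", "OGTT", "cpeptide", CPEPTIDE_GRID,
                         np.asarray(values, float))


def _iigi(values):
    return AnalyteSeries("p", "IIGI", "cpeptide", CPEPTIDE_GRID,
                         np.asarray(values, float))


class TestDispositionIndex:
    def test_constant_rate_arithmetic(self):
        """ISR=2 pmol/kg/min over [0,30] at SSPG 120 gives 60/120 = 0.5."""
        assert disposition_index(_isr(np.full(13, 2.0)), 120.0) == pytest.approx(0.5)

    def test_linearity_in_secretion(self):
        base = disposition_index(_isr(np.linspace(1, 4, 13)), 100.0)
        doubled = disposition_index(_isr(2 * np.linspace(1, 4, 13)), 100.0)
        assert doubled == pytest.approx(2 * base)

    def test_decreasing_in_sspg(self):
        isr = _isr(np.full(13, 3.0))
        assert disposition_index(isr, 200.0) < disposition_index(isr, 100.0)

    def test_nonpositive_sspg_rejected(self):
        with pytest.raises(ValueError):
            disposition_index(_isr(np.full(13, 2.0)), 0.0)


class TestIncretinEffect:
    def test_identical_series_gives_zero(self):
        v = 400 + 100 * np.arange(7.0)
        assert incretin_effect(_cpep(v), _iigi(v)) == pytest.approx(0.0)

    def test_zero_iigi_gives_100(self):
        assert incretin_effect(_cpep(np.full(7, 500.0)),
                               _iigi(np.zeros(7))) == pytest.approx(100.0)

    def test_auc_ratio_arithmetic(self):
        """AUC 200 vs 120 (constant series scaled to those areas) -> 40%."""
        ogtt = _cpep(np.full(7, 200.0 / 180.0))
        iigi = _iigi(np.full(7, 120.0 / 180.0))
        assert incretin_effect(ogtt, iigi) == pytest.approx(40.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        o = 300 + 400 * rng.random(7)
        i = 200 + 300 * rng.random(7)
        base = incretin_effect(_cpep(o), _iigi(i))
        scaled = incretin_effect(_cpep(c * o), _iigi(c * i))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        short = AnalyteSeries("p", "IIGI", "cpeptide", [0.0, 60.0, 180.0],
                              [1.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            incretin_effect(_cpep(np.full(7, 1.0)), short)


class TestBodyFat:
    def test_hand_computed_values(self):
        assert body_fat_percent(25, 50, 0) == pytest.approx(36.1, abs=1e-12)
        assert body_fat_percent(25, 50, 1) == pytest.approx(25.3, abs=1e-12)

    def test_sex_gap_is_exactly_coefficient(self):
        gap = body_fat_percent(27, 44, 1) - body_fat_percent(27, 44, 0)
        assert gap == pytest.approx(-10.8, abs=1e-12)

    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError):
            body_fat_percent(25, 50, 2)


class TestHepaticIndex:
    def test_unit_arguments_leave_intercept(self):
        assert hepatic_ir_index(1, 1, 1, 1) == pytest.approx(-0.091, abs=1e-12)

    def test_monotone_in_insulin_and_hdl(self):
        lo = hepatic_ir_index(1000, 30, 60, 26)
        assert hepatic_ir_index(2000, 30, 60, 26) > lo
        assert hepatic_ir_index(1000, 30, 80, 26) < lo

    def test_nonpositive_argument_rejected(self):
        with pytest.raises(ValueError):
            hepatic_ir_index(0, 30, 60, 26)


class TestSurrogates:
    def test_homa_values(self):
        homa_ir, homa_b, _ = surrogate_markers(90.0, 4.5)
        assert homa_ir == pytest.approx(1.0)
        assert homa_b == pytest.approx(60.0)  # 1620 / 27

    def test_matsuda_fasting_form(self):
        _, _, matsuda = surrogate_markers(90.0, 4.5)
        assert matsuda == pytest.approx(10000.0 / (90.0 * 4.5))

    def test_homa_ir_increasing_in_both_inputs(self):
        base = surrogate_markers(90.0, 5.0)[0]
        assert surrogate_markers(110.0, 5.0)[0] > base
        assert surrogate_markers(90.0, 7.0)[0] > base

    def test_homa_b_undefined_below_63(self):
        with pytest.warns(RuntimeWarning):
            _, homa_b, _ = surrogate_markers(60.0, 5.0)
        assert np.isnan(homa_b)


class TestPolygenicScore:
    def test_no_missing_sum(self):
        w = {f"v{i}": 0.2 for i in range(5)}
        d = {f"v{i}": 1.0 for i in range(5)}
        assert polygenic_score(d, w) == pytest.approx(5 * 0.2)

    def test_missing_variant_population_substitution(self):
        """A missing variant contributes 2 * weight * frequency."""
        score = polygenic_score({"a": 1.0}, {"a": 0.5, "b": 2.0},
                                allele_freqs={"b": 0.5})
        assert score == pytest.approx(0.5 + 2.0)

    def test_empty_weights_warn_and_return_zero(self):
        with pytest.warns(RuntimeWarning):
            assert polygenic_score({}, {}) == 0.0

    def test_unresolvable_variant_rejected(self):
        with pytest.raises(LookupError):
            polygenic_score({}, {"x": 1.0})


class TestClassification:
    def test_insulin_sensitive_at_sspg_60(self):
        labels = classify_measures({"sspg": 60.0})
        assert labels["muscle_class"] == "IS" and not labels["muscle_ir"]

    def test_sspg_boundary_counts_as_resistant(self):
        assert classify_measures({"sspg": 120.0})["muscle_class"] == "IR"

    def test_intermediate_incretin_effect(self):
        assert classify_measures({"ie_pct": 63.7})["incretin_class"] == "intermediate"

    def test_di_binary_boundary_assigned_normal(self):
        labels = classify_measures({"di": 1.58})
        assert labels["beta_dysfunction"] is False

    @pytest.mark.parametrize(
        "di,expected",
        [(2.58, "normal"), (1.5, "intermediate"), (0.9, "dysfunction")],
    )
    def test_di_ternary_bands(self, di, expected):
        assert classify_measures({"di": di})["beta_class"] == expected

    @pytest.mark.parametrize(
        "hep,expected", [(3.5, "IS"), (4.3, "intermediate"), (5.0, "IR")]
    )
    def test_hepatic_ternary_bands(self, hep, expected):
        assert classify_measures({"hepatic_ir": hep})["hepatic_class"] == expected

    def test_missing_measure_warns_and_omits_label(self):
        with pytest.warns(RuntimeWarning):
            labels = classify_measures({"sspg": 100.0})
        assert "beta_class" not in labels

    def test_thresholds_configurable(self):
        th = Thresholds(sspg_ir=150.0)
        assert classify_measures({"sspg": 130.0}, th)["muscle_class"] == "IS"
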