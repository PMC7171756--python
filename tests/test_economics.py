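"""Thresholds, currency conversion, ICERs, AE screening, break-even price."""

import math

import numpy as np
import pytest
from scipy import stats

from hcc_cea.economics import (
    AEItem,
    ArmTotals,
    Threshold,
    ae_screen,
    breakeven_drug_price,
    compute_icer,
    convert_currency,
    threshold_value,
    thresholds_for,
    weighted_ae_cost,
)


class TestThresholds:
    @pytest.mark.parametrize(
        "gdp,factor,expected",
        [
            (54457, 3, 163_371),
            (54457, 6, 326_742),
            (54457, 9, 490_113),
            (62853, 3, 188_559),
            (62853, 6, 377_118),
            (62853, 9, 565_677),
        ],
    )
    def test_gdp_multiple_thresholds_exact(self, gdp, factor, expected):
        assert threshold_value(gdp, factor) == expected

    def test_zero_factor(self):
        assert threshold_value(1000.0, 0) == 0.0

    def test_thresholds_for_builds_3_6_9(self):
        values = [t.value for t in thresholds_for(54457)]
        assert values == [163_371, 326_742, 490_113]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            Threshold(-1.0, 3)
        with pytest.raises(ValueError):
            Threshold(1000.0, -1)


class TestCurrencyConversion:
    def test_nice_threshold_conversion(self):
        assert round(convert_currency(30_000, 0.689)) == 43_541

    def test_review_threshold_conversion(self):
        assert round(convert_currency(138_000, 0.689)) == 200_290

    def test_zero_amount(self):
        assert convert_currency(0.0, 0.741) == 0.0

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            convert_currency(100.0, 0.0)


def make_result(d_cost, d_ly, d_qaly, base_cost=2064.0, base_ly=0.973, base_qaly=0.698):
    bsc = ArmTotals("bsc", base_cost, base_ly, base_qaly)
    cabo = ArmTotals(
        "cabozantinib", base_cost + d_cost, base_ly + d_ly, base_qaly + d_qaly
    )
    return compute_icer(cabo, bsc, country="germany")


class TestComputeIcer:
    def test_published_german_increments(self):
        r = make_result(54_556.0, 0.178, 0.146)
        assert r.icer_per_ly == pytest.approx(306_494, abs=1)
        assert r.icer_per_ly == pytest.approx(306_778, rel=0.001)
        assert r.icer_per_qaly == pytest.approx(375_470, rel=0.005)

    def test_published_us_increments(self):
        r = make_result(172_866.0, 0.178, 0.146)
        assert r.icer_per_ly == pytest.approx(972_049, rel=0.001)
        assert r.icer_per_qaly == pytest.approx(1_189_706, rel=0.005)

    def test_equal_costs_with_gain_is_dominant(self):
        r = make_result(0.0, 0.1, 0.1)
        assert r.icer_per_qaly == 0.0
        assert r.dominance_qaly == "dominant"

    def test_costlier_without_gain_is_dominated(self):
        r = make_result(1000.0, -0.05, -0.05)
        assert math.isnan(r.icer_per_qaly)
        assert r.dominance_qaly == "dominated"

    def test_translation_invariance(self):
        r1 = make_result(54_556.0, 0.178, 0.146, base_cost=2064.0)
        r2 = make_result(54_556.0, 0.178, 0.146, base_cost=99_999.0)
        assert r1.icer_per_ly == pytest.approx(r2.icer_per_ly)
        assert r1.d_cost == pytest.approx(r2.d_cost)

    def test_cost_effective_verdict_uses_nmb(self):
        r = make_result(54_556.0, 0.178, 0.146)
        assert not r.cost_effective(Threshold(54457, 3), "ly")
        assert r.cost_effective(Threshold(54457, 9), "ly")


class TestAeScreen:
    def test_equal_proportions_excluded(self):
        res = ae_screen(50, 100, 50, 100)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.include

    def test_trial_sized_difference_included(self):
        """Hand Pearson chi-squared (no correction) as the oracle."""
        a, na, b, nb = 80, 470, 10, 237
        obs = np.array([[a, na - a], [b, nb - b]], dtype=float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row @ col / obs.sum()
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2, df=1))
        res = ae_screen(a, na, b, nb)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)
        assert p < 0.05 and res.include

    def test_alpha_one_includes_any_valid_table(self):
        assert ae_screen(50, 100, 50, 100, alpha=1.0).include

    def test_zero_margin_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero-margin"):
            res = ae_screen(0, 100, 0, 200)
        assert not res.include and math.isnan(res.p_value)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ae_screen(101, 100, 5, 50)


class TestWeightedAeCost:
    def test_zero_incidence_contributes_nothing(self):
        assert weighted_ae_cost([AEItem("x", 0.0, True)]) == (0.0, 0.0)

    def test_recurring_item_linearity(self):
        # incidence 0.5 at monthly cost 24 -> 12 in every cycle
        assert weighted_ae_cost([AEItem("x", 0.5 * 24.0, True)]) == (12.0, 12.0)

    def test_published_german_cabozantinib_totals(self):
        """Incidence-weighted items from the published German cabozantinib
        column: recurring parts equal the bracketed subsequent-month values,
        one-time parts the first-month excess; totals land near the printed
        682 (139) AE-total row (item rounding explains the small gap)."""
        printed = {  # item -> (first month, subsequent months)
            "diarrhea": (271.0, 13.0),
            "hand_foot_syndrome": (42.0, 29.0),
            "fatigue": (15.0, 15.0),
            "nausea_vomiting": (93.0, 45.0),
            "hypertension": (17.0, 12.0),
            "abdominal_pain": (24.0, 0.0),
            "stomatitis": (4.0, 4.0),
            "rash": (16.0, 16.0),
            "thrombocytopenia": (32.0, 0.0),
            "dyspepsia": (2.0, 0.0),
            "hypokalemia": (88.0, 1.0),
            "pain_in_extremity": (2.0, 0.0),
            "hypothyroidism": (13.0, 0.5),
            "hypomagnesemia": (33.0, 0.0),
            "urinary_tract_infection": (26.0, 0.0),
        }
        items = []
        for name, (first, sub) in printed.items():
            if sub > 0:
                items.append(AEItem(name, sub, recurring=True))
            if first > sub:
                items.append(AEItem(name, first - sub, recurring=False))
        first, subsequent = weighted_ae_cost(items)
        assert first == pytest.approx(682.0, rel=0.05)
        assert subsequent == pytest.approx(139.0, rel=0.05)


class TestBreakEven:
    @staticmethod
    def icer_fn(price):
        # linear stand-in: ICER rises $50/LY per $ of monthly price
        return 10_000.0 + 50.0 * price

    def test_fixed_point_returns_current_price(self):
        res = breakeven_drug_price(self.icer_fn, self.icer_fn(6841.0), 8461.0)
        assert res.status == "break_even"
        assert res.price == pytest.approx(6841.0, abs=1.0)

    def test_huge_threshold_caps_at_list_price(self):
        res = breakeven_drug_price(self.icer_fn, 1e12, 8461.0)
        assert res.status == "cost_effective_at_list_price"
        assert res.price == 8461.0

    def test_unreachable_threshold_reports_never(self):
        res = breakeven_drug_price(self.icer_fn, 5_000.0, 8461.0)
        assert res.status == "never" and res.price is None

    def test_breakeven_price_monotone_in_threshold(self):
        prices = [
            breakeven_drug_price(self.icer_fn, th, 8461.0).price
            for th in (100_000.0, 200_000.0, 300_000.0)
        ]
        assert prices[0] < prices[1] < prices[2]
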