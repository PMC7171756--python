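"""Parametric survival families, least-squares fitting and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from hcc_cea.survival import (
    FAMILIES,
    KMCurve,
    ParametricFit,
    SurvivalDistribution,
    cycle_transition_prob,
    fit_parametric,
    information_criteria,
    select_best,
    survival_at,
)

LN2 = math.log(2.0)


def random_distribution(family: str, rng) -> SurvivalDistribution:
    if family == "exponential":
        return SurvivalDistribution.exponential(rng.uniform(0.02, 0.5))
    if family == "weibull":
        return SurvivalDistribution.weibull(rng.uniform(2, 20), rng.uniform(0.5, 3))
    if family == "gompertz":
        return SurvivalDistribution.gompertz(rng.uniform(0.01, 0.5), rng.uniform(0.01, 0.3))
    if family == "loglogistic":
        return SurvivalDistribution.loglogistic(rng.uniform(2, 20), rng.uniform(0.5, 3))
    return SurvivalDistribution.lognormal(rng.uniform(0.5, 3), rng.uniform(0.3, 1.5))


class TestSurvivalFunctions:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_survival_starts_at_one(self, family, rng):
        dist = random_distribution(family, rng)
        assert survival_at(dist, 0.0) == pytest.approx(1.0)

    def test_exponential_median(self):
        dist = SurvivalDistribution.exponential(0.1)
        assert survival_at(dist, 6.9315) == pytest.approx(0.5, abs=1e-4)
        assert dist.median() == pytest.approx(LN2 / 0.1)

    def test_weibull_median_matches_trial_os(self):
        # scale obtained by solving S(10.2) = 0.5 at shape 1.3
        dist = SurvivalDistribution.weibull(13.52, 1.3)
        assert survival_at(dist, 10.2) == pytest.approx(0.5, abs=0.002)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_median_is_half_survival_point(self, family, rng):
        dist = random_distribution(family, rng)
        assert survival_at(dist, dist.median()) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_inverse_survival_round_trip(self, family, rng):
        dist = random_distribution(family, rng)
        for u in (0.9, 0.5, 0.1):
            assert survival_at(dist, dist.inverse_survival(u)) == pytest.approx(u)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(SurvivalDistribution.exponential(0.1), -1.0)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", (-0.1,)),
            ("weibull", (5.0, -1.0)),
            ("gompertz", (-0.1, 0.2)),
            ("loglogistic", (0.0, 1.0)),
            ("lognormal", (1.0, 0.0)),
        ],
    )
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(ValueError):
            SurvivalDistribution(family, params)

    @given(st.sampled_from(FAMILIES), st.integers(0, 2**32 - 1))
    @hyp_settings(derandomize=True, max_examples=60, deadline=None)
    def test_survival_monotone_and_transition_probs_valid(self, family, seed):
        """S is non-increasing on a dense grid and every per-cycle transition
        probability over the 84-cycle horizon lies in [0, 1]."""
        rng = np.random.default_rng(seed)
        dist = random_distribution(family, rng)
        grid = np.linspace(0, 120, 500)
        s = dist.survival(grid)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1 + 1e-12))
        probs = [cycle_transition_prob(dist, k, 1.0) for k in range(84)]
        assert all(0.0 <= p <= 1.0 for p in probs)


class TestCycleTransitionProb:
    def test_exponential_memoryless(self):
        dist = SurvivalDistribution.exponential(0.1)
        expected = 1.0 - math.exp(-0.1)
        for cycle in (0, 1, 10, 50):
            assert cycle_transition_prob(dist, cycle, 1.0) == pytest.approx(expected)

    def test_weibull_shape_one_reduces_to_exponential(self):
        lam = 0.1
        wei = SurvivalDistribution.weibull(1.0 / lam, 1.0)
        exp = SurvivalDistribution.exponential(lam)
        for cycle in range(0, 30, 5):
            assert cycle_transition_prob(wei, cycle, 1.0) == pytest.approx(
                cycle_transition_prob(exp, cycle, 1.0)
            )

    def test_increasing_hazard_gives_increasing_transition_prob(self):
        dist = SurvivalDistribution.weibull(13.52, 1.3)
        assert cycle_transition_prob(dist, 10, 1.0) > cycle_transition_prob(dist, 1, 1.0)

    def test_underflowed_survival_gives_certain_transition(self):
        dist = SurvivalDistribution.weibull(1.0, 3.0)
        assert cycle_transition_prob(dist, 5000, 1.0) == 1.0


class TestInformationCriteria:
    def test_least_squares_aic_value(self):
        aic, bic = information_criteria(0.012, 25, 2)
        assert aic == pytest.approx(25 * math.log(0.012 / 25) + 4, rel=1e-12)
        assert aic == pytest.approx(-187.0, abs=0.1)
        assert bic == pytest.approx(25 * math.log(0.012 / 25) + 2 * math.log(25))

    def test_unit_mean_ssr_leaves_only_penalty(self):
        aic, _ = information_criteria(25.0, 25, 3)
        assert aic == pytest.approx(6.0)

    def test_extra_parameter_costs_two_aic_points(self):
        aic2, _ = information_criteria(0.05, 30, 2)
        aic3, _ = information_criteria(0.05, 30, 3)
        assert aic3 - aic2 == pytest.approx(2.0)

    def test_perfect_fit_returns_sentinel_with_warning(self):
        with pytest.warns(RuntimeWarning):
            aic, bic = information_criteria(0.0, 25, 2)
        assert aic == -math.inf and bic == -math.inf


class TestFitting:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(1.0, 21.0)
        curve = KMCurve("OS", "bsc", tuple(t), tuple(np.exp(-0.2 * t)))
        fit = fit_parametric(curve, "exponential")
        assert fit.distribution.params[0] == pytest.approx(0.2, abs=1e-6)
        assert fit.ssr < 1e-12

    @pytest.mark.parametrize("family", FAMILIES)
    def test_noiseless_self_consistency(self, family, rng):
        dist = random_distribution(family, rng)
        t = np.linspace(0.5, 3 * dist.median(), 24)
        curve = KMCurve("OS", "bsc", tuple(t), tuple(dist.survival(t)))
        fit = fit_parametric(curve, family)
        assert fit.ssr < 1e-8

    def test_fit_never_beaten_by_grid_search_oracle(self):
        """On 20 random noisy curves the optimizer's Weibull SSR is at most
        the minimum over an exhaustive 50x50 (scale, shape) grid."""
        rng = np.random.default_rng(11)
        scales = np.geomspace(0.5, 60.0, 50)
        shapes = np.geomspace(0.3, 5.0, 50)
        for _ in range(20):
            true = random_distribution("weibull", rng)
            t = np.arange(1.0, 25.0)
            s = true.survival(t) + rng.normal(0, 0.02, size=t.size)
            s = np.clip(np.minimum.accumulate(s), 0.0, 1.0)
            curve = KMCurve("OS", "cabozantinib", tuple(t), tuple(s))
            fit = fit_parametric(curve, "weibull")
            grid_s = np.exp(
                -((t[None, None, :] / scales[:, None, None]) ** shapes[None, :, None])
            )
            grid_ssr = ((grid_s - s) ** 2).sum(axis=-1).min()
            assert fit.ssr <= grid_ssr + 1e-9

    def test_degenerate_flat_curve_flagged(self):
        t = np.arange(1.0, 8.0)
        curve = KMCurve("OS", "bsc", tuple(t), tuple(np.full(7, 0.8)))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_parametric(curve, "exponential")
        assert fit.degenerate
        assert fit.distribution.params[0] <= 1e-10

    def test_too_few_points_rejected(self):
        curve = KMCurve("OS", "bsc", (1.0, 2.0), (0.9, 0.8))
        with pytest.raises(ValueError):
            fit_parametric(curve, "weibull")


class TestSelectBest:
    @staticmethod
    def _fit(family, ssr, aic, bic):
        dist = {
            "exponential": SurvivalDistribution.exponential(0.1),
            "weibull": SurvivalDistribution.weibull(10, 1.2),
            "gompertz": SurvivalDistribution.gompertz(0.1, 0.05),
            "loglogistic": SurvivalDistribution.loglogistic(10, 1.5),
            "lognormal": SurvivalDistribution.lognormal(2.0, 0.8),
        }[family]
        return ParametricFit(dist, ssr, aic, bic, 25, 2)

    def test_published_pfs_goodness_of_fit_selects_weibull(self):
        """The printed SSR/AIC table for cabozantinib PFS ranks Weibull first."""
        fits = [
            self._fit("weibull", 0.012, -188, -185),
            self._fit("exponential", 0.026, -170, -168),
            self._fit("gompertz", 0.016, -180, -178),
            self._fit("loglogistic", 0.021, -173, -171),
            self._fit("lognormal", 0.015, -181, -179),
        ]
        sel = select_best(fits, endpoint="PFS")
        assert sel.family == "weibull"
        assert sel.hazard_warning is None
        assert list(sel.ranking["rank"]) == [1, 2, 3, 4, 5]

    def test_tie_break_follows_declared_family_order(self):
        fits = [
            self._fit("lognormal", 0.01, -100, -99),
            self._fit("weibull", 0.01, -100, -99),
        ]
        assert select_best(fits).family == "weibull"

    def test_vanishing_hazard_flagged_for_os_endpoint(self):
        fits = [
            self._fit("lognormal", 0.010, -200, -199),
            self._fit("weibull", 0.012, -190, -189),
        ]
        with pytest.warns(RuntimeWarning, match="hazard"):
            sel = select_best(fits, endpoint="OS")
        assert sel.family == "lognormal"
        assert sel.hazard_warning is not None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestKMCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            KMCurve("OS", "bsc", (1.0, 1.0), (0.9, 0.8))  # not strictly increasing
        with pytest.raises(ValueError):
            KMCurve("OS", "bsc", (1.0, 2.0), (0.8, 0.9))  # increasing survival
        with pytest.raises(ValueError):
            KMCurve("OS", "bsc", (1.0, 2.0), (1.2, 0.8))  # out of [0, 1]
        with pytest.raises(ValueError):
            KMCurve("DFS", "bsc", (1.0,), (0.9,))  # unknown endpoint

    def test_grid_sampling_is_right_continuous_step(self):
        curve = KMCurve("OS", "bsc", (0.0, 1.5, 3.0), (1.0, 0.6, 0.2))
        sampled = curve.on_grid([0.0, 1.0, 2.0, 3.0, 10.0])
        assert sampled.surv == (1.0, 1.0, 0.6, 0.2, 0.2)
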