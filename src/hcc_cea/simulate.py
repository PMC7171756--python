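"""Synthetic trial data: simulated survival times, KM curves and fixtures.

The published analysis rests on digitized Kaplan-Meier curves from the
CELESTIAL trial (cabozantinib vs placebo in second-line advanced HCC) that
are not deposited as coordinates. This module generates everything the
pipeline consumes instead: individual event times drawn from parametric
survival distributions with right-censoring, product-limit KM curves, and a
complete CELESTIAL-like input bundle — four Weibull curves median-matched to
the printed trial medians (OS 10.2 vs 8.0 months, PFS 5.2 vs 1.9 months),
the published per-country monthly cost tables, base-case utilities
(0.76 stable / 0.68 progressive) and GDP-per-capita threshold inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ModelSettings, StrategyInputs
from .economics import Threshold, thresholds_for
from .survival import KMCurve, SurvivalDistribution

ARMS = ("cabozantinib", "bsc")
ENDPOINTS = ("PFS", "OS")
COUNTRIES = ("germany", "us")

#: median survival (months) printed for the CELESTIAL trial
TRIAL_MEDIANS: dict[tuple[str, str], float] = {
    ("OS", "cabozantinib"): 10.2,
    ("OS", "bsc"): 8.0,
    ("PFS", "cabozantinib"): 5.2,
    ("PFS", "bsc"): 1.9,
}

#: randomized subjects per arm in the trial
TRIAL_ARM_SIZES: dict[str, int] = {"cabozantinib": 470, "bsc": 237}

#: monthly costs in $ per (country, arm, category): (first cycle, subsequent)
#: brackets in the source table give deviating second-and-following-month costs
COST_TABLES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "germany": {
        "cabozantinib": {
            "consultation": (37.0, 37.0),
            "laboratory": (27.0, 14.0),
            "imaging": (93.0, 93.0),
            "adverse_events": (682.0, 139.0),
        },
        "bsc": {
            "consultation": (37.0, 37.0),
            "laboratory": (27.0, 14.0),
            "imaging": (93.0, 93.0),
            "adverse_events": (213.0, 52.0),
        },
    },
    "us": {
        "cabozantinib": {
            "consultation": (110.0, 75.0),
            "laboratory": (110.0, 55.0),
            "imaging": (162.0, 162.0),
            "adverse_events": (1673.0, 645.0),
        },
        "bsc": {
            "consultation": (110.0, 75.0),
            "laboratory": (110.0, 55.0),
            "imaging": (162.0, 162.0),
            "adverse_events": (557.0, 166.0),
        },
    },
}

#: monthly cabozantinib price per country (German AMNOG reimbursement amount;
#: US average cash price, April 2019)
DRUG_PRICE_MONTHLY: dict[str, float] = {"germany": 6841.0, "us": 21581.0}
#: German list price of a 30-portion package before the AMNOG rebate
LIST_PRICE_MONTHLY: dict[str, float] = {"germany": 8461.0, "us": 21581.0}

#: 2018 GDP per capita in $
GDP_PER_CAPITA: dict[str, float] = {"germany": 54457.0, "us": 62853.0}

BASE_UTILITIES: tuple[float, float] = (0.76, 0.68)

#: purchasing power parities of 2019, foreign units per $
PPP_RATES: dict[str, float] = {"eur": 0.741, "gbp": 0.689}

#: default Weibull shape for the fixture curves: > 1 gives the monotonically
#: increasing hazard reported for the fitted curves
DEFAULT_FIXTURE_SHAPE = 1.3


@dataclass(frozen=True)
class SimulatedCohort:
    """Per-subject follow-up times (months) and event indicators."""

    times: np.ndarray
    events: np.ndarray
    distribution: SurvivalDistribution
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=bool)
        if t.size != e.size or t.size == 0:
            raise ValueError("times and events must be non-empty, equal length")
        if np.any(t <= 0):
            raise ValueError("follow-up times must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def censor_fraction(self) -> float:
        return float(1.0 - self.events.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events.astype(int)})


def simulate_survival(
    dist: SurvivalDistribution,
    n: int,
    censor_rate: float = 0.0,
    max_followup: float = 24.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Draw ``n`` subjects with inverse-CDF event times and right-censoring.

    Event times are S^{-1}(U) with U ~ Uniform(0,1). Administrative
    censoring truncates follow-up at ``max_followup`` months; on top of that
    an independent uniform censoring time C ~ Uniform(0, c) is applied, with
    the scale c solved so the expected overall censored fraction equals
    ``censor_rate`` (the realized fraction then matches to Monte Carlo
    noise, within about +/-5% at moderate n). Censoring independent of the
    event time keeps the Kaplan-Meier estimate consistent. Deterministic for
    a fixed seed.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    event_times = np.asarray(dist.inverse_survival(u), dtype=float)
    times = np.minimum(event_times, max_followup)
    events = event_times <= max_followup

    admin_frac = float(np.mean(~events))
    if censor_rate > admin_frac:
        x = np.minimum(event_times, max_followup)  # time at risk of censoring

        def expected_censored(c: float) -> float:
            # P(C < X) + P(admin censored and C >= maxf)
            p_random = np.mean(np.minimum(x / c, 1.0))
            p_admin_only = np.mean(~events) * max(0.0, 1.0 - max_followup / c)
            return float(p_random + p_admin_only)

        lo, hi = 1e-6, 1e6
        # expected_censored is decreasing in c: ~1 at lo, ~admin_frac at hi
        from scipy.optimize import brentq

        c_scale = brentq(lambda c: expected_censored(c) - censor_rate, lo, hi)
        censor_times = rng.uniform(0.0, c_scale, size=n)
        events = events & (event_times <= censor_times)
        times = np.minimum(times, censor_times)
    times = np.maximum(times, 1e-9)
    return SimulatedCohort(times=times, events=events, distribution=dist, seed=seed)


def kaplan_meier(
    cohort: SimulatedCohort, endpoint: str = "OS", arm: str = "cabozantinib"
) -> KMCurve:
    """Product-limit survival estimate at the distinct event times.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i) with d_i events
    among n_i at risk. The returned curve starts at (0, 1).
    """
    order = np.argsort(cohort.times, kind="stable")
    t = cohort.times[order]
    e = cohort.events[order]
    if not e.any():
        raise ValueError("cannot estimate a survival curve with no events")

    n_total = t.size
    times_out = [0.0]
    surv_out = [1.0]
    s = 1.0
    i = 0
    while i < n_total:
        ti = t[i]
        d = 0
        c = 0
        at_risk = n_total - i
        while i < n_total and t[i] == ti:
            if e[i]:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            times_out.append(float(ti))
            surv_out.append(s)
    return KMCurve(endpoint, arm, tuple(times_out), tuple(surv_out))


@dataclass(frozen=True)
class FixtureBundle:
    """Complete model inputs for one synthetic end-to-end run."""

    settings: ModelSettings
    distributions: dict[tuple[str, str], SurvivalDistribution]
    strategies: dict[str, dict[str, StrategyInputs]]  # country -> arm -> inputs
    thresholds: dict[str, list[Threshold]]
    gdp: dict[str, float] = field(default_factory=lambda: dict(GDP_PER_CAPITA))
    drug_price: dict[str, float] = field(default_factory=lambda: dict(DRUG_PRICE_MONTHLY))
    list_price: dict[str, float] = field(default_factory=lambda: dict(LIST_PRICE_MONTHLY))


def build_strategies(
    distributions: dict[tuple[str, str], SurvivalDistribution],
    cost_tables: dict[str, dict[str, dict[str, tuple[float, float]]]] | None = None,
    drug_price: dict[str, float] | None = None,
    utilities: tuple[float, float] = BASE_UTILITIES,
) -> dict[str, dict[str, StrategyInputs]]:
    """Assemble per-country, per-arm strategy inputs from survival curves and
    cost tables (defaults: the published tables)."""
    cost_tables = cost_tables if cost_tables is not None else COST_TABLES
    drug_price = drug_price if drug_price is not None else DRUG_PRICE_MONTHLY
    u_s, u_p = utilities
    out: dict[str, dict[str, StrategyInputs]] = {}
    for country, arms in cost_tables.items():
        out[country] = {}
        for arm, cats in arms.items():
            out[country][arm] = StrategyInputs(
                arm=arm,
                pfs_dist=distributions[("PFS", arm)],
                os_dist=distributions[("OS", arm)],
                u_stable=u_s,
                u_progressive=u_p,
                drug_cost_monthly=drug_price[country] if arm == "cabozantinib" else 0.0,
                category_costs=dict(cats),
            )
    return out


def celestial_fixture(
    shape: float = DEFAULT_FIXTURE_SHAPE,
    settings: ModelSettings = ModelSettings(),
) -> FixtureBundle:
    """CELESTIAL-like input bundle with median-matched Weibull curves.

    The four survival curves are Weibulls with the given shape whose scales
    are set so the medians equal the printed trial medians exactly; cost
    tables, utilities, drug prices and GDP thresholds are the published
    values.
    """
    dists = {
        key: SurvivalDistribution.weibull_from_median(median, shape)
        for key, median in TRIAL_MEDIANS.items()
    }
    return FixtureBundle(
        settings=settings,
        distributions=dists,
        strategies=build_strategies(dists),
        thresholds={c: thresholds_for(g) for c, g in GDP_PER_CAPITA.items()},
    )


def simulate_trial_km(
    n_per_arm: dict[str, int] | None = None,
    censor_rate: float = 0.2,
    max_followup: float = 24.0,
    shape: float = DEFAULT_FIXTURE_SHAPE,
    grid_months: int = 24,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], KMCurve], dict[tuple[str, str], SimulatedCohort]]:
    """Simulate both arms and endpoints and return monthly-grid KM curves.

    Arm sizes default to the trial's randomization (470 vs 237). Curves are
    sampled on a monthly grid to ``grid_months`` for fitting, mimicking a
    digitization of the published plots.
    """
    n_per_arm = n_per_arm or dict(TRIAL_ARM_SIZES)
    curves: dict[tuple[str, str], KMCurve] = {}
    cohorts: dict[tuple[str, str], SimulatedCohort] = {}
    grid = np.arange(0, grid_months + 1, dtype=float)
    for i, ((endpoint, arm), median) in enumerate(sorted(TRIAL_MEDIANS.items())):
        dist = SurvivalDistribution.weibull_from_median(median, shape)
        cohort = simulate_survival(
            dist,
            n=n_per_arm[arm],
            censor_rate=censor_rate,
            max_followup=max_followup,
            seed=seed * 1000 + i,
        )
        cohorts[(endpoint, arm)] = cohort
        curves[(endpoint, arm)] = kaplan_meier(cohort, endpoint, arm).on_grid(grid)
    return curves, cohorts


def write_km_csv(curves: dict[tuple[str, str], KMCurve], path) -> pd.DataFrame:
    df = pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
    df.to_csv(path, index=False)
    return df
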