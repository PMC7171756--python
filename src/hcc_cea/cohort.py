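"""Three-state partitioned-survival cohort model with discounted accrual.

The model tracks a cohort of second-line advanced-HCC patients through the
states stable -> progressive -> dead over a lifetime horizon of 84 monthly
cycles. State occupancy is read directly off the two fitted survival curves
(partitioned survival): the stable fraction is progression-free survival
S_PFS(t), the dead fraction is 1 - S_OS(t), and the progressive fraction is
the difference, clamped at zero should the extrapolated curves cross.

Accrual rules (per cycle, discounted at (1+r)^(-t/12) with t the cycle-start
time in months):

* life years and QALYs accrue over stable + progressive occupancy, weighted
  by the state utilities (0.76 stable / 0.68 progressive in the base case);
* drug and adverse-event costs accrue in stable cycles only (therapy until
  progression), with a possibly different first-cycle adverse-event cost;
* consultation, laboratory and imaging costs accrue in all alive cycles;
* optional scenario switches: a therapy cap (drug cost in the first N stable
  cycles only), a progression rebate (one monthly drug price credited for
  the cohort mass newly entering the progressive state), named utility
  variants, and a per-cycle progressive-utility decrement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survival import SurvivalDistribution

logger = logging.getLogger(__name__)

#: cost categories accruing over all alive (stable + progressive) cycles
ALIVE_CATEGORIES = ("consultation", "laboratory", "imaging")
#: cost categories accruing over stable cycles only
STABLE_CATEGORIES = ("adverse_events",)

#: named utility variant -> arm -> (stable, progressive) utility
UTILITY_VARIANTS: dict[str, dict[str, tuple[float, float]]] = {
    "base": {"cabozantinib": (0.760, 0.680), "bsc": (0.760, 0.680)},
    # stable utility under therapy raised per the trial's quality-of-life gain
    "qol_gain": {"cabozantinib": (0.852, 0.680), "bsc": (0.760, 0.680)},
    # utilities observed for cabozantinib as first-line therapy in advanced RCC
    "rcc_first_line": {"cabozantinib": (0.817, 0.777), "bsc": (0.817, 0.777)},
    # stable utilities reduced by incidence-weighted grade 3/4 AE disutilities
    "ae_disutility": {"cabozantinib": (0.728, 0.680), "bsc": (0.751, 0.680)},
}


@dataclass(frozen=True)
class ModelSettings:
    """Global cycle/horizon/discounting settings (84 monthly cycles, 3%/yr)."""

    horizon_cycles: int = 84
    cycle_length_months: float = 1.0
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if self.cycle_length_months <= 0:
            raise ValueError("cycle_length_months must be > 0")
        if not 0.0 <= self.annual_discount_rate <= 0.10:
            raise ValueError("annual_discount_rate must be in [0, 0.10]")

    def discount_factors(self) -> np.ndarray:
        """Per-cycle discount factors at cycle-start times."""
        t = np.arange(self.horizon_cycles) * self.cycle_length_months
        d = (1.0 + self.annual_discount_rate) ** (-t / 12.0)
        if self.half_cycle_correction:
            # evaluate discounting at mid-cycle instead
            d = (1.0 + self.annual_discount_rate) ** (
                -(t + 0.5 * self.cycle_length_months) / 12.0
            )
        return d


@dataclass(frozen=True)
class StrategyInputs:
    """Per-arm survival, utility and monthly cost inputs.

    ``category_costs`` maps each non-drug category to a
    ``(first_cycle, subsequent)`` pair of monthly $ amounts, following the
    published convention of a deviating second-and-following-months cost.
    """

    arm: str
    pfs_dist: SurvivalDistribution
    os_dist: SurvivalDistribution
    u_stable: float = 0.76
    u_progressive: float = 0.68
    drug_cost_monthly: float = 0.0
    category_costs: dict[str, tuple[float, float]] = field(default_factory=dict)
    one_time_costs: float = 0.0

    def __post_init__(self) -> None:
        for u, name in ((self.u_stable, "u_stable"), (self.u_progressive, "u_progressive")):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {u}")
        if self.drug_cost_monthly < 0 or self.one_time_costs < 0:
            raise ValueError("costs must be >= 0")
        for cat, pair in self.category_costs.items():
            first, sub = pair
            if first < 0 or sub < 0:
                raise ValueError(f"negative cost in category {cat!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Scenario switches layered on top of a strategy's base inputs."""

    therapy_cap_cycles: int | None = None
    progression_rebate: bool = False
    utility_variant: str | None = None
    progressive_utility_decrement_per_cycle: float = 0.0

    def __post_init__(self) -> None:
        if self.therapy_cap_cycles is not None and self.therapy_cap_cycles < 0:
            raise ValueError("therapy_cap_cycles must be >= 0")
        if self.progressive_utility_decrement_per_cycle < 0:
            raise ValueError("utility decrement must be >= 0")
        if (
            self.utility_variant is not None
            and self.utility_variant not in UTILITY_VARIANTS
        ):
            raise ValueError(
                f"unknown utility variant {self.utility_variant!r}; "
                f"known: {sorted(UTILITY_VARIANTS)}"
            )


BASE_SCENARIO = ScenarioSpec()


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted accumulators for one strategy."""

    arm: str
    stable: np.ndarray
    progressive: np.ndarray
    dead: np.ndarray
    discount: np.ndarray
    ly_cycle: np.ndarray
    qaly_cycle: np.ndarray
    cost_by_category: dict[str, np.ndarray]

    @property
    def total_ly(self) -> float:
        return float(self.ly_cycle.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_cycle.sum())

    @property
    def cost_totals(self) -> dict[str, float]:
        return {k: float(v.sum()) for k, v in self.cost_by_category.items()}

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_totals.values()))

    def state_ly(self, state: str) -> float:
        """Discounted life years accrued in one state ('stable'/'progressive')."""
        occ = getattr(self, state)
        dt = self.ly_cycle / np.maximum(self.stable + self.progressive, 1e-300)
        return float(np.sum(occ * dt))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": np.arange(len(self.stable)),
                "stable": self.stable,
                "progressive": self.progressive,
                "dead": self.dead,
                "discount": self.discount,
                "ly": self.ly_cycle,
                "qaly": self.qaly_cycle,
            }
        )
        for cat, v in self.cost_by_category.items():
            df[f"cost_{cat}"] = v
        return df


def state_occupancy(
    pfs: SurvivalDistribution,
    os_dist: SurvivalDistribution,
    cycle: int,
    cycle_length: float = 1.0,
) -> tuple[float, float, float]:
    """Occupancy (stable, progressive, dead) at the start of ``cycle``.

    stable = S_PFS(t), progressive = max(0, S_OS(t) - S_PFS(t)),
    dead = remainder; a crossing of the extrapolated curves (S_PFS > S_OS)
    clamps progressive at 0 and assigns the excess to dead.
    """
    t = cycle * cycle_length
    s_pfs = float(pfs.survival(t))
    s_os = float(os_dist.survival(t))
    if s_pfs > s_os + 1e-12:
        logger.warning(
            "PFS survival %.4f exceeds OS survival %.4f at t=%.2f months; "
            "clamping progressive occupancy at 0",
            s_pfs,
            s_os,
            t,
        )
    prog = max(0.0, s_os - s_pfs)
    return s_pfs, prog, 1.0 - s_pfs - prog


def apply_scenario(base: StrategyInputs, scenario: ScenarioSpec) -> StrategyInputs:
    """Return the strategy inputs with any named utility variant applied.

    Cap, rebate and utility-decrement switches act at run time inside
    :func:`run_cohort`; only input substitutions happen here, so an empty
    scenario returns the inputs unchanged.
    """
    if scenario.utility_variant is None:
        return base
    variant = UTILITY_VARIANTS[scenario.utility_variant]
    if base.arm not in variant:
        raise ValueError(
            f"utility variant {scenario.utility_variant!r} lacks arm {base.arm!r}"
        )
    u_s, u_p = variant[base.arm]
    return replace(base, u_stable=u_s, u_progressive=u_p)


def run_cohort(
    strategy: StrategyInputs,
    settings: ModelSettings = ModelSettings(),
    scenario: ScenarioSpec = BASE_SCENARIO,
) -> CohortTrace:
    """Run the discounted cohort trace for one strategy.

    Returns per-cycle occupancy plus discounted life-year, QALY and
    per-category cost accumulators. See the module docstring for the accrual
    rules; cost categories are 'drug', 'adverse_events', 'consultation',
    'laboratory', 'imaging', plus 'one_time' and a negative 'drug_rebate'
    when those features are active.
    """
    if (
        scenario.therapy_cap_cycles is not None
        and scenario.therapy_cap_cycles > settings.horizon_cycles
    ):
        raise ValueError("therapy_cap_cycles exceeds the model horizon")

    strategy = apply_scenario(strategy, scenario)
    n = settings.horizon_cycles
    delta = settings.cycle_length_months
    t = np.arange(n) * delta

    s_pfs = np.asarray(strategy.pfs_dist.survival(t), dtype=float)
    s_os = np.asarray(strategy.os_dist.survival(t), dtype=float)
    if np.any(s_pfs > s_os + 1e-12):
        k = int(np.argmax(s_pfs > s_os + 1e-12))
        logger.warning(
            "PFS curve crosses above OS curve from cycle %d (arm %s); "
            "progressive occupancy clamped at 0",
            k,
            strategy.arm,
        )
    stable = s_pfs
    progressive = np.maximum(0.0, s_os - s_pfs)
    dead = 1.0 - stable - progressive
    alive = stable + progressive

    d = settings.discount_factors()
    years_per_cycle = delta / 12.0

    u_prog = np.clip(
        strategy.u_progressive
        - scenario.progressive_utility_decrement_per_cycle * np.arange(n),
        0.0,
        1.0,
    )
    ly_cycle = alive * years_per_cycle * d
    qaly_cycle = (stable * strategy.u_stable + progressive * u_prog) * years_per_cycle * d

    costs: dict[str, np.ndarray] = {}

    drug_mask = np.ones(n)
    if scenario.therapy_cap_cycles is not None:
        drug_mask[scenario.therapy_cap_cycles :] = 0.0
    costs["drug"] = strategy.drug_cost_monthly * stable * d * drug_mask

    for cat, (first, sub) in strategy.category_costs.items():
        monthly = np.full(n, sub)
        monthly[0] = first
        occ = stable if cat in STABLE_CATEGORIES else alive
        costs[cat] = monthly * occ * d

    if strategy.one_time_costs:
        one_time = np.zeros(n)
        one_time[0] = strategy.one_time_costs * d[0]
        costs["one_time"] = one_time

    if scenario.progression_rebate and strategy.drug_cost_monthly > 0:
        # expected cohort mass newly entering progressive each cycle:
        # stable outflow minus the share of that cycle's deaths attributed to
        # stable (split proportionally to start-of-cycle occupancy)
        new_prog = np.zeros(n)
        deaths = np.diff(dead)
        stable_share = np.where(alive[:-1] > 0, stable[:-1] / alive[:-1], 0.0)
        outflow = stable[:-1] - stable[1:]
        new_prog[1:] = np.maximum(0.0, outflow - deaths * stable_share)
        costs["drug_rebate"] = -strategy.drug_cost_monthly * new_prog * d

    return CohortTrace(
        arm=strategy.arm,
        stable=stable,
        progressive=progressive,
        dead=dead,
        discount=d,
        ly_cycle=ly_cycle,
        qaly_cycle=qaly_cycle,
        cost_by_category=costs,
    )


def qaly_from_ly(ly_state: float, utility: float) -> float:
    """Quality-adjust discounted life years spent in one state."""
    if ly_state < 0:
        raise ValueError("life years must be >= 0")
    if not 0.0 <= utility <= 1.0:
        raise ValueError(f"utility must be in [0, 1], got {utility}")
    return ly_state * utility
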