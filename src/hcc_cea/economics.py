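"""ICERs, willingness-to-pay thresholds, AE screening and price analysis.

Incremental cost-effectiveness ratios (ICER = incremental cost / incremental
effect, cabozantinib minus best supportive care) are judged against
willingness-to-pay thresholds set at multiples (3/6/9) of GDP per capita,
following the WHO GDP-multiple convention. Adverse events enter the cost
model only when their all-grade incidence differs significantly between
arms (Pearson chi-squared, p < 0.05, no continuity correction), and their
per-cycle cost is the incidence-weighted sum of grade-specific treatment
costs, with one-time treatments (defined-duration drugs, hospitalizations)
charged to the first stable cycle only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTrace

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class Threshold:
    """A GDP-multiple willingness-to-pay threshold in $ per LY (QALY)."""

    gdp_per_capita: float
    factor: int

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise ValueError("gdp_per_capita must be > 0")
        if self.factor < 0:
            raise ValueError("factor must be >= 0")

    @property
    def value(self) -> float:
        return self.gdp_per_capita * self.factor


def threshold_value(gdp: float, factor: int) -> float:
    """Willingness-to-pay threshold = factor x GDP per capita, exactly."""
    return Threshold(gdp, factor).value


def thresholds_for(gdp: float, factors=(3, 6, 9)) -> list[Threshold]:
    return [Threshold(gdp, f) for f in factors]


def convert_currency(amount: float, ppp_rate: float) -> float:
    """Convert a foreign amount to $ at a purchasing-power parity of
    ``ppp_rate`` foreign units per $ (e.g. 0.741 EUR/$, 0.689 GBP/$)."""
    if ppp_rate <= 0:
        raise ValueError("ppp_rate must be > 0")
    return amount / ppp_rate


@dataclass(frozen=True)
class ArmTotals:
    """Total discounted cost, life years and QALYs for one strategy arm."""

    arm: str
    cost: float
    ly: float
    qaly: float
    cost_by_category: dict[str, float] | None = None

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "ArmTotals":
        return cls(
            arm=trace.arm,
            cost=trace.total_cost,
            ly=trace.total_ly,
            qaly=trace.total_qaly,
            cost_by_category=trace.cost_totals,
        )


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of cabozantinib against best supportive care.

    ``icer_per_ly``/``icer_per_qaly`` are NaN when the incremental effect is
    not positive; the corresponding dominance label then records whether the
    intervention is dominated (costlier, no effect gain) or dominant
    (cheaper with an effect gain).
    """

    country: str
    intervention: ArmTotals
    comparator: ArmTotals

    @property
    def d_cost(self) -> float:
        return self.intervention.cost - self.comparator.cost

    @property
    def d_ly(self) -> float:
        return self.intervention.ly - self.comparator.ly

    @property
    def d_qaly(self) -> float:
        return self.intervention.qaly - self.comparator.qaly

    def _icer(self, d_effect: float) -> float:
        if d_effect > 0:
            return self.d_cost / d_effect
        return math.nan

    def _dominance(self, d_effect: float) -> str | None:
        if d_effect > 0 and self.d_cost <= 0:
            return DOMINANT
        if d_effect <= 0 and self.d_cost > 0:
            return DOMINATED
        return None

    @property
    def icer_per_ly(self) -> float:
        return self._icer(self.d_ly)

    @property
    def icer_per_qaly(self) -> float:
        return self._icer(self.d_qaly)

    @property
    def dominance_ly(self) -> str | None:
        return self._dominance(self.d_ly)

    @property
    def dominance_qaly(self) -> str | None:
        return self._dominance(self.d_qaly)

    def cost_effective(self, threshold: Threshold, effect: str = "qaly") -> bool:
        """Net-monetary-benefit verdict at the given threshold."""
        d_eff = self.d_qaly if effect == "qaly" else self.d_ly
        return threshold.value * d_eff - self.d_cost > 0


def compute_icer(
    intervention: ArmTotals, comparator: ArmTotals, country: str = ""
) -> CEResult:
    """Incremental cost-effectiveness of ``intervention`` vs ``comparator``."""
    return CEResult(country=country, intervention=intervention, comparator=comparator)


# ---------------------------------------------------------------------------
# Adverse-event screening and costing


@dataclass(frozen=True)
class AEItem:
    """One adverse-event cost component, already incidence-weighted.

    ``monthly_cost`` is the incidence-weighted $ per cycle; recurring items
    (permanent therapy, e.g. antihypertensives) accrue every stable cycle,
    one-time items (defined-duration treatment or a single hospitalization)
    accrue in cycle 1 of the stable state only.
    """

    name: str
    monthly_cost: float
    recurring: bool

    def __post_init__(self) -> None:
        if self.monthly_cost < 0:
            raise ValueError("monthly_cost must be >= 0")


@dataclass(frozen=True)
class AEScreenResult:
    include: bool
    statistic: float
    p_value: float


def ae_screen(
    affected_a: int,
    total_a: int,
    affected_b: int,
    total_b: int,
    alpha: float = 0.05,
) -> AEScreenResult:
    """Screen one adverse event by a 2x2 Pearson chi-squared test.

    The AE is retained in the cost model only when the all-grade incidence
    differs significantly (p < alpha) between arms; no continuity correction
    is applied. A table with a zero margin carries no information and is
    excluded with a warning.
    """
    for v in (affected_a, total_a, affected_b, total_b):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    if affected_a > total_a or affected_b > total_b:
        raise ValueError("affected cannot exceed total")
    table = [
        [affected_a, total_a - affected_a],
        [affected_b, total_b - affected_b],
    ]
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in row_sums or 0 in col_sums:
        warnings.warn("zero-margin 2x2 table: AE excluded from screening", RuntimeWarning)
        return AEScreenResult(include=False, statistic=math.nan, p_value=math.nan)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    # alpha >= 1 is the no-screening boundary: every valid table is retained
    include = bool(p < alpha) or alpha >= 1.0
    return AEScreenResult(include=include, statistic=float(chi2), p_value=float(p))


def weighted_ae_cost(items: list[AEItem]) -> tuple[float, float]:
    """Total AE cost per cycle as (first cycle $, subsequent cycles $).

    Recurring items contribute to both; one-time items to the first stable
    cycle only.
    """
    first = sum(i.monthly_cost for i in items)
    subsequent = sum(i.monthly_cost for i in items if i.recurring)
    return float(first), float(subsequent)


def read_ae_csv(path) -> pd.DataFrame:
    """Read the AE screening/costing table
    (ae_name,arm,affected,total,grade,item_cost,recurring)."""
    df = pd.read_csv(path)
    required = {"ae_name", "arm", "affected", "total", "grade", "item_cost", "recurring"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"AE CSV missing columns: {sorted(missing)}")
    return df


def read_cost_csv(path) -> dict[str, dict[str, dict[str, tuple[float, float]]]]:
    """Read per-country cost tables
    (country,arm,category,item,cost_first,cost_subsequent), summed per
    (country, arm, category)."""
    df = pd.read_csv(path)
    required = {"country", "arm", "category", "cost_first", "cost_subsequent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cost CSV missing columns: {sorted(missing)}")
    out: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    grouped = df.groupby(["country", "arm", "category"])[["cost_first", "cost_subsequent"]].sum()
    for (country, arm, cat), row in grouped.iterrows():
        out.setdefault(str(country), {}).setdefault(str(arm), {})[str(cat)] = (
            float(row["cost_first"]),
            float(row["cost_subsequent"]),
        )
    return out


# ---------------------------------------------------------------------------
# Break-even price analysis


@dataclass(frozen=True)
class BreakEvenResult:
    """Monthly drug price at which the ICER meets a threshold."""

    price: float | None
    status: str  # "break_even" | "cost_effective_at_list_price" | "never"


def breakeven_drug_price(
    icer_at_price,
    threshold: float,
    price_cap: float,
    tol: float = 1.0,
) -> BreakEvenResult:
    """Find the monthly drug price where the ICER equals ``threshold``.

    ``icer_at_price`` maps a monthly drug price to the resulting ICER, which
    must be increasing in price. The root is bracketed on [0, price_cap] and
    solved by bisection to +/- ``tol`` $; if even the list price is
    cost-effective the status says so, and if no price >= 0 reaches the
    threshold the result is "never".
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if price_cap <= 0:
        raise ValueError("price_cap must be > 0")
    f_cap = icer_at_price(price_cap) - threshold
    if f_cap <= 0:
        return BreakEvenResult(price=price_cap, status="cost_effective_at_list_price")
    f_zero = icer_at_price(0.0) - threshold
    if f_zero >= 0:
        return BreakEvenResult(price=None, status="never")
    price = optimize.brentq(
        lambda p: icer_at_price(p) - threshold, 0.0, price_cap, xtol=tol
    )
    return BreakEvenResult(price=float(price), status="break_even")
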