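"""Parametric survival curves and their fit to digitized Kaplan-Meier points.

The cohort model extrapolates progression-free and overall survival beyond
the trial follow-up by fitting parametric families to (time, survival)
coordinates read off published Kaplan-Meier plots. Fitting minimizes the sum
of squared residuals between the parametric survival function and the KM
points; model selection ranks families by SSR with least-squares AIC/BIC as
tie-breakers and a long-run-hazard plausibility flag for palliative overall
survival, where a hazard that vanishes at long times is clinically
implausible.

Five families are supported, in their conventional survival-analysis
parameterizations:

==============  =======================  ==========================
family          parameters               S(t)
==============  =======================  ==========================
exponential     rate lam > 0             exp(-lam*t)
weibull         scale lam > 0,           exp(-(t/lam)**gamma)
                shape gamma > 0
gompertz        shape a > 0, rate b > 0  exp((b/a)*(1 - exp(a*t)))
loglogistic     scale alpha > 0,         1 / (1 + (t/alpha)**beta)
                shape beta > 0
lognormal       log-mean mu,             1 - Phi((ln t - mu)/sigma)
                log-sd sigma > 0
==============  =======================  ==========================

Time is measured in months throughout.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

FAMILIES: tuple[str, ...] = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
)

#: parameter names per family, in storage order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
}

#: families whose hazard eventually decreases (toward 0 for lognormal),
#: implausible as a long-run extrapolation of palliative overall survival
_VANISHING_HAZARD_FAMILIES = frozenset({"loglogistic", "lognormal"})

LN2 = math.log(2.0)


class FittingError(RuntimeError):
    """Raised when least-squares fitting fails to converge for a family."""


@dataclass(frozen=True)
class SurvivalDistribution:
    """A parametric survival distribution S(t) on t >= 0 (months).

    Instances are immutable and hashable; construct through the family
    classmethods (:meth:`weibull`, :meth:`exponential`, ...) or directly with
    a valid ``(family, params)`` pair.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if len(p) != len(PARAM_NAMES[self.family]):
            raise ValueError(
                f"{self.family} expects {len(PARAM_NAMES[self.family])} "
                f"parameters, got {len(p)}"
            )
        if not all(math.isfinite(v) for v in p):
            raise ValueError(f"non-finite parameters {p} for {self.family}")
        f = self.family
        if f == "exponential" and p[0] <= 0:
            raise ValueError("exponential rate must be > 0")
        elif f == "weibull" and (p[0] <= 0 or p[1] <= 0):
            raise ValueError("weibull scale and shape must be > 0")
        elif f == "gompertz" and (p[0] <= 0 or p[1] <= 0):
            # shape a <= 0 gives an improper distribution (S does not reach 0)
            raise ValueError("gompertz shape and rate must be > 0")
        elif f == "loglogistic" and (p[0] <= 0 or p[1] <= 0):
            raise ValueError("loglogistic scale and shape must be > 0")
        elif f == "lognormal" and p[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")

    # -- constructors -------------------------------------------------------

    @classmethod
    def exponential(cls, rate: float) -> "SurvivalDistribution":
        return cls("exponential", (rate,))

    @classmethod
    def weibull(cls, scale: float, shape: float) -> "SurvivalDistribution":
        return cls("weibull", (scale, shape))

    @classmethod
    def gompertz(cls, shape: float, rate: float) -> "SurvivalDistribution":
        return cls("gompertz", (shape, rate))

    @classmethod
    def loglogistic(cls, scale: float, shape: float) -> "SurvivalDistribution":
        return cls("loglogistic", (scale, shape))

    @classmethod
    def lognormal(cls, mu: float, sigma: float) -> "SurvivalDistribution":
        return cls("lognormal", (mu, sigma))

    @classmethod
    def weibull_from_median(
        cls, median: float, shape: float
    ) -> "SurvivalDistribution":
        """Weibull with the given shape whose median equals ``median``."""
        if median <= 0:
            raise ValueError("median must be > 0")
        return cls.weibull(median / LN2 ** (1.0 / shape), shape)

    # -- functions ----------------------------------------------------------

    def survival(self, t):
        """S(t) for scalar or array t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        f, p = self.family, self.params
        with np.errstate(divide="ignore", over="ignore"):
            if f == "exponential":
                s = np.exp(-p[0] * t)
            elif f == "weibull":
                s = np.exp(-((t / p[0]) ** p[1]))
            elif f == "gompertz":
                a, b = p
                s = np.exp((b / a) * (1.0 - np.exp(a * t)))
            elif f == "loglogistic":
                s = 1.0 / (1.0 + (t / p[0]) ** p[1])
            else:  # lognormal; log(0) -> -inf -> sf = 1, the correct limit
                s = stats.norm.sf((np.log(t) - p[0]) / p[1])
        return s if s.ndim else float(s)

    def hazard(self, t):
        """Instantaneous hazard h(t), t > 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("t must be > 0 for the hazard")
        f, p = self.family, self.params
        if f == "exponential":
            h = np.full_like(t, p[0])
        elif f == "weibull":
            lam, g = p
            h = (g / lam) * (t / lam) ** (g - 1.0)
        elif f == "gompertz":
            a, b = p
            h = b * np.exp(a * t)
        elif f == "loglogistic":
            al, be = p
            x = (t / al) ** be
            h = (be / t) * x / (1.0 + x)
        else:
            z = (np.log(t) - p[0]) / p[1]
            h = stats.norm.pdf(z) / (p[1] * t * stats.norm.sf(z))
        return h if h.ndim else float(h)

    def median(self) -> float:
        """Time at which S(t) = 1/2."""
        f, p = self.family, self.params
        if f == "exponential":
            return LN2 / p[0]
        if f == "weibull":
            return p[0] * LN2 ** (1.0 / p[1])
        if f == "gompertz":
            a, b = p
            return math.log1p(a * LN2 / b) / a
        if f == "loglogistic":
            return p[0]
        return math.exp(p[0])

    def inverse_survival(self, u):
        """t such that S(t) = u, for u in (0, 1]; the simulation quantile."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u > 1)):
            raise ValueError("u must be in (0, 1]")
        f, p = self.family, self.params
        if f == "exponential":
            t = -np.log(u) / p[0]
        elif f == "weibull":
            t = p[0] * (-np.log(u)) ** (1.0 / p[1])
        elif f == "gompertz":
            a, b = p
            t = np.log1p(-(a / b) * np.log(u)) / a
        elif f == "loglogistic":
            t = p[0] * ((1.0 - u) / u) ** (1.0 / p[1])
        else:
            t = np.exp(p[0] + p[1] * stats.norm.isf(u))
        return t if t.ndim else float(t)

    def params_as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.family], self.params))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v:.6g}" for k, v in self.params_as_dict().items())
        return f"{self.family}({inner})"


def survival_at(dist: SurvivalDistribution, t) -> float:
    """Survival probability S(t) of ``dist`` at time ``t`` months."""
    return dist.survival(t)


def cycle_transition_prob(
    dist: SurvivalDistribution, cycle_index: int, cycle_length: float
) -> float:
    """Conditional per-cycle event probability 1 - S(t+D)/S(t), t = k*D.

    This is the discrete transition probability implied by the fitted curve
    for a cohort cycle of length ``cycle_length`` months starting at cycle
    ``cycle_index``. When S(t) has underflowed to zero the probability is 1.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be > 0")
    t = cycle_index * cycle_length
    s0 = dist.survival(t)
    if s0 <= 0.0:
        logger.info("S(t)=0 at t=%.3f for %s; transition probability set to 1", t, dist)
        return 1.0
    p = 1.0 - dist.survival(t + cycle_length) / s0
    return float(min(1.0, max(0.0, p)))


# ---------------------------------------------------------------------------
# Kaplan-Meier curve container


@dataclass(frozen=True)
class KMCurve:
    """Ordered (time, survival) coordinates for one arm and endpoint.

    ``endpoint`` is ``"PFS"`` or ``"OS"``; ``arm`` is ``"cabozantinib"`` or
    ``"bsc"``. Times are months, strictly increasing; survival probabilities
    are non-increasing within [0, 1].
    """

    endpoint: str
    arm: str
    times: tuple[float, ...]
    surv: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError(f"endpoint must be PFS or OS, got {self.endpoint!r}")
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        if t.size != s.size or t.size == 0:
            raise ValueError("times and surv must be non-empty and equal length")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        object.__setattr__(self, "times", tuple(float(v) for v in t))
        object.__setattr__(self, "surv", tuple(float(v) for v in s))

    def __len__(self) -> int:
        return len(self.times)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.surv)

    def on_grid(self, grid) -> "KMCurve":
        """Sample the right-continuous step function on a new time grid."""
        grid = np.asarray(grid, dtype=float)
        t, s = self.arrays()
        idx = np.searchsorted(t, grid, side="right") - 1
        vals = np.where(idx >= 0, s[np.clip(idx, 0, None)], 1.0)
        return KMCurve(self.endpoint, self.arm, tuple(grid), tuple(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "endpoint": self.endpoint,
                "arm": self.arm,
                "time_months": self.times,
                "survival": self.surv,
            }
        )


def read_km_csv(path) -> dict[tuple[str, str], KMCurve]:
    """Read KM point curves from CSV columns endpoint,arm,time_months,survival."""
    df = pd.read_csv(path)
    required = {"endpoint", "arm", "time_months", "survival"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"KM CSV missing columns: {sorted(missing)}")
    curves: dict[tuple[str, str], KMCurve] = {}
    for (endpoint, arm), grp in df.groupby(["endpoint", "arm"], sort=False):
        grp = grp.sort_values("time_months")
        curves[(str(endpoint), str(arm))] = KMCurve(
            str(endpoint),
            str(arm),
            tuple(grp["time_months"].to_numpy(float)),
            tuple(grp["survival"].to_numpy(float)),
        )
    return curves


# ---------------------------------------------------------------------------
# Least-squares fitting


@dataclass(frozen=True)
class ParametricFit:
    """A fitted family with its goodness-of-fit summary."""

    distribution: SurvivalDistribution
    ssr: float
    aic: float
    bic: float
    n_points: int
    k_params: int
    degenerate: bool = field(default=False)

    @property
    def family(self) -> str:
        return self.distribution.family


def information_criteria(ssr: float, n: int, k: int) -> tuple[float, float]:
    """Least-squares (Gaussian) AIC and BIC from an SSR on n points, k params.

    aic = n*ln(ssr/n) + 2k and bic = n*ln(ssr/n) + k*ln(n). A perfect fit
    (ssr = 0) returns -inf sentinels with a warning.
    """
    if ssr < 0:
        raise ValueError("ssr must be >= 0")
    if n <= k:
        raise ValueError("need n > k points")
    if ssr == 0.0:
        warnings.warn("ssr=0: information criteria are -inf", RuntimeWarning)
        return (-math.inf, -math.inf)
    base = n * math.log(ssr / n)
    return (base + 2.0 * k, base + k * math.log(n))


def _guess_median(t: np.ndarray, s: np.ndarray) -> float:
    """Crude median of the curve, interpolated or tail-extrapolated."""
    below = np.nonzero(s <= 0.5)[0]
    if below.size:
        i = below[0]
        if i == 0 or s[i] == 0.5:
            return max(t[i], 1e-6)
        # linear interpolation between bracketing points
        t0, t1, s0, s1 = t[i - 1], t[i], s[i - 1], s[i]
        return t0 + (s0 - 0.5) * (t1 - t0) / (s0 - s1)
    s_last = min(s[-1], 1.0 - 1e-9)
    if s_last >= 1.0 - 1e-9 or t[-1] <= 0:
        return max(float(np.mean(t)), 1e-6)
    # exponential tail extrapolation
    return float(t[-1] * LN2 / -math.log(s_last))


def _starts_for(family: str, med: float) -> list[np.ndarray]:
    """Multi-start initial parameter vectors on the optimizer scale.

    Positive parameters are log-transformed (all but the lognormal log-mean),
    so every start/step stays inside the family's domain.
    """
    shapes = (0.6, 1.0, 1.5, 2.0, 3.0)
    starts: list[np.ndarray] = []
    if family == "exponential":
        for f in (0.25, 0.5, 1.0, 2.0, 4.0):
            starts.append(np.log([f * LN2 / med]))
    elif family == "weibull":
        for g in shapes:
            starts.append(np.log([med / LN2 ** (1.0 / g), g]))
    elif family == "gompertz":
        for a in (0.01, 0.05, 0.1, 0.25, 0.5):
            b = a * LN2 / math.expm1(a * med)
            starts.append(np.log([a, max(b, 1e-8)]))
    elif family == "loglogistic":
        for be in shapes:
            starts.append(np.log([med, be]))
    else:  # lognormal: mu free, sigma log-transformed
        for sig in (0.3, 0.6, 1.0, 1.5, 2.0):
            starts.append(np.array([math.log(med), math.log(sig)]))
    return starts


def _decode(family: str, theta: np.ndarray) -> SurvivalDistribution:
    if family == "lognormal":
        return SurvivalDistribution.lognormal(theta[0], math.exp(theta[1]))
    if family == "gompertz":
        a, b = np.exp(theta)
        return SurvivalDistribution.gompertz(a, b)
    p = tuple(np.exp(theta))
    return SurvivalDistribution(family, p)


def fit_parametric(curve: KMCurve, family: str) -> ParametricFit:
    """Fit one parametric family to a KM curve by least squares.

    Residuals are s_i - S(t_i) over the curve's points. Optimization runs
    multi-start local least squares on log-transformed parameters; the best
    of the converged starts is returned. A flat curve (all survival values
    equal) cannot identify a distribution and is reported at the exponential
    rate -> 0 boundary with a warning.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t, s = curve.arrays()
    k = len(PARAM_NAMES[family])
    if len(curve) < k + 1:
        raise ValueError(f"need at least {k + 1} points to fit {family}")

    if np.ptp(s) == 0.0:
        warnings.warn(
            "degenerate KM curve (all survival values equal); "
            "reporting exponential boundary fit",
            RuntimeWarning,
        )
        dist = SurvivalDistribution.exponential(1e-12)
        ssr = float(np.sum((s - dist.survival(t)) ** 2))
        aic, bic = information_criteria(max(ssr, 1e-300), len(curve), 1)
        return ParametricFit(dist, ssr, aic, bic, len(curve), 1, degenerate=True)

    med = _guess_median(t, s)

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            dist = _decode(family, theta)
        except ValueError:
            return np.full_like(s, 1e6)
        r = s - dist.survival(t)
        return np.where(np.isfinite(r), r, 1e6)

    best: tuple[float, np.ndarray] | None = None
    for theta0 in _starts_for(family, med):
        try:
            res = optimize.least_squares(residuals, theta0, method="trf", xtol=1e-12)
        except Exception:  # singular jacobian etc.; try the next start
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res.x)
    if best is None:
        raise FittingError(f"least-squares fit did not converge for {family}")

    ssr, theta = best
    dist = _decode(family, theta)
    aic, bic = information_criteria(max(ssr, 1e-300), len(curve), k)
    return ParametricFit(dist, ssr, aic, bic, len(curve), k)


def fit_all_families(curve: KMCurve) -> list[ParametricFit]:
    """Fit every supported family to the curve."""
    return [fit_parametric(curve, fam) for fam in FAMILIES]


# ---------------------------------------------------------------------------
# Model selection


@dataclass(frozen=True)
class SelectionResult:
    """Best family plus the full ranking and any hazard-shape caveat."""

    best: ParametricFit
    ranking: pd.DataFrame
    hazard_warning: str | None = None

    @property
    def family(self) -> str:
        return self.best.family


def select_best(
    fits: list[ParametricFit], endpoint: str | None = None
) -> SelectionResult:
    """Rank fits by SSR, then AIC, then BIC, then fixed family order.

    For an overall-survival endpoint in a palliative setting the long-run
    hazard should not vanish; if the winner is a family whose hazard
    eventually decreases toward zero (log-logistic, lognormal) a plausibility
    warning is attached (and emitted) rather than overriding the ranking.
    """
    if not fits:
        raise ValueError("select_best needs at least one fit")
    order = {fam: i for i, fam in enumerate(FAMILIES)}
    ranked = sorted(
        fits, key=lambda f: (f.ssr, f.aic, f.bic, order.get(f.family, 99))
    )
    table = pd.DataFrame(
        {
            "family": [f.family for f in ranked],
            "ssr": [f.ssr for f in ranked],
            "aic": [f.aic for f in ranked],
            "bic": [f.bic for f in ranked],
            "params": [
                ";".join(f"{k}={v:.8g}" for k, v in f.distribution.params_as_dict().items())
                for f in ranked
            ],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
    best = ranked[0]
    warning = None
    if (
        endpoint is not None
        and endpoint.upper() == "OS"
        and best.family in _VANISHING_HAZARD_FAMILIES
    ):
        warning = (
            f"{best.family} selected for an OS endpoint: its hazard "
            "eventually decreases (toward 0), implausible for long-run "
            "palliative overall survival"
        )
        warnings.warn(warning, RuntimeWarning)
    return SelectionResult(best=best, ranking=table, hazard_warning=warning)


def write_fit_report(
    fits_by_curve: dict[tuple[str, str], list[ParametricFit]], path
) -> pd.DataFrame:
    """Serialize one row per (curve, family) with ssr/aic/bic and parameters."""
    rows = []
    for (endpoint, arm), fits in fits_by_curve.items():
        for f in fits:
            rows.append(
                {
                    "endpoint": endpoint,
                    "arm": arm,
                    "family": f.family,
                    "ssr": f.ssr,
                    "aic": f.aic,
                    "bic": f.bic,
                    "n_points": f.n_points,
                    "k_params": f.k_params,
                    "params": ";".join(
                        f"{k}={v:.10g}"
                        for k, v in f.distribution.params_as_dict().items()
                    ),
                }
            )
    report = pd.DataFrame(rows)
    report.to_csv(path, index=False)
    return report
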