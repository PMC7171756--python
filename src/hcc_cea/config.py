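"""YAML run configuration shared by the CLI commands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import ModelSettings, ScenarioSpec

COUNTRIES = ("germany", "us")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Paths, model settings and analysis switches for one pipeline run."""

    km_csv: Path | None = None
    cost_csv: Path | None = None
    country: str = "both"
    out_dir: Path = Path("results")
    seed: int = 0
    settings: ModelSettings = field(default_factory=ModelSettings)
    scenarios: list[tuple[str, ScenarioSpec]] = field(
        default_factory=lambda: list(DEFAULT_SCENARIOS)
    )
    psa_iterations: int = 10_000
    psa_cost_se_fraction: float = 0.20
    psa_utility_se: float = 0.05

    def countries(self) -> tuple[str, ...]:
        if self.country == "both":
            return COUNTRIES
        if self.country not in COUNTRIES:
            raise ConfigError(f"unknown country {self.country!r}")
        return (self.country,)


#: the published scenario set (labels follow the sensitivity tables)
DEFAULT_SCENARIOS: list[tuple[str, ScenarioSpec]] = [
    ("base_case", ScenarioSpec()),
    ("therapy_capped_4_cycles", ScenarioSpec(therapy_cap_cycles=4)),
    ("progression_rebate", ScenarioSpec(progression_rebate=True)),
    ("utilities_qol_gain", ScenarioSpec(utility_variant="qol_gain")),
    ("utilities_rcc_first_line", ScenarioSpec(utility_variant="rcc_first_line")),
    ("utilities_ae_disutility", ScenarioSpec(utility_variant="ae_disutility")),
    (
        "decreasing_progressive_utility",
        ScenarioSpec(progressive_utility_decrement_per_cycle=0.005),
    ),
]


def _parse_scenario(label: str, spec: dict) -> tuple[str, ScenarioSpec]:
    known = {
        "therapy_cap_cycles",
        "progression_rebate",
        "utility_variant",
        "progressive_utility_decrement_per_cycle",
    }
    unknown = set(spec) - known
    if unknown:
        raise ConfigError(f"scenario {label!r}: unknown keys {sorted(unknown)}")
    try:
        return label, ScenarioSpec(**spec)
    except ValueError as exc:
        raise ConfigError(f"scenario {label!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    cfg = RunConfig()
    base = path.parent
    if raw.get("km_csv"):
        cfg.km_csv = (base / raw["km_csv"]).resolve()
        if not cfg.km_csv.exists():
            raise ConfigError(f"km_csv not found: {cfg.km_csv}")
    if raw.get("cost_csv"):
        cfg.cost_csv = (base / raw["cost_csv"]).resolve()
        if not cfg.cost_csv.exists():
            raise ConfigError(f"cost_csv not found: {cfg.cost_csv}")
    cfg.country = str(raw.get("country", "both")).lower()
    cfg.countries()  # validate
    cfg.out_dir = base / raw.get("out_dir", "results")
    cfg.seed = int(raw.get("seed", 0))

    s = raw.get("settings", {})
    try:
        cfg.settings = ModelSettings(
            horizon_cycles=int(s.get("horizon_cycles", 84)),
            cycle_length_months=float(s.get("cycle_length_months", 1.0)),
            annual_discount_rate=float(s.get("annual_discount_rate", 0.03)),
            half_cycle_correction=bool(s.get("half_cycle_correction", False)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    raw_scen = raw.get("scenarios")
    if raw_scen is None:
        cfg.scenarios = list(DEFAULT_SCENARIOS)
    else:
        cfg.scenarios = [
            _parse_scenario(str(label), spec or {}) for label, spec in raw_scen.items()
        ]

    p = raw.get("psa", {})
    cfg.psa_iterations = int(p.get("n_iter", 10_000))
    cfg.psa_cost_se_fraction = float(p.get("cost_se_fraction", 0.20))
    cfg.psa_utility_se = float(p.get("utility_se", 0.05))
    return cfg
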