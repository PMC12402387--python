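"""Master configuration schema, loading/saving and dotted-path patching.

A single JSON (or YAML) document drives the whole analysis: the cycle grid,
the three treatment strategies, shared drug unit costs, economic parameters,
the uncertain-parameter specifications for sensitivity analysis, the
background-mortality stub and the synthetic survival truths (or, after
fitting, a fit bundle replaces the truths at run time).

Unknown keys are rejected; validation errors name the offending path.
Sensitivity analyses address parameters by dotted paths into this document,
e.g. ``drug_costs.benmelstobart``, ``economics.u_pfs``,
``strategies.B+A+EC.ae_probabilities.neutropenia`` or
``cycle.annual_discount_rate``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cohort, economics

__all__ = [
    "SCHEMA_VERSION",
    "CycleModel",
    "LifeTableModel",
    "ComponentModel",
    "StrategyModel",
    "EconModel",
    "ParamSpecModel",
    "SurvivalTruthModel",
    "DigitizationModel",
    "MasterConfig",
    "load_config",
    "save_config",
    "apply_patches",
]

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CycleModel(_Strict):
    cycle_length_days: float = 21.0
    horizon_years: float = 5.0
    n_cycles: int = 87
    annual_discount_rate: float = Field(default=0.05, ge=0.0)
    half_cycle_correction: bool = False

    def to_engine(self) -> cohort.CycleSpec:
        return cohort.CycleSpec(**self.model_dump())


class LifeTableModel(_Strict):
    annual_rate: float = Field(default=0.0075, ge=0.0, lt=1.0)

    def to_engine(self) -> cohort.LifeTable:
        return cohort.LifeTable(annual_rate=self.annual_rate)


class ComponentModel(_Strict):
    drug: str
    max_cycles: Optional[int] = None


class StrategyModel(_Strict):
    name: str
    components: list[ComponentModel]
    ae_probabilities: dict[str, float]


class EconModel(_Strict):
    u_pfs: float = 0.84
    u_pd: float = 0.47
    bsc_cost_per_cycle: float = 1543.46
    followup_frequency_cycles: int = 3
    ae_costs: dict[str, float] = Field(default_factory=dict)
    ae_disutilities: dict[str, float] = Field(default_factory=dict)
    followup_costs: dict[str, float] = Field(default_factory=dict)


class ParamSpecModel(_Strict):
    name: str
    base: float
    low: float
    high: float
    distribution: Literal["gamma", "beta"]


class SurvivalTruthModel(_Strict):
    family: str
    params: list[float]


class DigitizationModel(_Strict):
    n_points: int = 30
    jitter_sd: float = 0.01
    round_decimals: int = 3
    t_max_factor: float = 3.0
    n_at_risk: int = 250


class MasterConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = 42
    wtp_lambda: float = Field(default=38070.59, gt=0.0)
    rmb_per_usd: float = 7.0467
    cycle: CycleModel = Field(default_factory=CycleModel)
    life_table: LifeTableModel = Field(default_factory=LifeTableModel)
    drug_costs: dict[str, float] = Field(default_factory=dict)
    economics: EconModel = Field(default_factory=EconModel)
    strategies: list[StrategyModel] = Field(default_factory=list)
    survival: dict[str, dict[str, SurvivalTruthModel]] = Field(default_factory=dict)
    digitization: DigitizationModel = Field(default_factory=DigitizationModel)
    param_specs: list[ParamSpecModel] = Field(default_factory=list)
    n_psa_iterations: int = 1000
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _cross_checks(self) -> "MasterConfig":
        if not 0.0 <= self.economics.u_pd < self.economics.u_pfs <= 1.0:
            raise ValueError("economics: requires 0 <= u_pd < u_pfs <= 1")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"strategies: duplicate names in {names}")
        for strat in self.strategies:
            for comp in strat.components:
                if comp.drug not in self.drug_costs:
                    raise ValueError(
                        f"strategies.{strat.name}: drug {comp.drug!r} has no "
                        "entry in drug_costs"
                    )
            for ae in strat.ae_probabilities:
                if ae not in self.economics.ae_costs:
                    raise ValueError(
                        f"strategies.{strat.name}.ae_probabilities: {ae!r} has "
                        "no entry in economics.ae_costs"
                    )
                if ae not in self.economics.ae_disutilities:
                    raise ValueError(
                        f"strategies.{strat.name}.ae_probabilities: {ae!r} has "
                        "no entry in economics.ae_disutilities"
                    )
        for spec in self.param_specs:
            if not spec.low <= spec.base <= spec.high:
                raise ValueError(f"param_specs.{spec.name}: requires low <= base <= high")
        return self

    # -- engine-facing views -------------------------------------------------

    def cycle_spec(self) -> cohort.CycleSpec:
        return self.cycle.to_engine()

    def life_table_engine(self) -> cohort.LifeTable:
        return self.life_table.to_engine()

    def econ_params(self) -> economics.EconParams:
        e = self.economics
        return economics.EconParams(
            u_pfs=e.u_pfs,
            u_pd=e.u_pd,
            ae_costs=dict(e.ae_costs),
            ae_disutilities=dict(e.ae_disutilities),
            followup_costs=dict(e.followup_costs),
            followup_frequency_cycles=e.followup_frequency_cycles,
            bsc_cost_per_cycle=e.bsc_cost_per_cycle,
            wtp_lambda=self.wtp_lambda,
        )

    def strategy_configs(self) -> list[cohort.StrategyConfig]:
        out = []
        for strat in self.strategies:
            comps = tuple(
                cohort.DrugComponent(
                    name=c.drug,
                    cost_per_cycle=self.drug_costs[c.drug],
                    max_cycles=c.max_cycles,
                )
                for c in strat.components
            )
            out.append(
                cohort.StrategyConfig(
                    name=strat.name,
                    drug_components=comps,
                    ae_probabilities=dict(strat.ae_probabilities),
                )
            )
        return out

    def survival_truths(self) -> dict[str, dict[str, tuple[str, tuple[float, ...]]]]:
        return {
            arm: {ep: (t.family, tuple(t.params)) for ep, t in eps.items()}
            for arm, eps in self.survival.items()
        }


def load_config(path) -> MasterConfig:
    """Load and validate a master config from JSON or YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return MasterConfig.model_validate(raw)


def save_config(config: MasterConfig, path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


# ---------------------------------------------------------------------------
# dotted-path patching (used by one-way DSA, PSA and scenarios)
# ---------------------------------------------------------------------------


def _set_path(obj, parts: list[str], value) -> None:
    head, rest = parts[0], parts[1:]
    if isinstance(obj, dict):
        if head not in obj:
            raise KeyError(head)
        if rest:
            _set_path(obj[head], rest, value)
        else:
            obj[head] = value
        return
    if isinstance(obj, list):
        # address list elements by their 'name' or 'drug' field
        for item in obj:
            key = item.get("name", item.get("drug")) if isinstance(item, dict) else None
            if key == head:
                if not rest:
                    raise KeyError(head)
                _set_path(item, rest, value)
                return
        raise KeyError(head)
    raise KeyError(head)


def apply_patches(config: MasterConfig, patches: dict[str, float]) -> MasterConfig:
    """Return a new validated config with dotted-path overrides applied.

    Raises ``KeyError`` naming the first unresolvable path segment.
    """
    data = config.model_dump(mode="python")
    for path, value in patches.items():
        parts = path.split(".")
        try:
            _set_path(data, parts, value)
        except KeyError as exc:
            raise KeyError(f"unknown config path {path!r} (failed at {exc.args[0]!r})")
    return MasterConfig.model_validate(data)
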