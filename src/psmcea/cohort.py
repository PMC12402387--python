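"""Three-state partitioned-survival cohort model.

State occupancy at each 21-day cycle is read directly off the fitted OS and
PFS curves: alive-and-progression-free = S_PFS, progressed = S_OS - S_PFS,
dead = 1 - S_OS.  A background-mortality floor keeps the modeled death
hazard at or above general-population mortality.  Costs (drug acquisition
while progression-free, periodic follow-up monitoring, best supportive care
after progression, one-off adverse-event management) and utility-weighted
life-years accrue per cycle and are discounted to present value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .survival import survival_function

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "CycleSpec",
    "DrugComponent",
    "StrategyConfig",
    "LifeTable",
    "CohortTrace",
    "ArmOutcome",
    "discount_factor",
    "state_occupancy",
    "apply_mortality_floor",
    "first_cycle_ae_burden",
    "run_cohort",
]

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


def discount_factor(annual_rate: float, t_years) -> float | np.ndarray:
    """Present-value multiplier (1 + rate)^(-t) at time t in years."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = np.power(1.0 + annual_rate, -t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CycleSpec:
    """Model time grid: 21-day cycles over a 5-year horizon (87 cycles)."""

    cycle_length_days: float = 21.0
    horizon_years: float = 5.0
    n_cycles: int = 87
    annual_discount_rate: float = 0.05
    half_cycle_correction: bool = False

    def __post_init__(self):
        if self.cycle_length_days <= 0 or self.horizon_years <= 0 or self.n_cycles <= 0:
            raise ValueError("cycle spec fields must be positive")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if (
            self.n_cycles * self.cycle_length_days
            < self.horizon_years * DAYS_PER_YEAR - self.cycle_length_days
        ):
            raise ValueError("n_cycles does not cover the stated horizon")

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    def boundary_times_months(self) -> np.ndarray:
        """Times of cycle boundaries 0..n_cycles, in months."""
        return np.arange(self.n_cycles + 1) * self.cycle_length_months

    def start_times_years(self) -> np.ndarray:
        """Cycle start times 0..n_cycles-1, in years (discounting grid)."""
        return np.arange(self.n_cycles) * self.cycle_length_years


@dataclass(frozen=True)
class DrugComponent:
    name: str
    cost_per_cycle: float
    max_cycles: int | None = None  # None = continue while progression-free

    def __post_init__(self):
        if self.cost_per_cycle < 0:
            raise ValueError(f"cost for {self.name} must be >= 0")
        if self.max_cycles is not None and self.max_cycles < 0:
            raise ValueError("max_cycles must be >= 0 or None")


@dataclass(frozen=True)
class StrategyConfig:
    name: str
    drug_components: tuple[DrugComponent, ...]
    ae_probabilities: Mapping[str, float]

    def __post_init__(self):
        for ae, p in self.ae_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"AE probability for {ae} must be in [0,1]")


@dataclass(frozen=True)
class LifeTable:
    """Flat annual all-cause mortality rate (stand-in for a full life table)."""

    annual_rate: float = 0.0075

    def __post_init__(self):
        if not 0.0 <= self.annual_rate < 1.0:
            raise ValueError("annual mortality rate must be in [0, 1)")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy fractions (evaluated at cycle starts)."""

    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    time_years: np.ndarray

    def __post_init__(self):
        sums = self.pfs + self.pd + self.dead
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("state occupancies must sum to 1 at every cycle")

    def __len__(self) -> int:
        return len(self.pfs)


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one strategy (plus per-cycle accrual vectors)."""

    strategy: str
    total_cost: float
    total_qaly: float
    total_ly: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    cycle_costs: np.ndarray | None = None
    cycle_qalys: np.ndarray | None = None


def state_occupancy(s_pfs: float, s_os: float):
    """Partition the cohort at one time point from the two survival curves.

    Independent parametric fits can cross; S_PFS is clipped to S_OS.
    """
    pfs = min(s_pfs, s_os)
    pd_frac = max(0.0, s_os - s_pfs)
    return pfs, pd_frac, 1.0 - s_os


def apply_mortality_floor(
    s_os: Sequence[float], life_table: LifeTable | None, cycle_spec: CycleSpec
) -> np.ndarray:
    """Floor the per-cycle death hazard at background mortality.

    Hazards are compared per cycle: the model's cumulative hazard over a
    cycle, -ln(S_{k+1}/S_k), against the background annual rate scaled by
    the cycle length in years; the larger applies.
    """
    s = np.asarray(s_os, dtype=float)
    if life_table is None or life_table.annual_rate == 0.0:
        return s.copy()
    h_bg = life_table.annual_rate * cycle_spec.cycle_length_years
    out = np.empty_like(s)
    out[0] = s[0]
    for k in range(len(s) - 1):
        if s[k] <= 0.0:
            cond = 0.0
        else:
            cond = min(s[k + 1] / s[k], 1.0)
        h_model = -math.log(cond) if cond > 0 else math.inf
        cond_adj = math.exp(-max(h_model, h_bg)) if math.isfinite(h_model) else 0.0
        out[k + 1] = out[k] * cond_adj
    return out


def first_cycle_ae_burden(
    ae_probabilities: Mapping[str, float],
    ae_costs: Mapping[str, float],
    ae_disutilities: Mapping[str, float],
    cycle_spec: CycleSpec,
) -> tuple[float, float]:
    """Expected one-off adverse-event cost and QALY decrement at cycle 0.

    All grade >=3 events are assumed to occur in the first treatment cycle
    and to last one cycle; cost = sum p_i * cost_i, QALY loss =
    sum p_i * disutility_i * cycle length in years.
    """
    cost = 0.0
    decrement = 0.0
    for ae, p in ae_probabilities.items():
        if ae not in ae_costs:
            raise KeyError(f"AE {ae!r} has a probability but no cost entry")
        if ae not in ae_disutilities:
            raise KeyError(f"AE {ae!r} has a probability but no disutility entry")
        cost += p * ae_costs[ae]
        decrement += p * ae_disutilities[ae] * cycle_spec.cycle_length_years
    return cost, decrement


def _sf_from(fit) -> callable:
    if hasattr(fit, "family") and hasattr(fit, "params"):
        return survival_function(fit.family, fit.params)
    family, params = fit
    return survival_function(family, params)


def run_cohort(
    fits: Mapping[str, object],
    strategy: StrategyConfig,
    econ: "EconParams",
    cycle_spec: CycleSpec,
    life_table: LifeTable | None = None,
) -> tuple[CohortTrace, ArmOutcome]:
    """Run the partitioned-survival cohort for one strategy.

    Parameters
    ----------
    fits
        Mapping with keys "PFS" and "OS"; values are FitResult objects or
        (family, params) pairs on the month time scale.
    strategy
        Arm-specific drug components (with optional cycle caps) and
        grade >=3 adverse-event probabilities.
    econ
        Utilities, AE costs/disutilities, follow-up and BSC costs
        (:class:`psmcea.economics.EconParams`).
    cycle_spec
        Time grid and annual discount rate.
    life_table
        Optional background-mortality floor.

    Returns the per-cycle trace and the discounted ArmOutcome.
    """
    if "PFS" not in fits or "OS" not in fits:
        raise KeyError(f"strategy {strategy.name!r}: fits must contain PFS and OS")
    t_m = cycle_spec.boundary_times_months()
    s_pfs_raw = _sf_from(fits["PFS"])(t_m)
    s_os_raw = _sf_from(fits["OS"])(t_m)
    s_os = apply_mortality_floor(s_os_raw, life_table, cycle_spec)
    # progression-free occupancy cannot exceed overall survival
    s_pfs = np.minimum(s_pfs_raw, s_os)

    n = cycle_spec.n_cycles
    if cycle_spec.half_cycle_correction:
        pfs = 0.5 * (s_pfs[:-1] + s_pfs[1:])[:n]
        osv = 0.5 * (s_os[:-1] + s_os[1:])[:n]
    else:
        pfs = s_pfs[:n]
        osv = s_os[:n]
    pd_frac = np.maximum(0.0, osv - pfs)
    dead = 1.0 - osv
    t_years = cycle_spec.start_times_years()
    trace = CohortTrace(pfs=pfs, pd=pd_frac, dead=dead, time_years=t_years)

    df = discount_factor(cycle_spec.annual_discount_rate, t_years)
    cyc_years = cycle_spec.cycle_length_years

    breakdown: dict[str, float] = {}
    cycle_costs = np.zeros(n)
    # drug acquisition while progression-free, honoring per-component caps
    for comp in strategy.drug_components:
        k_max = n if comp.max_cycles is None else min(comp.max_cycles, n)
        per_cycle = np.zeros(n)
        per_cycle[:k_max] = comp.cost_per_cycle * pfs[:k_max] * df[:k_max]
        breakdown[f"drug:{comp.name}"] = float(per_cycle.sum())
        cycle_costs += per_cycle
    # follow-up monitoring bundle on its schedule while progression-free
    bundle = sum(econ.followup_costs.values())
    freq = econ.followup_frequency_cycles
    sched = np.arange(n) % freq == 0
    fu = np.where(sched, bundle * pfs * df, 0.0)
    breakdown["followup"] = float(fu.sum())
    cycle_costs += fu
    # best supportive care per cycle in the progressed state
    bsc = econ.bsc_cost_per_cycle * pd_frac * df
    breakdown["bsc"] = float(bsc.sum())
    cycle_costs += bsc
    # one-off adverse-event management at cycle 0 (discount factor there is 1)
    ae_cost, ae_qaly_loss = first_cycle_ae_burden(
        strategy.ae_probabilities, econ.ae_costs, econ.ae_disutilities, cycle_spec
    )
    breakdown["ae"] = ae_cost
    cycle_costs[0] += ae_cost

    cycle_qalys = (pfs * econ.u_pfs + pd_frac * econ.u_pd) * cyc_years * df
    cycle_qalys = cycle_qalys.copy()
    cycle_qalys[0] -= ae_qaly_loss
    ly = float(np.sum((pfs + pd_frac) * cyc_years))

    outcome = ArmOutcome(
        strategy=strategy.name,
        total_cost=float(cycle_costs.sum()),
        total_qaly=float(cycle_qalys.sum()),
        total_ly=ly,
        cost_breakdown=breakdown,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )
    return trace, outcome
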