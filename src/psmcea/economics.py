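"""Incremental cost-effectiveness arithmetic.

For an evaluated strategy (index 1) against a control (index 0):

    ICER     = dC / dE                      [USD per QALY]
    INHB(l)  = dE - dC / l                  [QALY]
    INMB(l)  = dE * l - dC = INHB * l       [USD]

where dC and dE are the differences in discounted mean cost and QALYs and
l (lambda) is the willingness-to-pay threshold.  A strategy is deemed
cost-effective when ICER < lambda, equivalently INHB > 0 (for dE > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "EconParams",
    "ComparisonResult",
    "icer",
    "inhb",
    "inmb",
    "compare_all",
]

# dominance flags returned instead of a signed ICER outside the dC>0, dE>0 quadrant
DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and less effective
UNDEFINED = "undefined"    # dE == 0


@dataclass(frozen=True)
class EconParams:
    """Utilities, event costs and the willingness-to-pay threshold.

    Costs are 2023 USD; the default threshold 38,070.59 USD/QALY is three
    times Chinese per-capita GDP.  Discounting lives on the CycleSpec.
    """

    u_pfs: float = 0.84
    u_pd: float = 0.47
    ae_costs: Mapping[str, float] = field(default_factory=dict)
    ae_disutilities: Mapping[str, float] = field(default_factory=dict)
    followup_costs: Mapping[str, float] = field(default_factory=dict)
    followup_frequency_cycles: int = 3
    bsc_cost_per_cycle: float = 1543.46
    wtp_lambda: float = 38070.59

    def __post_init__(self):
        if not (0.0 <= self.u_pd <= 1.0 and 0.0 <= self.u_pfs <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        if self.u_pd >= self.u_pfs:
            raise ValueError("u_pd must be < u_pfs")
        if self.wtp_lambda <= 0:
            raise ValueError("willingness-to-pay threshold must be > 0")
        if self.bsc_cost_per_cycle < 0:
            raise ValueError("BSC cost must be >= 0")
        if self.followup_frequency_cycles < 1:
            raise ValueError("follow-up frequency must be >= 1 cycle")
        for name, m in (
            ("ae_costs", self.ae_costs),
            ("followup_costs", self.followup_costs),
        ):
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} must be >= 0")


def icer(delta_cost: float, delta_eff: float):
    """Incremental cost-effectiveness ratio, or a dominance flag.

    Returns dC/dE as a number only where the ratio is meaningful;
    otherwise a flag: ``"dominant"`` (dC < 0, dE > 0), ``"dominated"``
    (dC > 0, dE < 0) or ``"undefined"`` (dE == 0).
    """
    if delta_eff == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_eff > 0:
        return DOMINANT
    if delta_cost > 0 and delta_eff < 0:
        return DOMINATED
    return delta_cost / delta_eff


def inhb(delta_cost: float, delta_eff: float, wtp_lambda: float) -> float:
    """Incremental net health benefit, dE - dC/lambda, in QALYs."""
    if wtp_lambda <= 0:
        raise ValueError("lambda must be > 0")
    return delta_eff - delta_cost / wtp_lambda


def inmb(delta_cost: float, delta_eff: float, wtp_lambda: float) -> float:
    """Incremental net monetary benefit, dE*lambda - dC, in USD."""
    if wtp_lambda <= 0:
        raise ValueError("lambda must be > 0")
    return delta_eff * wtp_lambda - delta_cost


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise incremental economics at a given threshold."""

    evaluated: str
    control: str
    cost_evaluated: float
    cost_control: float
    eff_evaluated: float
    eff_control: float
    wtp_lambda: float

    @property
    def delta_cost(self) -> float:
        return self.cost_evaluated - self.cost_control

    @property
    def delta_eff(self) -> float:
        return self.eff_evaluated - self.eff_control

    @property
    def icer(self):
        return icer(self.delta_cost, self.delta_eff)

    @property
    def inhb(self) -> float:
        return inhb(self.delta_cost, self.delta_eff, self.wtp_lambda)

    @property
    def inmb(self) -> float:
        return inmb(self.delta_cost, self.delta_eff, self.wtp_lambda)

    @property
    def cost_effective(self) -> bool:
        return self.inhb > 0

    def as_dict(self) -> dict:
        return {
            "evaluated": self.evaluated,
            "control": self.control,
            "cost_evaluated": self.cost_evaluated,
            "cost_control": self.cost_control,
            "eff_evaluated": self.eff_evaluated,
            "eff_control": self.eff_control,
            "delta_cost": self.delta_cost,
            "delta_eff": self.delta_eff,
            "icer": self.icer if isinstance(self.icer, str) else float(self.icer),
            "inhb": self.inhb,
            "inmb": self.inmb,
            "wtp_lambda": self.wtp_lambda,
        }


def compare_all(
    outcomes: Sequence,
    wtp_lambda: float,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[ComparisonResult]:
    """Pairwise comparisons between arm outcomes.

    ``outcomes`` is an ordered sequence of ArmOutcome-like objects (needs
    .strategy, .total_cost, .total_qaly).  By default, for arms
    [a0, a1, ..., an] every later arm is compared against every earlier one
    in order — for the three default strategies (EC, A+EC, B+A+EC) this
    yields exactly A+EC vs EC, B+A+EC vs EC and B+A+EC vs A+EC.
    """
    names = [o.strategy for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate arm names in {names}")
    if len(names) < 2:
        raise ValueError("need at least two arms to compare")
    by_name = {o.strategy: o for o in outcomes}
    if pairs is None:
        pairs = [
            (names[j], names[i])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        # canonical Table-2 row order: vs EC first, then vs the dual arm
        pairs.sort(key=lambda p: (names.index(p[1]), names.index(p[0])))
    results = []
    for evaluated, control in pairs:
        if evaluated not in by_name or control not in by_name:
            raise ValueError(f"unknown arm in pair ({evaluated}, {control})")
        e, c = by_name[evaluated], by_name[control]
        results.append(
            ComparisonResult(
                evaluated=evaluated,
                control=control,
                cost_evaluated=e.total_cost,
                cost_control=c.total_cost,
                eff_evaluated=e.total_qaly,
                eff_control=c.total_qaly,
                wtp_lambda=wtp_lambda,
            )
        )
    return results
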