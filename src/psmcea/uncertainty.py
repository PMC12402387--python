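"""Deterministic, probabilistic and scenario uncertainty analyses.

One-way DSA re-runs the full model at each parameter's range limits and
ranks parameters by the induced ICER swing (tornado).  PSA draws every
uncertain parameter jointly — gamma for costs, beta for probabilities,
proportions and utilities, both moment-matched to the published base value
and 95% range — re-runs the model per iteration, and summarizes incremental
results and cost-effectiveness acceptability curves.  Scenario analysis
applies declarative patches (drug price multipliers, discount overrides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import MasterConfig, ParamSpecModel, apply_patches
from .economics import ComparisonResult, inmb
from .model import ModelRunner

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSASample",
    "PSASummary",
    "CEACPoint",
    "Scenario",
    "InfeasibleMomentsError",
    "moment_match",
    "sample_param",
    "one_way",
    "run_psa",
    "ceac",
    "pairwise_ceac",
    "default_scenarios",
    "run_scenarios",
    "DEFAULT_LAMBDA_GRID",
]

# 0 to 250k USD/QALY in 2,500 steps — covers the 180k-240k window of interest
DEFAULT_LAMBDA_GRID = np.arange(0.0, 250_000.0 + 1, 2_500.0)

_Z95 = 3.92  # width of a 95% normal interval in SE units (2 x 1.96)


class InfeasibleMomentsError(ValueError):
    """Beta moment matching impossible: variance >= base*(1-base)."""


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter addressed by its dotted config path."""

    name: str
    base: float
    low: float
    high: float
    distribution: str  # "gamma" or "beta"

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: requires low <= base <= high")
        if self.distribution not in ("gamma", "beta"):
            raise ValueError(f"{self.name}: distribution must be gamma or beta")
        if self.distribution == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValueError(f"{self.name}: beta parameters must lie in [0, 1]")
        elif self.base <= 0 and self.high > self.low:
            raise ValueError(f"{self.name}: gamma requires base > 0")

    @classmethod
    def from_model(cls, m: ParamSpecModel) -> "ParamSpec":
        return cls(m.name, m.base, m.low, m.high, m.distribution)

    @property
    def se(self) -> float:
        """Standard error implied by treating [low, high] as a 95% interval."""
        return (self.high - self.low) / _Z95


def moment_match(spec: ParamSpec) -> tuple[str, tuple[float, float]]:
    """Distribution parameters matching the spec's mean and SE.

    gamma: shape = (base/SE)^2, scale = SE^2/base.
    beta:  alpha = base*(base*(1-base)/SE^2 - 1), beta = alpha*(1-base)/base.
    A zero-width range denotes a constant.
    """
    se = spec.se
    if se == 0.0:
        return "constant", (spec.base, 0.0)
    if spec.distribution == "gamma":
        shape = (spec.base / se) ** 2
        scale = se**2 / spec.base
        return "gamma", (shape, scale)
    var = se**2
    pq = spec.base * (1.0 - spec.base)
    if var >= pq or spec.base <= 0.0 or spec.base >= 1.0:
        raise InfeasibleMomentsError(
            f"{spec.name}: beta with base {spec.base} cannot have SE {se:.4g}"
        )
    alpha = spec.base * (pq / var - 1.0)
    beta = alpha * (1.0 - spec.base) / spec.base
    return "beta", (alpha, beta)


def sample_param(spec: ParamSpec, rng: np.random.Generator, size=None):
    """Draw from the moment-matched gamma/beta distribution for one spec."""
    kind, (a, b) = moment_match(spec)
    if kind == "constant":
        return spec.base if size is None else np.full(size, spec.base)
    if kind == "gamma":
        return rng.gamma(a, b, size=size)
    draw = rng.beta(a, b, size=size)
    return np.clip(draw, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity (tornado)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    icer_at_low: float
    icer_at_high: float
    failed: bool = False

    @property
    def bar_width(self) -> float:
        if self.failed:
            return float("nan")
        return abs(self.icer_at_high - self.icer_at_low)


def _pair_icer(runner: ModelRunner, cfg: MasterConfig, pair: tuple[str, str]) -> float:
    outcomes = runner.run(cfg)
    e, c = outcomes[pair[0]], outcomes[pair[1]]
    dc = e.total_cost - c.total_cost
    de = e.total_qaly - c.total_qaly
    if de == 0:
        return math.nan
    return dc / de


def one_way(
    runner: ModelRunner,
    specs: Sequence[ParamSpec],
    pair: tuple[str, str],
    *,
    sort: bool = True,
) -> list[TornadoEntry]:
    """Tornado analysis: re-run the model at each spec's low and high.

    All other parameters stay at base.  A model failure at an extreme is
    flagged on the entry rather than dropped.  Entries are sorted by
    descending bar width.
    """
    entries = []
    for spec in specs:
        try:
            lo = _pair_icer(runner, apply_patches(runner.base_config, {spec.name: spec.low}), pair)
            hi = _pair_icer(runner, apply_patches(runner.base_config, {spec.name: spec.high}), pair)
            entries.append(TornadoEntry(spec.name, lo, hi))
        except Exception:
            entries.append(TornadoEntry(spec.name, math.nan, math.nan, failed=True))
    if sort:
        entries.sort(key=lambda e: (math.isnan(e.bar_width), -(e.bar_width if not math.isnan(e.bar_width) else 0.0)))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASample:
    iteration: int
    params: dict[str, float]
    arm_costs: dict[str, float]
    arm_qalys: dict[str, float]

    def incremental(self, pair: tuple[str, str]) -> tuple[float, float]:
        e, c = pair
        return (
            self.arm_costs[e] - self.arm_costs[c],
            self.arm_qalys[e] - self.arm_qalys[c],
        )


@dataclass(frozen=True)
class PSASummary:
    n: int
    pairs: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def run_psa(
    runner: ModelRunner,
    specs: Sequence[ParamSpec],
    n: int,
    seed: int,
    *,
    pairs: Sequence[tuple[str, str]] | None = None,
    max_failure_fraction: float = 0.10,
) -> tuple[list[PSASample], PSASummary]:
    """Monte Carlo PSA: joint parameter draws, full model re-run per draw.

    Reproducible for a fixed seed.  The summary reports, per pair, the mean
    incremental cost and QALYs, the ratio-of-means ICER (headline), the
    iteration-wise mean ICER (secondary; unstable when dE approaches 0) and
    2.5/97.5 percentile intervals.  Aborts if more than
    ``max_failure_fraction`` of iterations fail.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    strategies = [s.name for s in runner.base_config.strategies]
    if pairs is None:
        pairs = [
            (strategies[j], strategies[i])
            for i in range(len(strategies))
            for j in range(i + 1, len(strategies))
        ]
        pairs.sort(key=lambda p: (strategies.index(p[1]), strategies.index(p[0])))
    samples: list[PSASample] = []
    failures: list[str] = []
    for it in range(n):
        drawn = {spec.name: float(sample_param(spec, rng)) for spec in specs}
        try:
            outcomes = runner.run_patched(drawn)
        except Exception as exc:  # noqa: BLE001 - diagnostics collected below
            failures.append(f"iteration {it}: {exc}")
            continue
        samples.append(
            PSASample(
                iteration=it,
                params=drawn,
                arm_costs={k: o.total_cost for k, o in outcomes.items()},
                arm_qalys={k: o.total_qaly for k, o in outcomes.items()},
            )
        )
    if len(failures) > max_failure_fraction * n:
        raise RuntimeError(
            f"{len(failures)}/{n} PSA iterations failed; first: {failures[0]}"
        )
    summary = PSASummary(n=len(samples))
    for pair in pairs:
        dc = np.array([s.incremental(pair)[0] for s in samples])
        de = np.array([s.incremental(pair)[1] for s in samples])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(de != 0, dc / de, np.nan)
        summary.pairs[pair] = {
            "mean_delta_cost": float(dc.mean()),
            "mean_delta_eff": float(de.mean()),
            "icer_ratio_of_means": float(dc.mean() / de.mean()) if de.mean() != 0 else math.nan,
            "icer_mean_of_ratios": float(np.nanmean(ratios)),
            "delta_cost_p2.5": float(np.percentile(dc, 2.5)),
            "delta_cost_p97.5": float(np.percentile(dc, 97.5)),
            "delta_eff_p2.5": float(np.percentile(de, 2.5)),
            "delta_eff_p97.5": float(np.percentile(de, 97.5)),
        }
    return samples, summary


# ---------------------------------------------------------------------------
# cost-effectiveness acceptability curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEACPoint:
    wtp_lambda: float
    probability: dict[str, float]


def ceac(
    samples: Sequence[PSASample],
    lambda_grid: Sequence[float],
    strategies: Sequence[str],
) -> list[CEACPoint]:
    """Probability each strategy has the maximal net monetary benefit.

    Probabilities sum to 1 across strategies at every threshold (ties go to
    the first strategy in the given order).
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be nonempty")
    if not samples:
        raise ValueError("ceac requires at least one PSA sample")
    costs = np.array([[s.arm_costs[name] for name in strategies] for s in samples])
    qalys = np.array([[s.arm_qalys[name] for name in strategies] for s in samples])
    points = []
    for lam in lambda_grid:
        nmb = qalys * lam - costs
        best = np.argmax(nmb, axis=1)
        freq = np.bincount(best, minlength=len(strategies)) / len(samples)
        points.append(CEACPoint(float(lam), dict(zip(strategies, freq.tolist()))))
    return points


def pairwise_ceac(
    samples: Sequence[PSASample],
    lambda_grid: Sequence[float],
    pair: tuple[str, str],
) -> list[tuple[float, float]]:
    """Fraction of iterations with INMB > 0 for one ordered pair, per lambda."""
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be nonempty")
    inc = np.array([s.incremental(pair) for s in samples])
    out = []
    for lam in lambda_grid:
        p = float(np.mean([inmb(dc, de, lam) > 0 for dc, de in inc])) if lam > 0 else float(
            np.mean(inc[:, 0] < 0)
        )
        out.append((float(lam), p))
    return out


# ---------------------------------------------------------------------------
# scenario analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Declarative patch set: drug price multipliers and/or discount override."""

    name: str
    price_multipliers: dict[str, float] = field(default_factory=dict)
    discount_override: float | None = None


def default_scenarios(drug: str = "benmelstobart") -> list[Scenario]:
    """The published scenario set: 50%/90% price cuts; 3%/8% discounting."""
    return [
        Scenario(f"{drug} price -50%", {drug: 0.5}),
        Scenario(f"{drug} price -90%", {drug: 0.1}),
        Scenario("discount 8%", discount_override=0.08),
        Scenario("discount 3%", discount_override=0.03),
    ]


def run_scenarios(
    runner: ModelRunner,
    scenarios: Sequence[Scenario],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[tuple[Scenario, list[ComparisonResult]]]:
    """Re-run the comparisons table under each scenario's patches."""
    results = []
    for sc in scenarios:
        patches: dict[str, float] = {}
        for drug, mult in sc.price_multipliers.items():
            if drug not in runner.base_config.drug_costs:
                raise KeyError(f"scenario {sc.name!r}: unknown drug {drug!r}")
            patches[f"drug_costs.{drug}"] = runner.base_config.drug_costs[drug] * mult
        if sc.discount_override is not None:
            patches["cycle.annual_discount_rate"] = sc.discount_override
        cfg = apply_patches(runner.base_config, patches)
        results.append((sc, runner.compare(cfg, pairs=pairs)))
    return results
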