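"""Synthetic inputs with known ground truth.

The trial's digitized KM coordinates are not deposited, so every pipeline
input is emulated: digitized-looking survival curves sampled from known
parametric families with plot-digitizer-style jitter, a master config whose
economic block reproduces the published parameter table verbatim, and a
flat background-mortality stub.  Because the generating families and
parameters are known, fitting and selection can be scored exactly
(recovery experiments).

Default truths: overall-survival medians 19.3 / 13.3 / 11.9 months for the
triple, dual and chemo-only arms (the trial's reported medians);
progression-free medians fixed at 40% of the OS median.  The triple arm's
PFS curve is log-normal and all other curves log-logistic — the same
families the published analysis selected — with sigma = 0.8 and shape = 2.0
respectively (unimodal-hazard shapes typical of fitted SCLC trial curves).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import (
    ComponentModel,
    DigitizationModel,
    EconModel,
    MasterConfig,
    ParamSpecModel,
    StrategyModel,
    SurvivalTruthModel,
)
from .survival import (
    DigitizedCurve,
    FitResult,
    fit_all_families,
    reconstruct_interval_data,
    select_best,
    survival_at,
)

__all__ = [
    "ARMS",
    "CurveTruth",
    "SyntheticTruth",
    "median_survival",
    "default_truth",
    "gen_km_curve",
    "gen_km_curves",
    "gen_master_config",
    "recovery_experiment",
]

ARMS = ("EC", "A+EC", "B+A+EC")

_OS_MEDIANS = {"EC": 11.9, "A+EC": 13.3, "B+A+EC": 19.3}
_PFS_FRACTION = 0.40
_LOGLOGISTIC_SHAPE = 2.0
_LOGNORMAL_SIGMA = 0.8


def median_survival(family: str, params) -> float:
    """Time t with S(t) = 0.5, solved numerically (months)."""
    lo, hi = 1e-9, 1.0
    while survival_at(family, params, hi) > 0.5:
        hi *= 2.0
        if hi > 1e7:
            return math.inf
    return float(
        optimize.brentq(lambda t: survival_at(family, params, t) - 0.5, lo, hi)
    )


@dataclass(frozen=True)
class CurveTruth:
    """Generating family for one arm x endpoint."""

    arm: str
    endpoint: str
    family: str
    params: tuple[float, ...]

    @property
    def median(self) -> float:
        return median_survival(self.family, self.params)


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generating configuration for a set of digitized-like curves."""

    curves: tuple[CurveTruth, ...]
    digitization: DigitizationModel = field(default_factory=DigitizationModel)
    seed: int = 42

    def __post_init__(self):
        medians = {(c.arm, c.endpoint): c.median for c in self.curves}
        for (arm, ep), m in medians.items():
            if not math.isfinite(m):
                raise ValueError(f"{arm}/{ep}: implied median survival is not finite")
        for arm in {c.arm for c in self.curves}:
            pfs = medians.get((arm, "PFS"))
            os_ = medians.get((arm, "OS"))
            if pfs is not None and os_ is not None and os_ < pfs:
                raise ValueError(f"{arm}: OS median must be >= PFS median")
        if self.digitization.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def curve(self, arm: str, endpoint: str) -> CurveTruth:
        for c in self.curves:
            if c.arm == arm and c.endpoint == endpoint:
                return c
        raise KeyError((arm, endpoint))


def default_truth(seed: int = 42) -> SyntheticTruth:
    curves = []
    for arm in ARMS:
        os_med = _OS_MEDIANS[arm]
        pfs_med = _PFS_FRACTION * os_med
        curves.append(
            CurveTruth(arm, "OS", "log-logistic", (_LOGLOGISTIC_SHAPE, os_med))
        )
        if arm == "B+A+EC":
            curves.append(
                CurveTruth(arm, "PFS", "log-normal", (math.log(pfs_med), _LOGNORMAL_SIGMA))
            )
        else:
            curves.append(
                CurveTruth(arm, "PFS", "log-logistic", (_LOGLOGISTIC_SHAPE, pfs_med))
            )
    return SyntheticTruth(curves=tuple(curves), seed=seed)


def gen_km_curve(
    truth: CurveTruth,
    rng: np.random.Generator,
    digitization: DigitizationModel | None = None,
) -> DigitizedCurve:
    """Digitized-looking curve: S(t) on a grid + jitter, re-monotonized.

    The time grid spans ``t_max_factor`` times the true median; Gaussian
    jitter (truncated at three standard deviations) emulates digitizer
    error, values are rounded to the digitizer's resolution, forced
    nonincreasing by a cumulative minimum and clamped to [0, 1]; the first
    point is pinned at (0, 1).
    """
    dig = digitization or DigitizationModel()
    t_max = dig.t_max_factor * truth.median
    grid = np.linspace(0.0, t_max, dig.n_points + 1)
    s_true = survival_at(truth.family, truth.params, grid)
    noise = rng.normal(0.0, dig.jitter_sd, size=grid.shape) if dig.jitter_sd > 0 else 0.0
    noise = np.clip(noise, -3.0 * dig.jitter_sd, 3.0 * dig.jitter_sd)
    s = np.clip(np.round(s_true + noise, dig.round_decimals), 0.0, 1.0)
    s_mono = np.minimum.accumulate(s)
    if dig.jitter_sd > 0:
        altered = np.mean(np.abs(s_mono - s) > 0.5 * 10.0 ** (-dig.round_decimals))
        if altered > 0.5:
            warnings.warn(
                f"{truth.arm}/{truth.endpoint}: jitter so large that "
                f"{altered:.0%} of points were re-monotonized"
            )
    s_mono[0] = 1.0
    return DigitizedCurve(
        arm_label=truth.arm,
        endpoint=truth.endpoint,
        points=tuple(zip(grid.tolist(), s_mono.tolist())),
        n_at_risk_initial=dig.n_at_risk,
    )


def gen_km_curves(truth: SyntheticTruth, seed: int | None = None) -> list[DigitizedCurve]:
    """Generate every curve in the truth set, bit-reproducibly per seed."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return [gen_km_curve(c, rng, truth.digitization) for c in truth.curves]


# ---------------------------------------------------------------------------
# default master config (economic block = published parameter table)
# ---------------------------------------------------------------------------

_DRUG_COSTS = {
    "anlotinib": (563.24, 450.59, 675.89),
    "carboplatin": (74.50, 59.60, 89.40),
    "etoposide": (134.53, 107.62, 161.44),
    "benmelstobart": (3485.32, 2788.26, 4182.38),
}

_AE_COSTS = {
    "neutropenia": (16619.16, 13295.33, 19942.99),
    "leukopenia": (16619.16, 13295.33, 19942.99),
    "thrombocytopenia": (2674.01, 2139.20, 3208.81),
    "anemia": (510.35, 408.28, 612.42),
    "hypertension": (14.45, 11.56, 17.34),
}

_FOLLOWUP_COSTS = {
    "contrast_ct": (447.02, 357.61, 536.42),
    "cranial_mri": (248.34, 198.67, 298.01),
    "lymph_node_ultrasound": (19.87, 15.89, 23.84),
    "tumor_marker": (72.52, 58.01, 87.02),
    "bone_scan": (120.62, 96.50, 144.75),
    "complete_blood_count": (2.70, 2.16, 3.24),
    "blood_biochemistry": (30.09, 24.07, 36.10),
}

_BSC = (1543.46, 1234.77, 1852.15)
_UTILITIES = {"u_pfs": (0.84, 0.67, 0.88), "u_pd": (0.47, 0.38, 0.57)}
_AE_DISUTILITIES = {
    "neutropenia": (0.09, 0.07, 0.11),
    "leukopenia": (0.09, 0.07, 0.11),
    "thrombocytopenia": (0.20, 0.16, 0.24),
    "anemia": (0.07, 0.06, 0.09),
    "hypertension": (0.04, 0.03, 0.05),
}
_AE_PROBS = {
    "B+A+EC": {
        "neutropenia": (0.70, 0.63, 0.76),
        "leukopenia": (0.38, 0.34, 0.42),
        "thrombocytopenia": (0.50, 0.45, 0.55),
        "anemia": (0.24, 0.22, 0.26),
        "hypertension": (0.16, 0.14, 0.17),
    },
    "A+EC": {
        "neutropenia": (0.73, 0.66, 0.80),
        "leukopenia": (0.31, 0.28, 0.34),
        "thrombocytopenia": (0.54, 0.48, 0.59),
        "anemia": (0.27, 0.24, 0.29),
        "hypertension": (0.12, 0.11, 0.13),
    },
    "EC": {
        "neutropenia": (0.69, 0.62, 0.76),
        "leukopenia": (0.35, 0.31, 0.38),
        "thrombocytopenia": (0.36, 0.32, 0.39),
        "anemia": (0.24, 0.21, 0.26),
        "hypertension": (0.02, 0.01, 0.02),
    },
}
_DISCOUNT = (0.05, 0.00, 0.08)

# chemotherapy backbone capped at 4 induction cycles; targeted/immune
# components continue until progression
_STRATEGY_COMPONENTS = {
    "EC": [("etoposide", 4), ("carboplatin", 4)],
    "A+EC": [("etoposide", 4), ("carboplatin", 4), ("anlotinib", None)],
    "B+A+EC": [
        ("etoposide", 4),
        ("carboplatin", 4),
        ("anlotinib", None),
        ("benmelstobart", None),
    ],
}


def _param_specs() -> list[ParamSpecModel]:
    specs: list[ParamSpecModel] = []

    def add(name, triple, dist):
        base, lo, hi = triple
        specs.append(ParamSpecModel(name=name, base=base, low=lo, high=hi, distribution=dist))

    for drug, triple in _DRUG_COSTS.items():
        add(f"drug_costs.{drug}", triple, "gamma")
    for ae, triple in _AE_COSTS.items():
        add(f"economics.ae_costs.{ae}", triple, "gamma")
    for item, triple in _FOLLOWUP_COSTS.items():
        add(f"economics.followup_costs.{item}", triple, "gamma")
    add("economics.bsc_cost_per_cycle", _BSC, "gamma")
    for u, triple in _UTILITIES.items():
        add(f"economics.{u}", triple, "beta")
    for ae, triple in _AE_DISUTILITIES.items():
        add(f"economics.ae_disutilities.{ae}", triple, "beta")
    for arm, probs in _AE_PROBS.items():
        for ae, triple in probs.items():
            add(f"strategies.{arm}.ae_probabilities.{ae}", triple, "beta")
    add("cycle.annual_discount_rate", _DISCOUNT, "beta")
    return specs


def gen_master_config(seed: int = 42) -> MasterConfig:
    """Default master config: published economic inputs + synthetic truths."""
    truth = default_truth(seed)
    survival = {}
    for c in truth.curves:
        survival.setdefault(c.arm, {})[c.endpoint] = SurvivalTruthModel(
            family=c.family, params=list(c.params)
        )
    strategies = [
        StrategyModel(
            name=arm,
            components=[
                ComponentModel(drug=d, max_cycles=mc) for d, mc in _STRATEGY_COMPONENTS[arm]
            ],
            ae_probabilities={ae: t[0] for ae, t in _AE_PROBS[arm].items()},
        )
        for arm in ARMS
    ]
    return MasterConfig(
        seed=seed,
        drug_costs={d: t[0] for d, t in _DRUG_COSTS.items()},
        economics=EconModel(
            u_pfs=_UTILITIES["u_pfs"][0],
            u_pd=_UTILITIES["u_pd"][0],
            bsc_cost_per_cycle=_BSC[0],
            ae_costs={ae: t[0] for ae, t in _AE_COSTS.items()},
            ae_disutilities={ae: t[0] for ae, t in _AE_DISUTILITIES.items()},
            followup_costs={k: t[0] for k, t in _FOLLOWUP_COSTS.items()},
        ),
        strategies=strategies,
        survival=survival,
        digitization=truth.digitization,
        param_specs=_param_specs(),
    )


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------


def recovery_experiment(
    truth: CurveTruth,
    n_replicates: int,
    seed: int,
    digitization: DigitizationModel | None = None,
    criterion: str = "AIC",
) -> dict:
    """Generate -> reconstruct -> fit -> select, scored against the truth.

    Returns per-replicate relative parameter errors (for the true family's
    own fit) and the family-selection hit rate across all six candidates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    dig = digitization or DigitizationModel()
    rel_errors: list[np.ndarray] = []
    selected: list[str] = []
    for _ in range(n_replicates):
        curve = gen_km_curve(truth, rng, dig)
        data = reconstruct_interval_data(curve)
        fits = fit_all_families(data, seed=int(rng.integers(2**31)))
        best = select_best(fits, criterion)
        selected.append(best.family)
        own: FitResult = next(f for f in fits if f.family == truth.family)
        true_p = np.asarray(truth.params, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs((np.asarray(own.params) - true_p) / np.where(true_p != 0, true_p, 1.0))
        rel_errors.append(rel)
    rel_arr = np.vstack(rel_errors)
    return {
        "truth": truth,
        "n_replicates": n_replicates,
        "selected": selected,
        "hit_rate": float(np.mean([s == truth.family for s in selected])),
        "relative_errors": rel_arr,
        "median_relative_error": float(np.median(rel_arr)),
    }
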