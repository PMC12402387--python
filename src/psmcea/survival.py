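"""Parametric extrapolation of digitized Kaplan-Meier curves.

Digitized (time, survival) coordinates from published KM plots are turned
into pseudo interval count data, fitted by maximum likelihood to six
standard parametric families, and the best family per curve is selected by
AIC or BIC.  The fitted curves feed the partitioned-survival cohort model.

Parameterizations (t in months):

=================  ====================  =======================================
family             params                survival function S(t)
=================  ====================  =======================================
exponential        (rate,)               exp(-rate*t)
weibull            (shape, scale)        exp(-(t/scale)**shape)
log-logistic       (shape, scale)        1 / (1 + (t/scale)**shape)
log-normal         (mu, sigma)           1 - Phi((ln t - mu)/sigma)
gompertz           (shape, rate)         exp(-(rate/shape)*(exp(shape*t)-1)),
                                         shape > 0 enforced
generalized-gamma  (mu, sigma, Q)        Prentice form; Q -> 0 is log-normal
=================  ====================  =======================================
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "FAMILIES",
    "FAMILY_ORDER",
    "DigitizedCurve",
    "IntervalData",
    "FitResult",
    "ParameterDomainError",
    "InconsistentCurveError",
    "DegenerateDataError",
    "FitFailureError",
    "survival_at",
    "survival_function",
    "validate_params",
    "reconstruct_interval_data",
    "fit_family",
    "fit_all_families",
    "select_best",
    "per_cycle_conditional_survival",
    "read_curves_csv",
    "write_curves_csv",
    "fits_to_frame",
    "write_fit_bundle",
    "read_fit_bundle",
]

FAMILY_ORDER = (
    "exponential",
    "weibull",
    "log-logistic",
    "log-normal",
    "gompertz",
    "generalized-gamma",
)

_LOG_EPS = 1e-300
_EXP_MAX = 700.0


class ParameterDomainError(ValueError):
    """Parameters violate the family's positivity constraints."""


class InconsistentCurveError(ValueError):
    """Digitized curve hits zero survival and later rises above zero."""


class DegenerateDataError(ValueError):
    """Interval data contains no events, so nothing can be fitted."""


class FitFailureError(RuntimeError):
    """Every optimizer start (and the fallback) failed to converge."""

    def __init__(self, family: str, diagnostics: list[str]):
        self.family = family
        self.diagnostics = diagnostics
        super().__init__(f"fit failed for family {family!r}: {diagnostics}")


# ---------------------------------------------------------------------------
# survival functions
# ---------------------------------------------------------------------------


def _sf_exponential(t: np.ndarray, rate: float) -> np.ndarray:
    return np.exp(-rate * t)


def _sf_weibull(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    return np.exp(-np.power(t / scale, shape, where=t > 0, out=np.zeros_like(t)))


def _sf_loglogistic(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    z = np.power(t / scale, shape, where=t > 0, out=np.zeros_like(t))
    return 1.0 / (1.0 + z)


def _sf_lognormal(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    out = np.ones_like(t)
    pos = t > 0
    with np.errstate(divide="ignore"):
        z = (np.log(t, where=pos, out=np.zeros_like(t)) - mu) / sigma
    out[pos] = special.ndtr(-z[pos])
    return out


def _sf_gompertz(t: np.ndarray, shape: float, rate: float) -> np.ndarray:
    # cumulative hazard may overflow to inf for large shape*t; S underflows to 0
    with np.errstate(over="ignore"):
        h = (rate / shape) * (np.exp(shape * t) - 1.0)
        return np.exp(-h)


def _sf_gengamma(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    if abs(q) < 1e-8:
        return _sf_lognormal(t, mu, sigma)
    out = np.ones_like(t)
    pos = t > 0
    w = (np.log(t, where=pos, out=np.zeros_like(t)) - mu) / sigma
    a = q ** -2.0
    v = a * np.exp(np.minimum(q * w, _EXP_MAX))
    if q > 0:
        cdf = special.gammainc(a, v)
    else:
        cdf = special.gammaincc(a, v)
    out[pos] = 1.0 - cdf[pos]
    return out


@dataclass(frozen=True)
class _Family:
    name: str
    param_names: tuple[str, ...]
    sf: Callable[..., np.ndarray]
    # True where the parameter must be strictly positive (fitted on log scale)
    positive: tuple[bool, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


FAMILIES: dict[str, _Family] = {
    "exponential": _Family("exponential", ("rate",), _sf_exponential, (True,)),
    "weibull": _Family("weibull", ("shape", "scale"), _sf_weibull, (True, True)),
    "log-logistic": _Family(
        "log-logistic", ("shape", "scale"), _sf_loglogistic, (True, True)
    ),
    "log-normal": _Family("log-normal", ("mu", "sigma"), _sf_lognormal, (False, True)),
    "gompertz": _Family("gompertz", ("shape", "rate"), _sf_gompertz, (True, True)),
    "generalized-gamma": _Family(
        "generalized-gamma", ("mu", "sigma", "Q"), _sf_gengamma, (False, True, False)
    ),
}


def _get_family(family: str) -> _Family:
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; expected one of {list(FAMILY_ORDER)}"
        ) from None


def validate_params(family: str, params: Sequence[float]) -> None:
    fam = _get_family(family)
    params = tuple(float(p) for p in params)
    if len(params) != fam.n_params:
        raise ParameterDomainError(
            f"{family} expects {fam.n_params} params {fam.param_names}, got {len(params)}"
        )
    for name, value, pos in zip(fam.param_names, params, fam.positive):
        if not math.isfinite(value):
            raise ParameterDomainError(f"{family} parameter {name} is not finite")
        if pos and value <= 0:
            raise ParameterDomainError(
                f"{family} parameter {name} must be > 0, got {value}"
            )


def survival_at(family: str, params: Sequence[float], t):
    """Evaluate S(t) for one parametric family.

    `t` may be a scalar or array of times in months; returns the same shape.
    """
    validate_params(family, params)
    fam = _get_family(family)
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("survival_at requires t >= 0")
    out = np.clip(fam.sf(np.atleast_1d(arr), *params), 0.0, 1.0)
    return float(out[0]) if arr.ndim == 0 else out.reshape(arr.shape)


def survival_function(family: str, params: Sequence[float]) -> Callable:
    """Return a vectorized S(t) closure for a validated (family, params)."""
    validate_params(family, params)
    fam = _get_family(family)
    p = tuple(float(x) for x in params)

    def sf(t):
        arr = np.atleast_1d(np.asarray(t, dtype=float))
        return np.clip(fam.sf(arr, *p), 0.0, 1.0)

    return sf


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigitizedCurve:
    """One arm x endpoint survival curve digitized from a published KM plot."""

    arm_label: str
    endpoint: str  # "PFS" or "OS"
    points: tuple[tuple[float, float], ...]
    n_at_risk_initial: int

    def __post_init__(self):
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError(f"endpoint must be PFS or OS, got {self.endpoint!r}")
        if self.n_at_risk_initial <= 0:
            raise ValueError("n_at_risk_initial must be positive")
        pts = tuple((float(t), float(s)) for t, s in self.points)
        object.__setattr__(self, "points", pts)
        if not pts or pts[0] != (0.0, 1.0):
            raise ValueError("first digitized point must be (0, 1.0)")
        times = [t for t, _ in pts]
        survs = [s for _, s in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("digitized times must be strictly increasing")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValueError("digitized survival must be nonincreasing")
        if any(s < 0 or s > 1 for s in survs):
            raise ValueError("survival values must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points])


@dataclass(frozen=True)
class IntervalData:
    """Pseudo individual data on a grid: events/censorings per interval.

    ``censored[k]`` counts subjects censored at the right boundary of
    interval k; reconstruction from a digitized curve censors everyone
    still at risk at the final boundary (no earlier censoring is assumed).
    """

    boundaries: tuple[float, ...]
    events: tuple[int, ...]
    censored: tuple[int, ...]
    at_risk: tuple[int, ...]

    def __post_init__(self):
        m = len(self.boundaries) - 1
        if m < 1 or len(self.events) != m or len(self.censored) != m:
            raise ValueError("events/censored must have len(boundaries) - 1 entries")
        if len(self.at_risk) != m + 1:
            raise ValueError("at_risk must have one entry per boundary")
        if any(e < 0 for e in self.events) or any(c < 0 for c in self.censored):
            raise ValueError("counts must be nonnegative")
        for k in range(m):
            if self.at_risk[k + 1] != self.at_risk[k] - self.events[k] - self.censored[k]:
                raise ValueError("at_risk bookkeeping violated at interval %d" % k)

    @property
    def n_initial(self) -> int:
        return self.at_risk[0]

    @property
    def total_events(self) -> int:
        return int(sum(self.events))


@dataclass(frozen=True)
class FitResult:
    """One parametric family's maximum-likelihood fit to interval data."""

    family: str
    params: tuple[float, ...]
    loglik: float
    aic: float = field(default=float("nan"))
    bic: float = field(default=float("nan"))
    n_params: int = 0
    n_obs: int = 0

    def __post_init__(self):
        validate_params(self.family, self.params)
        k = FAMILIES[self.family].n_params
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "n_params", k)
        if self.n_obs <= 0:
            raise ValueError("n_obs must be positive")
        object.__setattr__(self, "aic", 2.0 * k - 2.0 * self.loglik)
        object.__setattr__(self, "bic", k * math.log(self.n_obs) - 2.0 * self.loglik)

    def sf(self, t):
        return survival_at(self.family, self.params, t)


# ---------------------------------------------------------------------------
# pseudo-data reconstruction
# ---------------------------------------------------------------------------


def reconstruct_interval_data(curve: DigitizedCurve) -> IntervalData:
    """Convert a digitized curve into interval event counts.

    Events per interval follow the conditional survival drops,
    d_k = round(n_k * (1 - S_{k+1}/S_k)); no censoring is assumed before
    the last digitized time, where all remaining subjects are censored.
    """
    s = curve.survival
    n = len(s) - 1
    at_risk = [int(curve.n_at_risk_initial)]
    events: list[int] = []
    for k in range(n):
        if s[k] <= 0:
            if s[k + 1] > 0:
                raise InconsistentCurveError(
                    "survival rises above zero after reaching zero"
                )
            events.append(0)
            at_risk.append(at_risk[-1])
            continue
        cond_drop = 1.0 - s[k + 1] / s[k]
        d = int(round(at_risk[-1] * cond_drop))
        d = max(0, min(d, at_risk[-1]))
        events.append(d)
        at_risk.append(at_risk[-1] - d)
    censored = [0] * n
    censored[-1] = at_risk[-1]  # administrative censoring at final boundary
    at_risk[-1] = 0
    return IntervalData(
        boundaries=tuple(curve.times.tolist()),
        events=tuple(events),
        censored=tuple(censored),
        at_risk=tuple(at_risk),
    )


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


def interval_loglik(family: str, params: Sequence[float], data: IntervalData) -> float:
    """Multinomial interval-censored log-likelihood.

    Events in (t_k, t_{k+1}] contribute ln(S(t_k) - S(t_{k+1})); subjects
    censored at a boundary contribute ln S at that boundary.
    """
    sf = survival_function(family, params)
    s = sf(np.asarray(data.boundaries))
    d = np.asarray(data.events, dtype=float)
    c = np.asarray(data.censored, dtype=float)
    diff = np.maximum(s[:-1] - s[1:], _LOG_EPS)
    ll = float(np.sum(d * np.log(diff)))
    ll += float(np.sum(c * np.log(np.maximum(s[1:], _LOG_EPS))))
    return ll


def _transform(fam: _Family, params: np.ndarray) -> np.ndarray:
    """Natural params -> unconstrained optimizer space (log for positive)."""
    x = np.array(params, dtype=float)
    for i, pos in enumerate(fam.positive):
        if pos:
            x[i] = math.log(x[i])
    return x


def _untransform(fam: _Family, x: np.ndarray) -> np.ndarray:
    p = np.array(x, dtype=float)
    for i, pos in enumerate(fam.positive):
        if pos:
            p[i] = math.exp(min(p[i], 50.0))
    return p


def _empirical_anchors(data: IntervalData) -> tuple[np.ndarray, np.ndarray]:
    """Interior (t, S) pairs of the empirical step curve, S strictly in (0,1)."""
    n0 = data.n_initial
    # empirical survival on the grid (no censoring assumed before the end)
    surv = np.empty(len(data.boundaries))
    surv[0] = 1.0
    alive = n0
    for k, d in enumerate(data.events):
        alive -= d
        surv[k + 1] = alive / n0
    t = np.asarray(data.boundaries)
    keep = (t > 0) & (surv > 1e-6) & (surv < 1 - 1e-6)
    if keep.sum() < 2:
        keep = (t > 0) & (surv > 1e-9)
    return t[keep], surv[keep]


def _start_values(family: str, data: IntervalData) -> np.ndarray:
    """Regression-based starting values on the appropriate linearized scale."""
    t, s = _empirical_anchors(data)
    lt = np.log(t)
    # crude median
    idx = int(np.argmin(np.abs(s - 0.5)))
    t_med = max(t[idx], 1e-3)
    if family == "exponential":
        return np.array([math.log(2.0) / t_med])
    if family == "weibull":
        y = np.log(-np.log(np.clip(s, 1e-9, 1 - 1e-9)))
        k, c = np.polyfit(lt, y, 1)
        k = min(max(k, 0.1), 10.0)
        scale = math.exp(-c / k)
        return np.array([k, min(max(scale, 1e-3), 1e4)])
    if family == "log-logistic":
        y = np.log(1.0 / np.clip(s, 1e-9, 1 - 1e-9) - 1.0)
        b, c = np.polyfit(lt, y, 1)
        b = min(max(b, 0.1), 10.0)
        alpha = math.exp(-c / b)
        return np.array([b, min(max(alpha, 1e-3), 1e4)])
    if family == "log-normal":
        z = special.ndtri(np.clip(1.0 - s, 1e-9, 1 - 1e-9))
        slope, c = np.polyfit(lt, z, 1)
        sigma = 1.0 / min(max(slope, 0.05), 20.0)
        mu = -c * sigma
        return np.array([mu, sigma])
    if family == "gompertz":
        rate0 = math.log(2.0) / t_med
        return np.array([0.05, rate0])
    if family == "generalized-gamma":
        mu, sigma = _start_values("log-normal", data)
        return np.array([mu, sigma, 0.5])
    raise ValueError(family)


def fit_family(
    data: IntervalData, family: str, *, n_starts: int = 5, seed: int = 0
) -> FitResult:
    """Fit one parametric family to interval data by maximum likelihood.

    Uses bounded quasi-Newton optimization from ``n_starts`` seeded starts
    (a regression-based start plus random perturbations); if every start
    fails, falls back to least squares on the log cumulative hazard.
    """
    fam = _get_family(family)
    if data.total_events < 1:
        raise DegenerateDataError("interval data contains no events")

    def nll(x: np.ndarray) -> float:
        p = _untransform(fam, x)
        try:
            return -interval_loglik(family, p, data)
        except (ParameterDomainError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    x0 = _transform(fam, _start_values(family, data))
    best: optimize.OptimizeResult | None = None
    diagnostics: list[str] = []
    for i in range(n_starts):
        start = x0 if i == 0 else x0 + rng.normal(0.0, 0.3, size=x0.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, start, method="L-BFGS-B")
        if not np.all(np.isfinite(res.x)) or not math.isfinite(res.fun):
            diagnostics.append(f"start {i}: non-finite result")
            continue
        if best is None or res.fun < best.fun:
            best = res
        if not res.success:
            diagnostics.append(f"start {i}: {res.message}")
    if best is None or best.fun >= 1e11:
        params = _fallback_cumhaz_ls(fam, data, diagnostics)
    else:
        params = _untransform(fam, best.x)
    ll = interval_loglik(family, params, data)
    return FitResult(
        family=family,
        params=tuple(params),
        loglik=ll,
        n_obs=data.n_initial,
    )


def _fallback_cumhaz_ls(
    fam: _Family, data: IntervalData, diagnostics: list[str]
) -> np.ndarray:
    t, s = _empirical_anchors(data)
    target = np.log(-np.log(np.clip(s, 1e-12, 1 - 1e-12)))

    def resid(x):
        p = _untransform(fam, x)
        sf = fam.sf(t, *p)
        return np.log(-np.log(np.clip(sf, 1e-12, 1 - 1e-12))) - target

    x0 = _transform(fam, _start_values(fam.name, data))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.least_squares(resid, x0)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitFailureError(fam.name, diagnostics + ["fallback LS failed"])
    return _untransform(fam, res.x)


def fit_all_families(
    data: IntervalData,
    families: Iterable[str] = FAMILY_ORDER,
    *,
    seed: int = 0,
) -> list[FitResult]:
    """Fit every requested family, skipping (with a warning) ones that fail."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_family(data, fam, seed=seed))
        except FitFailureError as exc:  # pragma: no cover - rare
            warnings.warn(f"skipping {fam}: {exc}")
    return fits


def select_best(fits: Sequence[FitResult], criterion: str = "AIC") -> FitResult:
    """Pick the fit minimizing AIC or BIC.

    Ties break toward fewer parameters, then the fixed family order.
    """
    if not fits:
        raise ValueError("select_best requires a nonempty list of fits")
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")

    def key(f: FitResult):
        value = f.aic if crit == "AIC" else f.bic
        return (round(value, 9), f.n_params, FAMILY_ORDER.index(f.family))

    return min(fits, key=key)


def per_cycle_conditional_survival(fit, cycle_index: int, cycle_length: float) -> float:
    """Probability of surviving cycle k given alive at its start.

    ``fit`` may be a FitResult or a (family, params) pair; returns
    S(t_{k+1})/S(t_k) with times in months, and 0 once S(t_k) = 0.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    family, params = _as_family_params(fit)
    t0 = cycle_index * cycle_length
    t1 = (cycle_index + 1) * cycle_length
    s = survival_at(family, params, np.array([t0, t1]))
    if s[0] <= 1e-300:  # cohort already absorbed in the dead state
        return 0.0
    return float(min(s[1] / s[0], 1.0))


def _as_family_params(fit) -> tuple[str, tuple[float, ...]]:
    if isinstance(fit, FitResult):
        return fit.family, fit.params
    if hasattr(fit, "family") and hasattr(fit, "params"):
        return fit.family, tuple(fit.params)
    family, params = fit
    return family, tuple(params)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_curves_csv(path) -> list[DigitizedCurve]:
    """Read digitized curves from long-format CSV.

    Columns: arm, endpoint, time_months, survival; an optional
    n_at_risk_initial column sets the starting at-risk count per curve
    (default 250).
    """
    df = pd.read_csv(path)
    required = {"arm", "endpoint", "time_months", "survival"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curves CSV missing columns: {sorted(missing)}")
    curves = []
    for (arm, endpoint), grp in df.groupby(["arm", "endpoint"], sort=False):
        grp = grp.sort_values("time_months")
        n0 = int(grp["n_at_risk_initial"].iloc[0]) if "n_at_risk_initial" in grp else 250
        curves.append(
            DigitizedCurve(
                arm_label=str(arm),
                endpoint=str(endpoint),
                points=tuple(zip(grp["time_months"], grp["survival"])),
                n_at_risk_initial=n0,
            )
        )
    return curves


def write_curves_csv(curves: Sequence[DigitizedCurve], path) -> None:
    rows = [
        {
            "arm": c.arm_label,
            "endpoint": c.endpoint,
            "time_months": t,
            "survival": s,
            "n_at_risk_initial": c.n_at_risk_initial,
        }
        for c in curves
        for t, s in c.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def fits_to_frame(
    fits_by_curve: dict[tuple[str, str], list[FitResult]],
    selected: dict[tuple[str, str], FitResult],
) -> pd.DataFrame:
    """Tabulate all candidate fits (one row each) with a selected flag."""
    rows = []
    for (arm, endpoint), fits in fits_by_curve.items():
        for f in fits:
            p = list(f.params) + [None] * (3 - len(f.params))
            rows.append(
                {
                    "arm": arm,
                    "endpoint": endpoint,
                    "family": f.family,
                    "param1": p[0],
                    "param2": p[1],
                    "param3": p[2],
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "bic": f.bic,
                    "selected": selected[(arm, endpoint)].family == f.family,
                }
            )
    return pd.DataFrame(rows)


def write_fit_bundle(selected: dict[tuple[str, str], FitResult], path) -> None:
    """Serialize selected fits as JSON: {arm: {endpoint: {family, params, ...}}}."""
    bundle: dict[str, dict] = {}
    for (arm, endpoint), f in selected.items():
        bundle.setdefault(arm, {})[endpoint] = {
            "family": f.family,
            "params": list(f.params),
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "n_obs": f.n_obs,
        }
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)


def read_fit_bundle(path) -> dict[str, dict[str, tuple[str, tuple[float, ...]]]]:
    """Load a fit bundle as {arm: {endpoint: (family, params)}}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        arm: {ep: (d["family"], tuple(d["params"])) for ep, d in eps.items()}
        for arm, eps in raw.items()
    }
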