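"""Report writers and the end-to-end pipeline.

``run_all`` chains every stage — synthetic curve generation (when no
digitized curves are supplied), parametric fitting and model selection, the
cohort model per strategy, pairwise economics, tornado DSA, Monte Carlo
PSA, CEACs and scenario analyses — and writes CSV/JSON artifacts plus a
Markdown summary and a manifest.  All randomness derives from the config
seed through named substreams, so two runs with the same config produce
byte-identical JSON outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import survival as sv
from . import uncertainty as unc
from .cohort import ArmOutcome, CohortTrace
from .config import MasterConfig, save_config
from .economics import ComparisonResult
from .model import ModelRunner
from .synthetic import gen_km_curves, SyntheticTruth, CurveTruth

logger = logging.getLogger("psmcea")

__all__ = [
    "fit_curves",
    "comparisons_frame",
    "trace_frame",
    "tornado_frame",
    "psa_pairs_frame",
    "psa_arms_frame",
    "ceac_frame",
    "scenarios_frame",
    "markdown_summary",
    "run_all",
]


def _substream_seeds(seed: int, n: int = 4) -> list[int]:
    """Named substream seeds derived from the master seed (all < 2**31)."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def fit_curves(
    curves: Sequence[sv.DigitizedCurve],
    criterion: str = "AIC",
    seed: int = 0,
) -> tuple[dict, dict]:
    """Fit all six families to every curve and select the best per curve.

    Returns (fits_by_curve, selected), both keyed by (arm, endpoint).
    """
    fits_by_curve: dict[tuple[str, str], list[sv.FitResult]] = {}
    selected: dict[tuple[str, str], sv.FitResult] = {}
    for curve in curves:
        data = sv.reconstruct_interval_data(curve)
        fits = sv.fit_all_families(data, seed=seed)
        key = (curve.arm_label, curve.endpoint)
        fits_by_curve[key] = fits
        selected[key] = sv.select_best(fits, criterion)
        logger.info(
            "fit %s/%s: selected %s (AIC %.2f)",
            curve.arm_label,
            curve.endpoint,
            selected[key].family,
            selected[key].aic,
        )
    return fits_by_curve, selected


def _bundle_from_selected(selected: dict) -> dict:
    bundle: dict[str, dict] = {}
    for (arm, ep), f in selected.items():
        bundle.setdefault(arm, {})[ep] = (f.family, f.params)
    return bundle


# ---------------------------------------------------------------------------
# tabulation (tables round USD/QALY to 2 decimals; JSON keeps full precision)
# ---------------------------------------------------------------------------


def comparisons_frame(
    outcomes: Sequence[ArmOutcome], comparisons: Sequence[ComparisonResult]
) -> pd.DataFrame:
    rows = [
        {
            "Strategy": outcomes[0].strategy,
            "Cost": round(outcomes[0].total_cost, 2),
            "Incr cost": None,
            "Eff": round(outcomes[0].total_qaly, 2),
            "Incr eff": None,
            "ICER": None,
            "INHB": None,
            "INMB": None,
            "Remarks": None,
        }
    ]
    for c in comparisons:
        ic = c.icer
        rows.append(
            {
                "Strategy": c.evaluated,
                "Cost": round(c.cost_evaluated, 2),
                "Incr cost": round(c.delta_cost, 2),
                "Eff": round(c.eff_evaluated, 2),
                "Incr eff": round(c.delta_eff, 2),
                "ICER": ic if isinstance(ic, str) else round(ic, 2),
                "INHB": round(c.inhb, 2),
                "INMB": round(c.inmb, 2),
                "Remarks": f"compared with {c.control}",
            }
        )
    return pd.DataFrame(rows)


def trace_frame(trace: CohortTrace, outcome: ArmOutcome) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cycle": np.arange(len(trace)),
            "time_years": trace.time_years,
            "pfs": trace.pfs,
            "pd": trace.pd,
            "dead": trace.dead,
            "cycle_cost": outcome.cycle_costs,
            "cycle_qaly": outcome.cycle_qalys,
        }
    )


def tornado_frame(entries: Sequence[unc.TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "param": e.param,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "width": e.bar_width,
                "rank": i + 1,
                "failed": e.failed,
            }
            for i, e in enumerate(entries)
        ]
    )


def psa_pairs_frame(samples, pairs) -> pd.DataFrame:
    rows = []
    for s in samples:
        for pair in pairs:
            dc, de = s.incremental(pair)
            rows.append(
                {
                    "iteration": s.iteration,
                    "evaluated": pair[0],
                    "control": pair[1],
                    "delta_cost": dc,
                    "delta_eff": de,
                }
            )
    return pd.DataFrame(rows)


def psa_arms_frame(samples, strategies) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {"iteration": s.iteration}
        for name in strategies:
            row[f"cost_{name}"] = s.arm_costs[name]
            row[f"qaly_{name}"] = s.arm_qalys[name]
        rows.append(row)
    return pd.DataFrame(rows)


def ceac_frame(points: Sequence[unc.CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"lambda": p.wtp_lambda, **{f"p_{k}": v for k, v in p.probability.items()}} for p in points]
    )


def scenarios_frame(results) -> pd.DataFrame:
    rows = []
    for i, (sc, comparisons) in enumerate(results, start=1):
        for c in comparisons:
            ic = c.icer
            rows.append(
                {
                    "No.": i,
                    "Scenario": sc.name,
                    "Strategy": c.evaluated,
                    "Cost": round(c.cost_evaluated, 2),
                    "Incr cost": round(c.delta_cost, 2),
                    "Eff": round(c.eff_evaluated, 2),
                    "Incr eff": round(c.delta_eff, 2),
                    "ICER": ic if isinstance(ic, str) else round(ic, 2),
                    "Remarks": f"compared with {c.control}",
                }
            )
    return pd.DataFrame(rows)


def _md_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    body = [
        ["" if pd.isna(v) else str(v) for v in row] for row in df.itertuples(index=False)
    ]
    widths = [max(len(c), *(len(r[i]) for r in body)) if body else len(c) for i, c in enumerate(cols)]
    fmt = lambda cells: "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines += [fmt(r) for r in body]
    return "\n".join(lines)


def markdown_summary(
    comparisons_df: pd.DataFrame, scenarios_df: pd.DataFrame | None = None
) -> str:
    parts = ["# Cost-effectiveness summary", "", "## Base case", ""]
    parts.append(_md_table(comparisons_df))
    if scenarios_df is not None and not scenarios_df.empty:
        parts += ["", "## Scenarios", "", _md_table(scenarios_df)]
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _log_defaults(config: MasterConfig) -> None:
    c = config.cycle
    logger.info(
        "model defaults: %d cycles of %.0f days over %.1f years; discount %.3f; "
        "half-cycle correction %s; background mortality %.4f/yr; follow-up bundle "
        "every %d cycles; AEs costed once at cycle 0; chemo capped per component; "
        "WTP lambda %.2f",
        c.n_cycles,
        c.cycle_length_days,
        c.horizon_years,
        c.annual_discount_rate,
        c.half_cycle_correction,
        config.life_table.annual_rate,
        config.economics.followup_frequency_cycles,
        config.wtp_lambda,
    )


def run_all(
    config: MasterConfig,
    outdir,
    curves: Sequence[sv.DigitizedCurve] | None = None,
    criterion: str = "AIC",
    n_psa: int | None = None,
) -> dict:
    """Run the full pipeline and write all artifacts under ``outdir``.

    Returns the manifest dict.  On a stage failure the manifest (with the
    failed stage recorded) is still written before the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"status": "running", "stage": None, "artifacts": []}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["artifacts"].append(name)

    seeds = _substream_seeds(config.seed)
    seed_curves, seed_fit, seed_psa, _ = seeds
    _log_defaults(config)
    try:
        manifest["stage"] = "curves"
        if curves is None:
            truth = SyntheticTruth(
                curves=tuple(
                    CurveTruth(arm, ep, fam, tuple(params))
                    for arm, eps in config.survival_truths().items()
                    for ep, (fam, params) in eps.items()
                ),
                digitization=config.digitization,
                seed=seed_curves,
            )
            curves = gen_km_curves(truth)
            emit("curves.csv", lambda p: sv.write_curves_csv(curves, p))

        manifest["stage"] = "fit"
        fits_by_curve, selected = fit_curves(curves, criterion, seed=seed_fit)
        emit(
            "fits.csv",
            lambda p: sv.fits_to_frame(fits_by_curve, selected).to_csv(p, index=False),
        )
        emit("fit_bundle.json", lambda p: sv.write_fit_bundle(selected, p))
        bundle = _bundle_from_selected(selected)

        manifest["stage"] = "cohort"
        runner = ModelRunner(config, bundle)
        outcomes = runner.run()
        traces = runner.traces()
        for name, outcome in outcomes.items():
            safe = name.replace("+", "_")
            emit(
                f"trace_{safe}.csv",
                lambda p, n=name, o=outcome: trace_frame(traces[n], o).to_csv(p, index=False),
            )
        emit(
            "outcomes.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        k: {
                            "total_cost": o.total_cost,
                            "total_qaly": o.total_qaly,
                            "total_ly": o.total_ly,
                            "cost_breakdown": o.cost_breakdown,
                        }
                        for k, o in outcomes.items()
                    },
                    indent=2,
                    sort_keys=True,
                )
            ),
        )

        manifest["stage"] = "comparisons"
        comparisons = runner.compare()
        comp_df = comparisons_frame(list(outcomes.values()), comparisons)
        emit("comparisons.csv", lambda p: comp_df.to_csv(p, index=False))
        emit(
            "comparisons.json",
            lambda p: p.write_text(
                json.dumps([c.as_dict() for c in comparisons], indent=2, sort_keys=True)
            ),
        )

        manifest["stage"] = "dsa"
        specs = [unc.ParamSpec.from_model(m) for m in config.param_specs]
        strategies = [s.name for s in config.strategies]
        tornado_frames = []
        for c in comparisons:
            entries = unc.one_way(runner, specs, (c.evaluated, c.control))
            df = tornado_frame(entries)
            df.insert(0, "pair", f"{c.evaluated} vs {c.control}")
            tornado_frames.append(df)
        emit(
            "tornado.csv",
            lambda p: pd.concat(tornado_frames, ignore_index=True).to_csv(p, index=False),
        )

        manifest["stage"] = "psa"
        n_iter = n_psa if n_psa is not None else config.n_psa_iterations
        samples, psa_summary = unc.run_psa(runner, specs, n_iter, seed_psa)
        pairs = list(psa_summary.pairs)
        emit("psa_pairs.csv", lambda p: psa_pairs_frame(samples, pairs).to_csv(p, index=False))
        emit(
            "psa_arms.csv",
            lambda p: psa_arms_frame(samples, strategies).to_csv(p, index=False),
        )
        emit(
            "psa_summary.json",
            lambda p: p.write_text(
                json.dumps(
                    {f"{e} vs {c}": stats for (e, c), stats in psa_summary.pairs.items()},
                    indent=2,
                    sort_keys=True,
                )
            ),
        )

        manifest["stage"] = "ceac"
        points = unc.ceac(samples, unc.DEFAULT_LAMBDA_GRID, strategies)
        ceac_df = ceac_frame(points)
        pw = unc.pairwise_ceac(samples, unc.DEFAULT_LAMBDA_GRID, (strategies[-1], strategies[0]))
        ceac_df[f"p_pairwise_{strategies[-1]}_vs_{strategies[0]}"] = [p for _, p in pw]
        emit("ceac.csv", lambda p: ceac_df.to_csv(p, index=False))

        manifest["stage"] = "scenarios"
        scen_results = unc.run_scenarios(runner, unc.default_scenarios())
        scen_df = scenarios_frame(scen_results)
        emit("scenarios.csv", lambda p: scen_df.to_csv(p, index=False))

        emit(
            "summary.md",
            lambda p: p.write_text(markdown_summary(comp_df, scen_df)),
        )
        emit("config_used.json", lambda p: save_config(config, p))
        manifest["status"] = "ok"
        manifest["stage"] = "done"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
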