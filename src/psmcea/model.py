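"""Model runner: one validated config in, arm outcomes and comparisons out.

The runner binds a fit bundle (or the config's synthetic survival truths)
to the cohort engine and re-evaluates all strategies for any patched copy
of the configuration — the primitive that one-way DSA, PSA and scenario
analyses loop over.  Survival-curve parameters are deliberately held fixed
across sensitivity runs: the source material provides no uncertainty
distribution for them.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import cohort, economics
from .config import MasterConfig, apply_patches

__all__ = ["ModelRunner"]

FitBundle = Mapping[str, Mapping[str, tuple[str, tuple[float, ...]]]]


class ModelRunner:
    """Evaluates the partitioned-survival model for (patched) configs.

    Parameters
    ----------
    base_config
        Validated master configuration.
    fit_bundle
        ``{arm: {"PFS"|"OS": (family, params)}}``; defaults to the
        config's ``survival`` block (synthetic ground truths).
    """

    def __init__(self, base_config: MasterConfig, fit_bundle: FitBundle | None = None):
        self.base_config = base_config
        self.fit_bundle = fit_bundle if fit_bundle is not None else base_config.survival_truths()
        for strat in base_config.strategies:
            if strat.name not in self.fit_bundle:
                raise KeyError(f"no fitted curves for strategy {strat.name!r}")
            for ep in ("PFS", "OS"):
                if ep not in self.fit_bundle[strat.name]:
                    raise KeyError(f"strategy {strat.name!r} missing {ep} curve")

    def run(self, config: MasterConfig | None = None) -> dict[str, cohort.ArmOutcome]:
        """Run every strategy; returns {name: ArmOutcome} in config order."""
        cfg = config if config is not None else self.base_config
        spec = cfg.cycle_spec()
        econ = cfg.econ_params()
        lt = cfg.life_table_engine()
        out: dict[str, cohort.ArmOutcome] = {}
        for strat in cfg.strategy_configs():
            _, outcome = cohort.run_cohort(
                self.fit_bundle[strat.name], strat, econ, spec, lt
            )
            out[strat.name] = outcome
        return out

    def traces(self, config: MasterConfig | None = None) -> dict[str, cohort.CohortTrace]:
        cfg = config if config is not None else self.base_config
        spec = cfg.cycle_spec()
        econ = cfg.econ_params()
        lt = cfg.life_table_engine()
        return {
            strat.name: cohort.run_cohort(
                self.fit_bundle[strat.name], strat, econ, spec, lt
            )[0]
            for strat in cfg.strategy_configs()
        }

    def compare(
        self,
        config: MasterConfig | None = None,
        pairs: Sequence[tuple[str, str]] | None = None,
    ) -> list[economics.ComparisonResult]:
        cfg = config if config is not None else self.base_config
        outcomes = list(self.run(cfg).values())
        return economics.compare_all(outcomes, cfg.wtp_lambda, pairs=pairs)

    def run_patched(self, patches: dict[str, float]) -> dict[str, cohort.ArmOutcome]:
        """Run with dotted-path overrides applied to the base config."""
        return self.run(apply_patches(self.base_config, patches))
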