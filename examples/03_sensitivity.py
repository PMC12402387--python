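"""One-way (tornado) and probabilistic sensitivity analysis.

Which inputs move the triple-therapy-vs-chemotherapy ICER the most, and how
robust is the base-case verdict to joint parameter uncertainty?
"""

from psmcea import ModelRunner, gen_master_config
from psmcea.uncertainty import ParamSpec, ceac, one_way, run_psa

config = gen_master_config(seed=42)
runner = ModelRunner(config)
specs = [ParamSpec.from_model(m) for m in config.param_specs]
pair = ("B+A+EC", "EC")

entries = one_way(runner, specs, pair)
print(f"tornado, {pair[0]} vs {pair[1]} (top 5 of {len(entries)} parameters):")
print(f"{'parameter':<45}{'ICER low':>12}{'ICER high':>12}{'width':>10}")
for e in entries[:5]:
    print(f"{e.param:<45}{e.icer_at_low:>12,.0f}{e.icer_at_high:>12,.0f}{e.bar_width:>10,.0f}")

samples, summary = run_psa(runner, specs, n=500, seed=7)
stats = summary.pairs[pair]
print(f"\nPSA ({summary.n} Monte Carlo draws, all parameters sampled jointly):")
print(f"  mean dC ${stats['mean_delta_cost']:,.0f} "
      f"(95% CI {stats['delta_cost_p2.5']:,.0f} to {stats['delta_cost_p97.5']:,.0f})")
print(f"  mean dE {stats['mean_delta_eff']:.3f} QALY "
      f"(95% CI {stats['delta_eff_p2.5']:.3f} to {stats['delta_eff_p97.5']:.3f})")
print(f"  ICER (ratio of means) ${stats['icer_ratio_of_means']:,.0f}/QALY")

strategies = [s.name for s in config.strategies]
print("\nacceptability (probability of highest net monetary benefit):")
print(f"{'lambda ($/QALY)':>16}" + "".join(f"{s:>10}" for s in strategies))
for lam in (38070.59, 150_000.0, 200_000.0, 250_000.0):
    (pt,) = ceac(samples, [lam], strategies)
    print(f"{lam:>16,.0f}" + "".join(f"{pt.probability[s]:>10.2f}" for s in strategies))
print(
    "\nThe antibody's acquisition cost dominates the tornado; only at several"
    "\ntimes the base threshold does triple therapy become the likely choice."
)
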