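"""Scenario analysis: drug price cuts and alternative discount rates.

Re-runs the comparisons table under declarative patches - benmelstobart
price reduced by 50% / 90%, and annual discounting at 3% / 8% - mirroring
typical price-negotiation what-ifs.
"""

from psmcea import ModelRunner, gen_master_config
from psmcea.uncertainty import default_scenarios, run_scenarios

config = gen_master_config(seed=42)
runner = ModelRunner(config)
pair = [("B+A+EC", "EC")]

(base,) = runner.compare(pairs=pair)
print(f"base case        : ICER ${base.icer:,.0f}/QALY (triple vs chemo)")

for scenario, (comp,) in run_scenarios(runner, default_scenarios(), pairs=pair):
    icer = comp.icer if isinstance(comp.icer, str) else f"${comp.icer:,.0f}"
    verdict = "cost-effective" if comp.cost_effective else "not cost-effective"
    print(f"{scenario.name:<17}: ICER {icer}/QALY -> {verdict} at "
          f"${comp.wtp_lambda:,.0f}/QALY")

print(
    "\nEven a 90% antibody price cut leaves the ICER above the threshold;"
    "\ndiscount-rate choices barely move it. Price, not methodology, decides."
)
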