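# psmcea

Partitioned-survival cost-effectiveness analysis of first-line therapy for
extensive-stage small-cell lung cancer (ES-SCLC), comparing three strategies
from the Chinese healthcare-system perspective:

* **EC** — etoposide + carboplatin chemotherapy alone,
* **A+EC** — anlotinib added to EC,
* **B+A+EC** — benmelstobart (a PD-L1 antibody) + anlotinib + EC.

The package is aimed at health economists and methodologists who want a
tested, scriptable implementation of the whole workflow: parametric
extrapolation of digitized Kaplan–Meier curves, a three-state cohort model,
incremental economics, and the standard uncertainty analyses.

## The model

**Survival extrapolation.** Digitized (time, survival) coordinates from
published KM plots are converted to pseudo interval data — events per
interval `d_k = round(n_k (1 − S_{k+1}/S_k))`, administrative censoring at
the last digitized time — and fitted by maximum likelihood to six parametric
families (exponential, Weibull, log-logistic, log-normal, Gompertz,
generalized gamma). The best family per curve is selected by AIC (or BIC).

**Partitioned-survival cohort.** State occupancy at each 21-day cycle over a
5-year horizon (87 cycles) is read directly off the fitted curves:

```
PFS(t) = min(S_PFS(t), S_OS(t)),   PD(t) = S_OS(t) − S_PFS(t),   dead(t) = 1 − S_OS(t)
```

with the per-cycle death hazard floored at general-population background
mortality. Drug costs accrue while progression-free (chemotherapy capped at
4 induction cycles), a follow-up monitoring bundle every 3 cycles in PFS,
best supportive care per cycle after progression, and grade ≥3
adverse-event costs and disutilities once in the first cycle. Costs and
QALYs (utilities 0.84 progression-free / 0.47 progressed) are discounted at
5%/year.

**Incremental economics.** For an evaluated strategy against a control, with
willingness-to-pay threshold λ = $38,070.59/QALY (3× Chinese per-capita GDP):

```
ICER = ΔC/ΔE      INHB(λ) = ΔE − ΔC/λ      INMB(λ) = ΔE·λ − ΔC
```

**Uncertainty.** One-way DSA re-runs the model at each parameter's range
limits (tornado); PSA draws all parameters jointly (gamma for costs, beta
for probabilities and utilities, moment-matched to the published base value
and 95% range) over Monte Carlo iterations; acceptability curves report the
probability each strategy maximizes net monetary benefit across thresholds;
scenario analysis applies price cuts and discount-rate overrides.

The trial's digitized coordinates are not deposited, so a synthetic-data
module generates every input with known ground truth (published OS medians
19.3 / 13.3 / 11.9 months; the published cost/utility table verbatim),
which is what the tests and examples run against.

## Worked example

```python
from psmcea import ModelRunner, gen_master_config

config = gen_master_config(seed=42)
runner = ModelRunner(config)
for name, o in runner.run().items():
    print(f"{name:<10} cost ${o.total_cost:>12,.2f}  QALYs {o.total_qaly:.3f}")
for c in runner.compare():
    print(f"{c.evaluated} vs {c.control}: ICER ${c.icer:,.0f}/QALY, INHB {c.inhb:.2f}")
```

prints

```
EC         cost $   41,949.13  QALYs 0.831
A+EC       cost $   50,937.52  QALYs 0.909
B+A+EC     cost $  114,714.26  QALYs 1.209
A+EC vs EC: ICER $114,763/QALY, INHB -0.16
B+A+EC vs EC: ICER $192,380/QALY, INHB -1.53
B+A+EC vs A+EC: ICER $212,650/QALY, INHB -1.38
```

Triple therapy gains about 0.38 QALYs over chemotherapy alone but at an
ICER of roughly $192,000/QALY — far above the $38,070.59 threshold, so the
INHB is negative: under these (synthetic-truth) survival curves the
intensified regimens are not cost-effective, and one-way sensitivity
analysis ranks the antibody's acquisition cost as the dominant driver. The
`examples/` scripts walk through each capability (fitting/extrapolation,
base case, DSA/PSA/CEAC, scenarios); a thin CLI covers the same pipeline:

```bash
cea fixtures --seed 42 --out data
cea run --config data/master.json --out results
```

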