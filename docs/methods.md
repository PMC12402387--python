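# Methods

## Model structure and assumptions

The analysis is a partitioned-survival ("area under the curve") cohort
model with three mutually exclusive health states: progression-free (PFS),
progressed disease (PD) and dead. Unlike a transition-matrix Markov model,
state occupancy is read directly off two marginal survival curves: the
share alive and progression-free at time *t* is `S_PFS(t)`, the share alive
overall is `S_OS(t)`, and the progressed share is their difference. This
carries the usual partitioned-survival assumptions: the two curves are
modeled independently (no structural link between progression and death),
and anything affecting the PD state is captured only through that
difference. Because independently fitted parametric curves can cross, the
engine clips `S_PFS ≤ S_OS` pointwise; the clipped share is reported in the
PFS state, which is the standard convention.

Time runs in 21-day treatment cycles over a 5-year horizon. The cycle count
is `ceil(5 × 365.25 / 21) = 87`, configurable; descriptions of the same
design sometimes say "about 90 cycles", and the knob exists for users who
want a different rounding. Occupancy is evaluated at cycle starts with no
half-cycle correction by default (a `half_cycle_correction` flag averages
start/end occupancy instead); with 87 short cycles the difference is well
under 1% of totals.

## Survival extrapolation

Digitized KM coordinates are converted to pseudo individual data on the
digitized grid. With no published at-risk tables, the reconstruction
assumes no censoring before the last digitized time: events per interval
are `d_k = round(n_k (1 − S_{k+1}/S_k))` and everyone still at risk is
administratively censored at the final boundary. If at-risk tables become
available they can be supplied directly as `IntervalData`.

Six families are fitted by maximizing the multinomial interval-censored
log-likelihood `Σ_k d_k ln(S(t_k) − S(t_{k+1})) + Σ c_k ln S(t_cens)`.
Parameterizations (time in months):

| family | parameters | S(t) |
|---|---|---|
| exponential | rate r > 0 | exp(−rt) |
| Weibull | shape k, scale σ > 0 | exp(−(t/σ)^k) |
| log-logistic | shape β, scale α > 0 | 1/(1 + (t/α)^β) |
| log-normal | μ, s > 0 | 1 − Φ((ln t − μ)/s) |
| Gompertz | shape a > 0, rate b > 0 | exp(−(b/a)(e^{at} − 1)) |
| generalized gamma | μ, σ > 0, Q | Prentice form; Q → 0 is log-normal |

Gompertz shapes are restricted positive so every family satisfies
S(t) → 0; a negative-shape Gompertz (plateauing survival) is rejected as a
parameter-domain error. Optimization is L-BFGS-B on log-transformed
positive parameters from five seeded starts (a regression-based start on
the linearized scale — e.g. `ln(−ln S)` on `ln t` for Weibull — plus random
perturbations); if every start fails, a least-squares fit on the log
cumulative hazard is used as fallback. Model selection minimizes AIC (or
BIC), breaking ties toward fewer parameters and then a fixed family order,
so selection is deterministic. Per-cycle transition quantities are
time-varying conditional survivals `S(t_{k+1})/S(t_k)`.

A practical identifiability limit, quantified by the recovery experiments:
log-normal and log-logistic curves with matched medians are nearly
indistinguishable once plot-digitizer jitter (sd ≈ 0.01) is added — the
selected family then alternates between the two while the fitted curves
remain almost identical. Family *selection* should therefore be trusted
only between well-separated shapes; the economics are insensitive to which
of the two near-identical fits wins.

## Background mortality

The modeled death hazard is floored at general-population mortality,
compared per cycle on the hazard scale: the model's cycle cumulative hazard
`−ln(S_{k+1}/S_k)` against the annual background rate times the cycle
length in years. A flat 0.0075/year stub stands in for a full life table
(configurable); with trial-like OS medians under 20 months the floor almost
never binds inside the 5-year horizon, so the stub's coarseness is
immaterial here.

## Costs, utilities, accrual rules

All costs are 2023 USD (the 7.0467 RMB/USD conversion used for the
published prices is kept as a config constant). Per cycle:

* **Drugs** accrue while progression-free. Etoposide and carboplatin are
  capped at 4 induction cycles; anlotinib and benmelstobart continue until
  progression. Caps are per-component and configurable.
* **Follow-up monitoring** (CT, MRI, ultrasound, tumor markers, bone scan,
  blood counts, biochemistry) is charged as one bundle every 3 cycles while
  progression-free. The source gives unit prices but no schedule; quarterly
  imaging is routine surveillance practice, and the frequency is a config
  knob. Follow-up is not charged in PD (the bundle is framed as
  pre-progression surveillance).
* **Best supportive care** ($1,543.46/cycle) accrues in the PD state.
* **Grade ≥3 adverse events** are assumed to occur in the first treatment
  cycle: expected management cost `Σ p_i c_i` and a one-cycle disutility
  decrement `Σ p_i d_i × (21/365.25)` are applied once at cycle 0.

Utilities are 0.84 (PFS) and 0.47 (PD). Discounting is per-cycle at the
cycle start time, `(1 + r)^{−t_years}` with r = 0.05 by default.

## Incremental economics

`ICER = ΔC/ΔE`, `INHB = ΔE − ΔC/λ`, `INMB = ΔE·λ − ΔC = INHB·λ`, with
λ = $38,070.59/QALY. ICERs outside the ΔC > 0, ΔE > 0 quadrant are reported
as flags (`dominant`, `dominated`, `undefined`) rather than signed numbers,
since a negative ratio conflates opposite verdicts; INHB/INMB stay numeric
everywhere. Report tables round USD and QALY values to 2 decimals; JSON
artifacts keep full precision.

## Uncertainty analyses

* **One-way DSA:** each parameter in turn is set to its range limits with
  everything else at base; the full model is re-run and parameters ranked
  by the absolute ICER swing. A failed extreme run flags the entry rather
  than dropping it.
* **PSA:** ranges are treated as 95% intervals, `SE = (high − low)/3.92`;
  costs are drawn from gamma distributions moment-matched as
  `shape = (base/SE)²`, `scale = SE²/base`, probabilities/utilities from
  betas with `α = base(base(1−base)/SE² − 1)`, `β = α(1−base)/base`
  (zero-width ranges are constants; infeasible beta moments raise). All
  table parameters — including the discount rate, per its published row —
  are sampled jointly per iteration; survival-curve parameters are *not*
  sampled because no uncertainty is published for them, a documented
  limitation. The headline PSA ICER is the ratio of means (stable); the
  iteration-wise mean ratio is reported secondarily since it diverges when
  ΔE approaches 0.
* **CEAC:** at each λ on a 0–250,000 grid (step 2,500), the probability a
  strategy attains the maximal net monetary benefit among the three
  (probabilities sum to 1); a pairwise variant (fraction of iterations with
  INMB > 0) is also exposed, since published acceptability claims often
  read as pairwise.
* **Scenarios:** declarative patches — per-drug price multipliers and
  discount overrides — with defaults mirroring the published set (50%/90%
  benmelstobart price cuts; 3%/8% discounting).

## Synthetic data: what it emulates and what it does not

The generator produces digitized-looking curves from known truths: S(t) on
a uniform grid to three times the true median (31 points), additive
Gaussian jitter (sd 0.01, truncated at 3 sd) emulating digitizer error,
rounding to 3 decimals, cumulative-minimum re-monotonization, and a pinned
(0, 1) first point; initial at-risk count 250 per curve. Default truths:
OS medians 19.3 / 13.3 / 11.9 months for triple/dual/chemo arms, PFS
medians at 40% of OS; the triple arm's PFS is log-normal (σ = 0.8) and the
other five curves log-logistic (shape 2.0) — the same family pattern the
original model selection produced, with shapes typical of fitted SCLC trial
curves.

What passing tests on these inputs show: the reconstruction–fit–select
pipeline recovers known generating processes, the cohort accounting is
exact against independent accumulation, and the economics respond to
parameters in the documented directions. What they do not show: agreement
with the original analysis's unpublished fitted curves (its base-case
totals are not reproducible from published material), real digitizer error
structure (which is autocorrelated, not i.i.d.), or within-trial censoring
patterns.

## Numerical choices and degenerate inputs

Probability differences inside logs are floored at 1e−300; Gompertz
cumulative hazards may overflow to infinity, mapping survival cleanly to 0.
Conditional survival from an absorbed state (S ≤ 1e−300) is 0 by
convention. Curve validation requires a (0, 1.0) first point, strictly
increasing times and nonincreasing survival; interval data with zero events
is rejected as degenerate rather than fitted. All randomness flows from one
master seed through named substreams (curve generation, fitting starts,
PSA), so every artifact is bit-reproducible.

## Problem sizes

Default runs use 6 curves × 6 families × 5 optimizer starts, 87-cycle
cohorts, 40 uncertain parameters, 1,000 PSA iterations and a 101-point λ
grid; the recovery experiments in the tests use 250–500 subjects per curve
and up to 50 replicates. The full pipeline completes in seconds on one CPU.

## Known limitations

Beyond the documented assumptions: no subsequent-line treatment switching
or time-varying utilities; a flat background-mortality stub rather than an
age-structured life table; AE burden applied wholly at cycle 0 with a
one-cycle disutility; no correlation structure in the PSA draws; and the
synthetic PFS medians are stand-ins (the trial's per-arm PFS medians are
not printed in the source material), so absolute cost/QALY totals should be
read as illustrative, not as estimates for the actual trial population.
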