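"""Fit parametric families to a digitized-style KM curve and pick the best.

Generates one synthetic overall-survival curve (log-logistic truth, median
11.9 months, digitizer jitter), reconstructs pseudo interval counts,
fits all six candidate families by maximum likelihood and selects by AIC.
"""

import numpy as np

from psmcea import fit_all_families, reconstruct_interval_data, select_best, survival_at
from psmcea.config import DigitizationModel
from psmcea.synthetic import CurveTruth, gen_km_curve

truth = CurveTruth("EC", "OS", "log-logistic", (2.0, 11.9))
curve = gen_km_curve(truth, np.random.default_rng(42), DigitizationModel())
data = reconstruct_interval_data(curve)
print(f"curve: {len(curve.points)} digitized points, n0={curve.n_at_risk_initial}, "
      f"{data.total_events} reconstructed events\n")

fits = fit_all_families(data, seed=0)
best = select_best(fits, "AIC")
print(f"{'family':<18}{'params':<28}{'loglik':>10}{'AIC':>10}{'BIC':>10}")
for f in sorted(fits, key=lambda f: f.aic):
    mark = " <- selected" if f.family == best.family else ""
    params = ", ".join(f"{p:.3f}" for p in f.params)
    print(f"{f.family:<18}{params:<28}{f.loglik:>10.1f}{f.aic:>10.1f}{f.bic:>10.1f}{mark}")

# the fitted curve extrapolates beyond the digitized follow-up window
t_max = curve.times[-1]
print(f"\ndigitized follow-up ends at {t_max:.1f} months; extrapolated survival:")
for t in (24, 36, 60):
    s = survival_at(best.family, best.params, float(t))
    print(f"  S({t} months) = {s:.3f}")
print("\nLower AIC/BIC = better fit; the selected family drives the cohort model.")
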