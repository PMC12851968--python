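"""Bayesian regression of CAS parameters on immune predictors.

Simulates a cohort in which CD21+CD11c+ B-cell counts raise the resting
baseline alpha (standardized effect +0.48) while every other effect is
null, regresses the generator's parameters on the six immune predictors
and prints the SEXIT summary for the alpha response.  A reduced sampler
configuration keeps the example quick; the analysis default is 5 chains
with 2,000 warmup + 2,000 sampling iterations.
"""

import numpy as np

from cardiocas import (
    RegressionSpec,
    diagnostics,
    fit_multivariate_regression,
    sexit_summary,
    simulate_cohort,
)

effects = np.zeros((7, 10))
effects[0, 3] = 0.48  # alpha ~ CD21+CD11c+ count

truth, _ = simulate_cohort(300, true_coefficients=effects, seed=8,
                           simulate_recordings=False)
spec = RegressionSpec(responses=("alpha",), chains=4, warmup=1000,
                      sampling=1000, seed=8)
draws = fit_multivariate_regression(truth.parameter_table(),
                                    truth.immune_table, spec)
sexit = sexit_summary(draws)

print("SEXIT summary, response alpha (standardized effects, ROPE +/-0.1):")
print(f"{'coefficient':>14} {'ES':>7} {'95% HDI':>18} {'pd':>6} {'ps':>6}")
for _, r in sexit.iterrows():
    if r.coefficient == "Intercept":
        continue
    print(f"{r.coefficient:>14} {r['median']:7.2f} "
          f"[{r.hdi_low:7.2f}, {r.hdi_high:6.2f}] {r.pd:6.3f} {r.ps:6.3f}")

diag = diagnostics(draws, seed=8)
print(f"\nconvergence: max R-hat {diag['max_rhat']:.4f}, "
      f"min ESS {diag['min_ess']:.0f}")
print("only the CD21+CD11c+ coefficient should carry high pd/ps; its ES "
      "should sit near the simulated +0.48.")
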