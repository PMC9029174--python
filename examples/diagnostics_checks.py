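"""Internal model evaluation on a fitted population model.

Observed-vs-predicted regression, visual predictive check coverage,
normalised prediction distribution errors and Bland-Altman agreement —
the standard adequacy panel for a population PK model.
"""

from pippk import (
    CohortDesign,
    NPAGConfig,
    bland_altman,
    final_error_model,
    generate_cohort,
    gof_regression,
    individual_posterior,
    npag_fit,
    npde,
    predict,
    vpc,
)

em = final_error_model()
subjects, _ = generate_cohort(CohortDesign.rich(30), seed=3)
fit = npag_fit(subjects, config=NPAGConfig(seed=3, max_cycles=30, ll_tol=1e-4))

records = []
for s in subjects:
    post = individual_posterior(s, fit.distribution, em)
    records.extend(predict(s, fit.distribution, post))

gof = gof_regression(records, which="population", error_model=em)
print(f"observed vs population-predicted: slope {gof.slope:.2f} "
      f"(95% CI {gof.slope_ci[0]:.2f} to {gof.slope_ci[1]:.2f}), r2 {gof.r2:.3f}")

v = vpc(subjects, fit.distribution, em, n_sim=1000, seed=0)
print(f"VPC: {100 * v.coverage:.1f}% of observations inside the simulated "
      f"5th-95th percentile band (adequate when >= 90%)")

nd = npde(subjects, fit.distribution, em, n_sim=1000, seed=0)
print(f"NPDE: mean {nd.mean:.3f} (target 0), variance {nd.variance:.3f} (target 1)")

ba = bland_altman([(r.observed, r.individual_predicted) for r in records])
print(f"Bland-Altman (percent of pair mean): bias {ba.bias:.2f}%, "
      f"LoA {ba.lower_loa:.1f}% to {ba.upper_loa:.1f}%")
# Slope near 1 with r2 near 1, ~90% VPC coverage and NPDE moments near
# (0, 1) indicate the population model reproduces its own data-generating
# behaviour.
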