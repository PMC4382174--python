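"""Characterize a compound's genotoxicity from per-wing scores.

Draws negative-binomial per-wing mwh-cell scores around a known sigmoid
dose-response (60 wings per dose, the study's sample size), runs the
one-sided dose-dependency test, and fits the constrained Hill sigmoid with
the saturation enforced, recovering EC50 and slope with 95% CIs.
"""

from wingspot import (
    DoseResponse, SigmoidParams, dose_dependency_test, fit_sigmoid,
    generate_dose_scores, two_sample_test,
)

truth = SigmoidParams(bottom=1.2, top=12.0, ec50_mM=2.5, slope=1.2)
doses = [0.0, 0.3, 0.6, 1.25, 2.5, 5.0, 10.0]
table = generate_dose_scores(truth, doses, n_wings=60, noise="nb", seed=21)
drc = DoseResponse.from_table(table, compound="demo", measure="auto")

slope_lin, p, verdict = dose_dependency_test(drc)
print(f"dose-dependency test: slope {slope_lin:.3f}, one-sided P = {p:.2e} "
      f"-> {verdict}")

control = drc.scores[0.0]
for dose in doses[1:3]:
    print(f"two-sample test at {dose} mM vs control: "
          f"P = {two_sample_test(drc.scores[dose], control):.3g}")

fit = fit_sigmoid(drc, top=truth.top)
print(f"EC50 = {fit.ec50_mM:.2f} mM, 95% CI [{fit.ci_ec50[0]:.2f}, "
      f"{fit.ci_ec50[1]:.2f}]  (true {truth.ec50_mM})")
print(f"slope = {fit.slope:.2f}, 95% CI [{fit.ci_slope[0]:.2f}, "
      f"{fit.ci_slope[1]:.2f}]  (true {truth.slope})")
print(f"bottom (spontaneous score) = {fit.bottom:.2f} cells/wing")
# EC50 is the dose producing half the maximal effect; the slope measures how
# steeply the effect rises with dose. Bottom/range absorb protocol scaling so
# EC50 and slope stay comparable between automated and manual counting.
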