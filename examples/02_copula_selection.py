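"""Select the copula family linking income and medical-expenditure shocks.

Builds pseudo-observations (u, v) = (G(ln I | x), H(ln ME | y)) from fitted
margins, then runs the empirical-copula Cramer-von Mises goodness-of-fit
test with parametric bootstrap on each candidate family and keeps the best
non-rejected one by log-likelihood.
"""

import finvuln as fv

spec = fv.rural_spec(n_households=1200, seed=1)
panel, _ = fv.generate_panel(spec)

income = fv.fit_fgls(panel, "income", fv.INCOME_COVARIATES)
medical = fv.fit_fgls(panel, "medical", fv.MEDICAL_COVARIATES)
pairs = fv.pseudo_observations(income, medical, panel)

chosen = fv.select_copula(["gaussian", "clayton", "gumbel", "frank"],
                          pairs, n_boot=100, seed=1)
print(f"selected family: {chosen.family}, gamma = {chosen.gamma:.3f}")
print(f"GOF statistic {chosen.gof_statistic:.4f}, "
      f"p-value {chosen.gof_pvalue:.3f}")
print("\ndecision trace (per-family log-likelihood and GOF p-value):")
for line in chosen.warnings:
    print(" ", line)
print("\nA p-value above 0.05 means the family is compatible with the "
      "observed dependence; among compatible families the highest "
      "log-likelihood wins.  The generating family here is Gaussian with "
      f"gamma = {spec.gamma}.")
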