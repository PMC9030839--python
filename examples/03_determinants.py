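"""Panel regressions of vulnerability on its household determinants.

Runs the full pipeline on synthetic urban and rural strata, then regresses
Delta on demographics, health, and insurance by pooled OLS, fixed effects,
and random effects, with the individual-effect F test, the Hausman test,
and a Chow stability test across the two wave windows.
"""

import finvuln as fv
from finvuln.config import RunConfig

cfg = RunConfig(seed=11)
out = fv.run_pipeline(cfg,
                      specs={"urban": fv.urban_spec(800, seed=11),
                             "rural": fv.rural_spec(800, seed=12)},
                      copula_family="gaussian")

for stratum in ("urban", "rural"):
    fits = out["determinants"][stratum]
    fixed = fits["fixed"]
    marks = fixed.significance_markers()
    print(f"\n=== {stratum}: fixed-effects estimates (n={fixed.n_obs}) ===")
    for name, coef in fixed.coefficients.items():
        if name == "const":
            continue
        se = fixed.standard_errors[name]
        print(f"  {name:<10} {coef:+.4f} ({se:.4f}) {marks[name]}")
    h_stat, h_df, h_p = fits["tests"]["hausman"]
    f_stat, f_df, f_p = fits["tests"]["f_individual"]
    c_stat, c_df, c_p = fits["tests"]["chow"]
    print(f"  F(individual effects) = {f_stat:.2f}, p = {f_p:.3f}")
    print(f"  Hausman chi2({h_df}) = {h_stat:.2f}, p = {h_p:.3f}")
    print(f"  Chow F = {c_stat:.2f}, p = {c_p:.3f}")

print("\nPositive coefficients raise distress risk (e.g. household size, "
      "poor health); negative ones protect (education, labor share, "
      "employee insurance).  Time-invariant covariates are absorbed by "
      "the fixed effects and dropped with a warning.")
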