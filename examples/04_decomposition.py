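"""Attribute the change in mean vulnerability to its determinants.

Two demonstrations: (1) the decomposition arithmetic on the published
CHARLS elasticities and covariate changes, reproducing the printed
contribution tables; (2) the same decomposition computed end to end on a
synthetic panel from the fitted fixed-effects model.
"""

import finvuln as fv
from finvuln.config import RunConfig
from finvuln.reference import TOTALS, published_contributions

# -- published worked example -------------------------------------------------
printed = published_contributions("urban", "2011-2013")
total = TOTALS[("urban", "2011-2013")]
table = fv.contribution_rows(printed["elasticity"].to_dict(),
                             printed["change_pct"].to_dict(), total)
print(f"urban 2011-2013: mean vulnerability changed by {total:.3f}%")
print(table.rows.round(3).to_string())
print(f"residual {table.residual_absolute:.3f} "
      f"({table.residual_relative:.2f}% of the total)\n")
print("Each absolute contribution is elasticity x percent change of the "
      "determinant; e.g. the spread of employee medical insurance "
      "(insur_em, +156%) accounts for most of the decline in urban "
      "vulnerability over 2011-2013.\n")

# -- same decomposition on a synthetic panel ----------------------------------
out = fv.run_pipeline(RunConfig(seed=3),
                      specs={"urban": fv.urban_spec(800, seed=3)},
                      copula_family="gaussian")
synth = out["decomposition"][("urban", 2011, 2013)]
print("synthetic urban 2011-2013 decomposition "
      f"(total change {synth.total_absolute:.2f}%):")
print(synth.to_frame().round(3).to_string())
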