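"""Contribution decomposition of changes in mean vulnerability.

Between two waves the percent change in mean vulnerability is attributed to
each determinant through its elasticity.  The elasticity of determinant x is
the fixed-effects coefficient scaled by (x_bar / delta_bar); its absolute
contribution is elasticity times the percent change in x_bar; the relative
contribution expresses that as a share of the total percent change in mean
vulnerability.  A residual row absorbs the part of the total the determinants
do not explain, so relative contributions (rows plus residual) sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def elasticity(coef: float, x_bar: float, y_bar: float) -> float:
    """Fixed-effects coefficient scaled to an elasticity: coef * x_bar / y_bar."""
    if y_bar == 0:
        raise ValueError("mean vulnerability y_bar must be nonzero")
    return coef * x_bar / y_bar


def percent_change(x_bar_t: float, x_bar_t1: float) -> float:
    """100 * (x_t1 - x_t) / x_t."""
    if x_bar_t == 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return 100.0 * (x_bar_t1 - x_bar_t) / x_bar_t


@dataclass
class DecompositionTable:
    """Per-determinant contribution rows plus residual and total."""

    rows: pd.DataFrame          # index: determinant; columns: elasticity,
                                # change_pct, absolute_contribution,
                                # relative_contribution
    residual_absolute: float
    residual_relative: float
    total_absolute: float       # percent change in mean vulnerability
    window: tuple | None = None
    stratum: str | None = None

    @property
    def total_relative(self) -> float:
        return 100.0

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.loc["residual"] = [np.nan, np.nan,
                               self.residual_absolute, self.residual_relative]
        out.loc["total"] = [np.nan, np.nan, self.total_absolute, 100.0]
        return out


def contribution_rows(elasticities: dict, changes: dict,
                      total: float) -> DecompositionTable:
    """Assemble a decomposition table from given elasticities and changes.

    ``total`` is the percent change in mean vulnerability over the window.
    Row absolute contributions are elasticity x change (exact arithmetic);
    the residual closes the identity total = sum(rows) + residual.
    """
    if total == 0:
        raise ValueError("total change is zero; relative contributions undefined")
    names = list(elasticities)
    rows = pd.DataFrame(index=pd.Index(names, name="determinant"),
                        columns=["elasticity", "change_pct",
                                 "absolute_contribution", "relative_contribution"],
                        dtype=float)
    for name in names:
        e, c = elasticities[name], changes[name]
        absolute = e * c
        rows.loc[name] = [e, c, absolute, 100.0 * absolute / total]
    explained = rows["absolute_contribution"].sum()
    resid = total - explained
    return DecompositionTable(rows, resid, 100.0 * resid / total, total)


def contribution_table(fe, means_t: dict, means_t1: dict,
                       delta_mean_t: float, delta_mean_t1: float,
                       determinants=None, window=None,
                       stratum=None) -> DecompositionTable:
    """Decompose the change in mean vulnerability between two waves.

    Parameters
    ----------
    fe : PanelEstimates or dict
        Fixed-effects coefficients (a fitted :class:`PanelEstimates` or a
        plain name -> coefficient dict).
    means_t, means_t1 : dict
        Determinant means in the base and end wave of the window; the base
        wave's means enter the elasticities.
    delta_mean_t, delta_mean_t1 : float
        Mean vulnerability in the two waves.
    """
    coefs = fe.coefficients if hasattr(fe, "coefficients") else dict(fe)
    if determinants is None:
        determinants = [c for c in coefs if c != "const"]
    missing = [c for c in determinants if c not in coefs]
    if missing:
        raise KeyError(f"fixed-effects coefficients missing for: {', '.join(missing)}")
    total = percent_change(delta_mean_t, delta_mean_t1)
    elas = {c: elasticity(coefs[c], means_t[c], delta_mean_t) for c in determinants}
    chg = {c: percent_change(means_t[c], means_t1[c]) for c in determinants}
    table = contribution_rows(elas, chg, total)
    table.window, table.stratum = window, stratum
    return table
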