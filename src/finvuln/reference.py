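"""Published reference values from the CHARLS 2011/2013/2015 application.

The study that introduced this vulnerability measure reports, for Chinese
urban and rural households, the per-determinant elasticities, covariate
percent changes, and contribution decompositions over the 2011-2013 and
2013-2015 windows, together with the total percent change in mean
vulnerability.  Those printed values are frozen here: the elasticities and
changes serve as worked-example *inputs* to the decomposition arithmetic,
and the printed contributions as the values that arithmetic should
reproduce (up to the rounding of the printed inputs).

Each table maps determinant -> (elasticity, change_pct, absolute
contribution, relative contribution) as printed.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["elasticity", "change_pct", "absolute_contribution",
            "relative_contribution"]

# stratum -> window -> {determinant: (elasticity, change, absolute, relative)}
_ROWS = {
    ("urban", "2011-2013"): {
        "age":       (-0.142, 1.368, -0.194, 1.006),
        "gender":    (-0.046, 23.088, -1.051, 5.447),
        "education": (-0.418, -5.888, 2.464, -12.768),
        "married":   (0.021, -3.133, -0.066, 0.343),
        "size":      (0.419, -8.283, -3.468, 17.972),
        "labor":     (-0.402, 7.552, -3.038, 15.742),
        "area":      (-0.103, -3.835, 0.394, -2.042),
        "health":    (1.048, 0.791, 0.829, -4.295),
        "diseases":  (-0.031, 8.761, -0.273, 1.416),
        "disable":   (0.074, -29.391, -2.188, 11.339),
        "health_s":  (0.096, 15.510, 1.492, -7.732),
        "insur_em":  (-0.071, 156.062, -11.027, 57.138),
        "insur_cm":  (-0.003, 57.895, -0.178, 0.922),
        "insur_om":  (-0.128, -10.130, 1.293, -6.700),
    },
    ("urban", "2013-2015"): {
        "age":       (-0.142, 3.351, -0.476, -0.663),
        "gender":    (-0.046, -2.748, 0.125, 0.174),
        "education": (-0.418, -3.557, 1.489, 2.075),
        "married":   (0.021, -2.985, -0.063, -0.088),
        "size":      (0.419, 14.593, 6.110, 8.517),
        "labor":     (-0.402, -9.201, 3.701, 5.159),
        "area":      (-0.103, -13.190, 1.356, 1.890),
        "health":    (1.048, 0.202, 0.212, 0.296),
        "diseases":  (-0.031, -0.458, 0.014, 0.020),
        "disable":   (0.074, 22.335, 1.663, 2.318),
        "health_s":  (0.096, 21.908, 2.108, 2.938),
        "insur_em":  (-0.071, 0.047, -0.003, -0.005),
        "insur_cm":  (-0.003, 7.692, -0.024, -0.033),
        "insur_om":  (-0.128, 2.359, -0.301, -0.420),
    },
    ("rural", "2011-2013"): {
        "age":       (-0.453, 1.341, -0.608, 3.517),
        "gender":    (0.104, 18.575, 1.929, -11.161),
        "education": (-0.347, 23.102, -8.027, 46.444),
        "married":   (-0.125, 3.732, -0.467, 2.705),
        "size":      (0.395, -9.949, -3.928, 22.725),
        "labor":     (-0.382, 6.085, -2.321, 13.431),
        "area":      (-0.013, 13.961, -0.181, 1.049),
        "health":    (0.781, -2.141, -1.672, 9.673),
        "diseases":  (0.090, 7.351, 0.663, -3.836),
        "disable":   (0.054, -33.648, -1.810, 10.474),
        "health_s":  (0.026, 4.314, 0.114, -0.660),
        "insur_em":  (0.001, 206.667, 0.198, -1.144),
        "insur_cm":  (-0.004, 93.750, -0.375, 2.169),
        "insur_om":  (0.014, -5.605, -0.077, 0.444),
    },
    ("rural", "2013-2015"): {
        "age":       (-0.453, 3.508, -1.590, -3.043),
        "gender":    (0.104, -2.532, -0.263, -0.503),
        "education": (-0.347, -2.502, 0.869, 1.664),
        "married":   (-0.125, -3.238, 0.406, 0.776),
        "size":      (0.395, 20.818, 8.219, 15.733),
        "labor":     (-0.382, -18.703, 7.136, 13.660),
        "area":      (-0.013, -9.153, 0.119, 0.228),
        "health":    (0.781, 0.746, 0.582, 1.115),
        "diseases":  (0.090, -1.297, -0.117, -0.224),
        "disable":   (0.054, 16.114, 0.867, 1.660),
        "health_s":  (0.026, 26.316, 0.696, 1.332),
        "insur_em":  (0.001, -8.696, -0.008, -0.016),
        "insur_cm":  (-0.004, -6.452, 0.026, 0.049),
        "insur_om":  (0.014, 3.207, 0.044, 0.084),
    },
}

#: Printed total percent change in mean vulnerability per (stratum, window).
TOTALS = {
    ("urban", "2011-2013"): -19.298,
    ("urban", "2013-2015"): 71.739,
    ("rural", "2011-2013"): -17.284,
    ("rural", "2013-2015"): 52.239,
}

#: Printed residual rows (absolute, relative).  The urban rows are known to
#: be internally inconsistent with the printed variable rows and totals and
#: are kept only for completeness; the rural rows verify.
RESIDUALS = {
    ("urban", "2011-2013"): (-3.968, 24.500),
    ("urban", "2013-2015"): (55.870, 79.880),
    ("rural", "2011-2013"): (-0.721, 4.170),
    ("rural", "2013-2015"): (35.254, 67.486),
}

#: Published copula dependence parameters (Gaussian family) per stratum.
COPULA_GAMMA = {"urban": 0.144, "rural": 0.214}


def published_contributions(stratum: str, window: str) -> pd.DataFrame:
    """Printed decomposition rows for one (stratum, window) cell."""
    key = (stratum, window)
    if key not in _ROWS:
        raise KeyError(f"no published table for {key}")
    return pd.DataFrame.from_dict(_ROWS[key], orient="index", columns=_COLUMNS)
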