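"""Read, validate, clean, and write household panel tables.

The canonical on-disk format is a headered CSV with one row per household-wave
observation.  Required columns (case-insensitive): ``household_id``, ``wave``,
``stratum``, the four per-capita monetary variables ``I``, ``ME``, ``DP``,
``LA`` (CNY/year), and the covariates ``Age``, ``Gender``, ``Education``,
``Married``, ``Size``, ``Labor``, ``Area``, ``Health``, ``Diseases``,
``Disable``, ``Health_S``, ``Insur_EM``, ``Insur_CM``, ``Insur_OM``.

Internally the panel is a :class:`pandas.DataFrame` with lower-cased column
names; ``stratum`` is ``"urban"`` or ``"rural"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BINARY_COLUMNS, MONETARY_COLUMNS, DETERMINANTS

ID_COLUMNS = ("household_id", "wave", "stratum")
REQUIRED_COLUMNS = ID_COLUMNS + MONETARY_COLUMNS + DETERMINANTS


class PanelSchemaError(ValueError):
    """The CSV is missing a required column or a field fails to parse."""


@dataclass
class CleanLog:
    """Record of rows dropped or values offset by :func:`clean_panel`."""

    dropped: list[tuple] = field(default_factory=list)   # (household_id, wave, reason)
    offset: list[tuple] = field(default_factory=list)    # (household_id, wave, column, old, new)
    flagged: list[tuple] = field(default_factory=list)   # (household_id, wave, column, value)

    @property
    def n_modified(self) -> int:
        return len(self.dropped) + len(self.offset)


def read_panel(path, config=None) -> pd.DataFrame:
    """Read a panel CSV and validate it against the schema.

    Column matching is case-insensitive.  Raises :class:`PanelSchemaError`
    naming the missing column, or the row index of a non-numeric monetary
    field.  Row order is preserved.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in MONETARY_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelSchemaError(
                f"non-numeric value in monetary column {col!r} at row {row}"
            )
        df[col] = coerced
    df["wave"] = df["wave"].astype(int)
    df["stratum"] = df["stratum"].astype(str).str.lower()
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    """Write a validated panel back to CSV (lower-case canonical header)."""
    df.to_csv(path, index=False)


def validate_panel(df: pd.DataFrame, strict: bool = True) -> list[str]:
    """Check the record invariants; return a list of problem descriptions.

    With ``strict=True`` any problem raises :class:`PanelSchemaError`.
    Binary columns outside {0,1} (a known artifact in some source data) are
    flagged, never silently coerced.
    """
    problems: list[str] = []
    if df.duplicated(subset=["household_id", "wave"]).any():
        problems.append("duplicate (household_id, wave) pairs")
    if (df["i"] <= 0).any():
        problems.append("non-positive income I")
    if (df["me"] <= 0).any():
        problems.append("non-positive medical expenditure ME")
    if (df["dp"] < 0).any():
        problems.append("negative debt payments DP")
    if (df["la"] < 0).any():
        problems.append("negative liquid assets LA")
    if ((df["labor"] < 0) | (df["labor"] > 1)).any():
        problems.append("labor outside [0,1]")
    if (~df["health"].isin(range(1, 7))).any():
        problems.append("health outside {1..6}")
    for col in BINARY_COLUMNS:
        if (~df[col].isin([0, 1])).any():
            problems.append(f"binary column {col!r} has values outside {{0,1}}")
    if strict and problems:
        raise PanelSchemaError("; ".join(problems))
    return problems


def clean_panel(
    df: pd.DataFrame, policy: str = "drop", me_offset: float = 1.0
) -> tuple[pd.DataFrame, CleanLog]:
    """Apply the zero-handling policy so the log-linear model is defined.

    ``drop``
        remove rows with I <= 0 or ME <= 0.
    ``offset``
        replace ME = 0 by ``me_offset`` (rows with I <= 0 or ME < 0 are
        still dropped — a log-income model cannot represent them).

    LA = 0 is legal and retained; the vulnerability measure maps it to a
    -inf asset threshold downstream.  Every modification is logged.
    """
    if policy not in ("drop", "offset"):
        raise ValueError(f"unknown clean policy {policy!r}")
    log = CleanLog()
    df = df.copy()

    for col in BINARY_COLUMNS:
        bad = ~df[col].isin([0, 1])
        for _, row in df.loc[bad].iterrows():
            log.flagged.append((row["household_id"], row["wave"], col, row[col]))

    if policy == "offset":
        zero_me = df["me"] == 0
        for _, row in df.loc[zero_me].iterrows():
            log.offset.append((row["household_id"], row["wave"], "me", 0.0, me_offset))
        df.loc[zero_me, "me"] = me_offset

    bad_i = df["i"] <= 0
    bad_me = df["me"] <= 0
    for _, row in df.loc[bad_i | bad_me].iterrows():
        reason = "I<=0" if row["i"] <= 0 else "ME<=0"
        log.dropped.append((row["household_id"], row["wave"], reason))
    df = df.loc[~(bad_i | bad_me)].reset_index(drop=True)
    return df, log
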