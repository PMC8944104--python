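"""Readers and writers for the tabular formats the pipeline touches.

Two minute-record dialects are supported: the public NHANES physical activity
monitor layout (PAXMIN files: SEQN / PAXDAYM / PAXDAYWM / PAXMTSM / PAXPREDM)
and the package's own ``synthetic`` layout with explicit column names.  All
readers are total: malformed input raises a diagnostic naming the file, the
offending rows and the violated rule — never a partial silent load.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

WEAR_STATES = ("wake_wear", "sleep_wear", "non_wear", "invalid")

#: wear states whose activity values are usable measurements; non-wear and
#: invalid minutes are treated as missing downstream
VALID_WEAR_STATES = ("wake_wear", "sleep_wear")

#: NHANES PAXPREDM wear-prediction codes
_PAXPREDM_MAP = {1: "wake_wear", 2: "sleep_wear", 3: "non_wear", 4: "invalid"}

#: sentinel used by PAXMTSM for unusable minute summaries
_PAXMTSM_MISSING = -0.01

HEALTH_LEVELS = ("excellent", "very good", "good", "fair", "poor")
POOR_FAIR = ("fair", "poor")

#: closed covariate level sets; "<25" marks pre-exclusion under-age rows
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<25", "25-29", "30-39", "40-49", "50-59", "60-69", "70+"),
    "gender": ("male", "female"),
    "race_ethnicity": ("NH White", "NH Black", "Mexican American",
                       "Other Hispanic", "NH Asian", "other"),
    "education": ("<HS", "HS grad", "some college", "college grad+"),
    "income": ("<$20k", "$20k-$44.9k", "$45k-$74.9k", ">=$75k"),
    "work_status": ("did not work", "<40 h", "40+ h"),
}

#: lower age bound of each age-group level, in years
AGE_GROUP_LOWER = {"<25": 0, "25-29": 25, "30-39": 30, "40-49": 40,
                   "50-59": 50, "60-69": 60, "70+": 70}

MINUTE_COLUMNS = ["participant_id", "day_index", "day_of_week",
                  "minute_of_day", "activity", "wear_state"]


def _require_columns(df: pd.DataFrame, cols: list[str], path: os.PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def read_minute_records(path: os.PathLike, dialect: str = "synthetic") -> pd.DataFrame:
    """Load and validate a minute-level activity table.

    Parameters
    ----------
    path : path
        CSV (or parquet, by extension) file.
    dialect : {"synthetic", "nhanes_paxmin"}
        ``nhanes_paxmin`` maps SEQN -> participant_id, PAXDAYM -> day_index,
        PAXDAYWM -> day_of_week, PAXMTSM -> activity (-0.01 sentinel becomes
        missing), PAXPREDM -> wear_state, and derives minute_of_day from row
        order within (SEQN, PAXDAYM) since the public files index time by
        sample count within day.
    """
    path = Path(path)
    df = _read_table(path)
    if dialect == "nhanes_paxmin":
        _require_columns(df, ["SEQN", "PAXDAYM", "PAXDAYWM", "PAXMTSM", "PAXPREDM"], path)
        out = pd.DataFrame(
            {
                "participant_id": df["SEQN"].astype(np.int64),
                "day_index": df["PAXDAYM"].astype(np.int64),
                "day_of_week": df["PAXDAYWM"].astype(np.int64),
                "activity": df["PAXMTSM"].astype(float),
                "wear_state": df["PAXPREDM"].map(_PAXPREDM_MAP),
            }
        )
        if out["wear_state"].isna().any():
            bad = sorted(df.loc[out["wear_state"].isna(), "PAXPREDM"].unique())
            raise FormatError(f"{path}: unknown PAXPREDM code(s) {bad}")
        out["minute_of_day"] = out.groupby(
            ["participant_id", "day_index"], sort=False
        ).cumcount().astype(np.int64)
        out.loc[np.isclose(out["activity"], _PAXMTSM_MISSING), "activity"] = np.nan
        out = out[MINUTE_COLUMNS]
    elif dialect == "synthetic":
        _require_columns(df, MINUTE_COLUMNS, path)
        out = df[MINUTE_COLUMNS].copy()
        for c in ("participant_id", "day_index", "day_of_week", "minute_of_day"):
            out[c] = out[c].astype(np.int64)
        out["activity"] = out["activity"].astype(float)
    else:
        raise FormatError(f"unknown minute-record dialect {dialect!r}")
    _validate_minute_records(out, path)
    return out.reset_index(drop=True)


def _validate_minute_records(df: pd.DataFrame, path: os.PathLike) -> None:
    bad_state = ~df["wear_state"].isin(WEAR_STATES)
    if bad_state.any():
        rows = df.index[bad_state][:5].tolist()
        raise FormatError(
            f"{path}: unknown wear_state at rows {rows} "
            f"(allowed: {list(WEAR_STATES)})"
        )
    for col, lo, hi in (("day_of_week", 1, 7), ("minute_of_day", 0, 1439)):
        bad = (df[col] < lo) | (df[col] > hi)
        if bad.any():
            raise FormatError(
                f"{path}: {col} out of range [{lo}, {hi}] at rows "
                f"{df.index[bad][:5].tolist()}"
            )
    neg = df["activity"] < 0
    if neg.any():
        raise FormatError(
            f"{path}: negative activity at rows {df.index[neg][:5].tolist()} "
            "(use the dialect's missing sentinel instead)"
        )
    dup = df.duplicated(["participant_id", "day_index", "minute_of_day"])
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise IntegrityError(
            f"{path}: duplicate (participant_id, day_index, minute_of_day) "
            f"at rows {rows}"
        )


def read_covariates(path: os.PathLike) -> pd.DataFrame:
    """Load a covariate table, deriving the combined-cycle exam weight.

    A ``WTMEC2YR`` column (the two-year examination weight) is halved to form
    ``exam_weight`` for a pooled two-cycle analysis; an ``exam_weight``
    column is taken as-is.  Covariate levels are closed sets — an unknown
    label is a load error, never a silent extra category.  Education, income,
    work status and self-rated health may be empty (missing); missingness is
    handled by the exclusion cascade, not here.
    """
    path = Path(path)
    df = _read_table(path)
    _require_columns(df, ["participant_id"], path)
    out = pd.DataFrame({"participant_id": df["participant_id"].astype(np.int64)})
    if out["participant_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate participant_id")
    for col, levels in COVARIATE_LEVELS.items():
        _require_columns(df, [col], path)
        vals = df[col].where(df[col].notna() & (df[col].astype(str).str.len() > 0))
        known = vals.isna() | vals.isin(levels)
        if not known.all():
            bad = sorted(set(vals[~known].astype(str)))
            raise FormatError(f"{path}: unknown {col} label(s) {bad}")
        required = col in ("age_group", "gender", "race_ethnicity")
        if required and vals.isna().any():
            raise FormatError(f"{path}: {col} may not be missing")
        out[col] = vals
    if "self_rated_health" in df.columns:
        h = df["self_rated_health"].where(
            df["self_rated_health"].notna()
            & (df["self_rated_health"].astype(str).str.len() > 0)
        )
        known = h.isna() | h.isin(HEALTH_LEVELS)
        if not known.all():
            raise FormatError(
                f"{path}: unknown self_rated_health label(s) "
                f"{sorted(set(h[~known].astype(str)))}"
            )
        out["self_rated_health"] = h
    else:
        out["self_rated_health"] = pd.Series(pd.NA, index=out.index, dtype=object)
    if "exam_weight" in df.columns:
        out["exam_weight"] = df["exam_weight"].astype(float)
    elif "WTMEC2YR" in df.columns:
        out["exam_weight"] = df["WTMEC2YR"].astype(float) / 2.0
    else:
        raise FormatError(f"{path}: need an exam_weight or WTMEC2YR column")
    bad_w = ~(out["exam_weight"] > 0) | ~np.isfinite(out["exam_weight"])
    if bad_w.any():
        raise IntegrityError(
            f"{path}: nonpositive or non-finite exam_weight at rows "
            f"{out.index[bad_w][:5].tolist()}"
        )
    return out


def health_outcome(covariates: pd.DataFrame) -> pd.Series:
    """Dichotomize self-rated health: fair/poor -> 1, else 0, missing -> NaN."""
    h = covariates["self_rated_health"]
    out = pd.Series(np.nan, index=covariates.index)
    out[h.isin(POOR_FAIR)] = 1.0
    out[h.isin([x for x in HEALTH_LEVELS if x not in POOR_FAIR])] = 0.0
    return out


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    # round_trip parsing so 17-significant-digit CSVs reproduce doubles bitwise
    return pd.read_csv(path, float_precision="round_trip")


def write_results(tables: dict[str, pd.DataFrame], out_dir: os.PathLike) -> list[Path]:
    """Write result tables as CSV with full-precision floats.

    Floats are written with 17 significant digits so a write/read round trip
    reproduces the numeric values bitwise.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=table.index.name is not None, float_format="%.17g")
        written.append(p)
    return written


def write_minute_records(records: pd.DataFrame, path: os.PathLike) -> None:
    """Write a minute-record table in the synthetic dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        records[MINUTE_COLUMNS].to_parquet(path, index=False)
    else:
        records[MINUTE_COLUMNS].to_csv(path, index=False, float_format="%.17g")
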