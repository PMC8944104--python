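"""Minute records -> per-participant 288-epoch mean profiles and exclusions.

Averaging is two-stage: each day contributes its within-day 5-minute mean
over valid minutes, and the epoch mean is the unweighted mean over the days
that contributed.  With complete data this equals pooling all minutes; with
partial wear it keeps every day's influence equal.  Minutes flagged non-wear
or invalid, and minutes with a missing activity value, never enter a mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fpca import N_EPOCHS
from .io import AGE_GROUP_LOWER, VALID_WEAR_STATES

STRATA = ("overall", "weekday", "weekend")


def classify_day(day_of_week: int) -> str:
    """Map a 1=Sunday..7=Saturday code to 'weekday' or 'weekend'."""
    if day_of_week in (1, 7):
        return "weekend"
    if 2 <= day_of_week <= 6:
        return "weekday"
    raise ConfigurationError(f"day_of_week must be 1..7, got {day_of_week!r}")


@dataclass
class ProfileSet:
    """Epoch-mean profiles for one stratum.

    ``means`` is participants x 288 with NaN where no day contributed;
    ``days`` holds the per-epoch contributing-day counts (0 exactly where the
    mean is NaN).
    """

    stratum: str
    means: pd.DataFrame
    days: pd.DataFrame

    def complete(self) -> pd.Series:
        """Boolean per participant: no missing epoch in this stratum."""
        return self.means.notna().all(axis=1)

    def has_data(self) -> pd.Series:
        """Boolean per participant: at least one valid epoch."""
        return self.means.notna().any(axis=1)


def epoch_means(records: pd.DataFrame, stratum: str = "overall") -> ProfileSet:
    """Per-participant 5-min epoch means across the stratum's days.

    Row order of the input never affects the result.  Participants present in
    ``records`` but without a single valid minute in the stratum get an
    all-missing profile (they flow to the exclusion cascade, not an error).
    """
    if stratum not in STRATA:
        raise ConfigurationError(f"stratum must be one of {STRATA}")
    all_ids = np.sort(records["participant_id"].unique())
    valid = (
        records["wear_state"].isin(VALID_WEAR_STATES)
        & records["activity"].notna()
    )
    df = records.loc[valid, ["participant_id", "day_index", "day_of_week",
                             "minute_of_day", "activity"]]
    if stratum == "weekday":
        df = df[df["day_of_week"].between(2, 6)]
    elif stratum == "weekend":
        df = df[df["day_of_week"].isin([1, 7])]
    epoch = df["minute_of_day"] // 5
    day_level = (
        df.assign(epoch=epoch)
        .groupby(["participant_id", "day_index", "epoch"], sort=True)["activity"]
        .mean()
    )
    across = day_level.groupby(["participant_id", "epoch"]).agg(["mean", "size"])
    means = across["mean"].unstack("epoch")
    days = across["size"].unstack("epoch")
    means = means.reindex(index=all_ids, columns=range(N_EPOCHS))
    days = days.reindex(index=all_ids, columns=range(N_EPOCHS)).fillna(0).astype(np.int64)
    means.index.name = days.index.name = "participant_id"
    return ProfileSet(stratum, means, days)


#: exclusion rules in the order they are applied
EXCLUSION_RULES = (
    "age_below_floor",
    "missing_education",
    "missing_income",
    "missing_work_status",
    "no_actigraphy",
    "incomplete_epoch_profile",
)


@dataclass
class AnalysisSet:
    """Outcome of the exclusion cascade for one analysis."""

    strata: tuple[str, ...]
    retained_ids: np.ndarray
    exclusion_log: dict[str, int] = field(default_factory=dict)
    n_input: int = 0

    @property
    def n_retained(self) -> int:
        return self.retained_ids.size

    def log_table(self) -> pd.DataFrame:
        rows = [{"rule": r, "excluded": self.exclusion_log[r]} for r in EXCLUSION_RULES]
        rows.append({"rule": "retained", "excluded": self.n_retained})
        return pd.DataFrame(rows)


def apply_exclusions(
    profiles: Mapping[str, ProfileSet] | ProfileSet,
    covariates: pd.DataFrame,
    age_floor: int = 25,
) -> AnalysisSet:
    """Apply the exclusion cascade in its documented order.

    1. age below the floor;
    2. missing education, then income, then work status;
    3. no actigraphy (no valid epoch in any requested stratum, or absent
       from the records entirely);
    4. an incomplete epoch profile in any requested stratum (a stratified
       analysis needs every requested stratum complete).

    Rules are sequential and mutually exclusive; the logged counts sum to
    input minus retained.
    """
    if isinstance(profiles, ProfileSet):
        profiles = {profiles.stratum: profiles}
    strata = tuple(profiles)
    cov = covariates.set_index("participant_id")
    alive = pd.Series(True, index=cov.index)
    log: dict[str, int] = {}

    age_lower = cov["age_group"].map(AGE_GROUP_LOWER)
    drop = alive & (age_lower < age_floor)
    log["age_below_floor"] = int(drop.sum())
    alive &= ~drop

    for rule, col in (
        ("missing_education", "education"),
        ("missing_income", "income"),
        ("missing_work_status", "work_status"),
    ):
        drop = alive & cov[col].isna()
        log[rule] = int(drop.sum())
        alive &= ~drop

    has_any = pd.Series(False, index=cov.index)
    complete_all = pd.Series(True, index=cov.index)
    for ps in profiles.values():
        has_any |= ps.has_data().reindex(cov.index, fill_value=False)
        complete_all &= ps.complete().reindex(cov.index, fill_value=False)

    drop = alive & ~has_any
    log["no_actigraphy"] = int(drop.sum())
    alive &= ~drop

    drop = alive & ~complete_all
    log["incomplete_epoch_profile"] = int(drop.sum())
    alive &= ~drop

    return AnalysisSet(
        strata=strata,
        retained_ids=np.asarray(alive.index[alive]),
        exclusion_log=log,
        n_input=len(cov),
    )
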