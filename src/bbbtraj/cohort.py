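"""Tidy cohort container shared by every pipeline stage.

A cohort is one row per animal: identifier, experimental group
(``sham`` / ``injured``), ``sex`` (``male`` / ``female``), a timepoint
label, and an arbitrary set of numeric feature columns in which missing
values are allowed (NaN in memory, empty field on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ["animal_id", "group", "sex", "timepoint"]
GROUPS = ("sham", "injured")
SEXES = ("male", "female")

#: canonical study design: hours post-injury for each timepoint label
DEFAULT_TIMEPOINTS = {"1h": 1.0, "6h": 6.0, "1d": 24.0, "3d": 72.0, "7d": 168.0}


class CohortError(ValueError):
    """Raised when a cohort table violates its structural contract."""


@dataclass
class CohortTable:
    """Per-animal records plus the ordered feature and timepoint axes.

    Parameters
    ----------
    df
        Tidy frame with the metadata columns ``animal_id, group, sex,
        timepoint`` followed by numeric feature columns.
    timepoint_order
        Timepoint labels in chronological order.  Every record's
        timepoint must be one of these.
    timepoint_hours
        Optional label -> hours mapping so that decay fitting and
        trajectory ordering are unambiguous.
    """

    df: pd.DataFrame
    timepoint_order: list[str]
    timepoint_hours: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoint_order = list(self.timepoint_order)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def n_animals(self) -> int:
        return len(self.df)

    def features_frame(self) -> pd.DataFrame:
        """Feature columns only, indexed by animal_id."""
        return self.df.set_index("animal_id")[self.feature_names]

    def validate(self) -> None:
        missing_meta = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing_meta:
            raise CohortError(f"missing metadata columns: {missing_meta}")
        if self.df["animal_id"].duplicated().any():
            dup = self.df.loc[self.df["animal_id"].duplicated(), "animal_id"]
            raise CohortError(f"duplicate animal ids: {sorted(set(dup))}")
        bad_group = set(self.df["group"]) - set(GROUPS)
        if bad_group:
            raise CohortError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(self.df["sex"]) - set(SEXES)
        if bad_sex:
            raise CohortError(f"unknown sex labels: {sorted(bad_sex)}")
        bad_tp = set(self.df["timepoint"]) - set(self.timepoint_order)
        if bad_tp:
            raise CohortError(f"timepoints outside declared order: {sorted(bad_tp)}")
        feats = self.feature_names
        if feats:
            vals = self.df[feats].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise CohortError("non-finite feature values (inf) present")

    # ------------------------------------------------------------------
    def copy(self) -> "CohortTable":
        return CohortTable(
            self.df.copy(), list(self.timepoint_order), dict(self.timepoint_hours)
        )

    def with_features(self, feature_df: pd.DataFrame) -> "CohortTable":
        """Rebuild the table with replacement feature columns (same rows)."""
        out = pd.concat(
            [self.df[META_COLUMNS].reset_index(drop=True),
             feature_df.reset_index(drop=True)],
            axis=1,
        )
        return CohortTable(out, list(self.timepoint_order), dict(self.timepoint_hours))

    def subset(self, mask: Sequence[bool] | pd.Series) -> "CohortTable":
        return CohortTable(
            self.df.loc[np.asarray(mask)].reset_index(drop=True),
            list(self.timepoint_order),
            dict(self.timepoint_hours),
        )

    def select_features(self, features: Iterable[str]) -> "CohortTable":
        features = list(features)
        absent = [f for f in features if f not in self.feature_names]
        if absent:
            raise CohortError(f"features not in table: {absent}")
        return CohortTable(
            self.df[META_COLUMNS + features].copy(),
            list(self.timepoint_order),
            dict(self.timepoint_hours),
        )

    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the tidy CSV dialect (missing values as empty fields)."""
        self.df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        timepoint_order: Sequence[str] | None = None,
        timepoint_hours: dict[str, float] | None = None,
    ) -> "CohortTable":
        df = pd.read_csv(path, dtype={"animal_id": str})
        if timepoint_order is None:
            # preserve first-appearance order; fall back to hours if known
            seen = list(dict.fromkeys(df["timepoint"]))
            hours = timepoint_hours or DEFAULT_TIMEPOINTS
            if all(tp in hours for tp in seen):
                seen.sort(key=lambda tp: hours[tp])
            timepoint_order = seen
        return cls(df, list(timepoint_order), dict(timepoint_hours or {}))

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.timepoint_order == other.timepoint_order
            and self.df.equals(other.df)
        )
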