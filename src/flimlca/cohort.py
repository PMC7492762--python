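"""Patient cohort container: covariates plus a right-censored outcome.

A :class:`Cohort` is a thin, validated wrapper around a pandas DataFrame with
the fixed columns ``patient_id``, ``time`` (days), ``event`` (1 = event,
0 = censored) and, for synthetic cohorts only, ``true_class``.  All remaining
columns are treated as covariates.  Missing covariate values are allowed and
stay missing (NaN); downstream model code decides how to impute them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Cohort", "RESERVED_COLUMNS", "CohortValidationError"]

RESERVED_COLUMNS = ("patient_id", "time", "event", "true_class")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema."""


@dataclass
class Cohort:
    table: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        df = self.table
        for col in ("patient_id", "time", "event"):
            if col not in df.columns:
                raise CohortValidationError(f"missing mandatory column '{col}'")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise CohortValidationError(f"duplicate column names: {dupes}")
        t = pd.to_numeric(df["time"], errors="coerce")
        if t.isna().any():
            bad = df.index[t.isna()].tolist()[:5]
            raise CohortValidationError(f"non-numeric or missing 'time' at rows {bad}")
        if (t <= 0).any():
            raise CohortValidationError("'time' must be positive")
        e = pd.to_numeric(df["event"], errors="coerce")
        if e.isna().any() or not np.isin(e.dropna().unique(), [0, 1]).all():
            raise CohortValidationError("'event' must be 0 or 1 with no missing values")
        self.table = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def patient_id(self) -> np.ndarray:
        return self.table["patient_id"].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def true_class(self) -> np.ndarray | None:
        if "true_class" not in self.table.columns:
            return None
        return self.table["true_class"].to_numpy()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in RESERVED_COLUMNS]

    def covariates(self, names: list[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else self.covariate_names
        missing = [n for n in names if n not in self.table.columns]
        if missing:
            raise CohortValidationError(f"unknown covariate columns: {missing}")
        return self.table[names].apply(pd.to_numeric, errors="coerce")

    def with_columns(self, extra: pd.DataFrame) -> "Cohort":
        """Return a new cohort with additional covariate columns merged on patient_id."""
        merged = self.table.merge(extra, on="patient_id", how="left")
        return Cohort(merged, name=self.name)
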