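"""Subject-level survival data container."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "CAUSE_CANCER", "CAUSE_OTHER", "CAUSE_NONE"]

CAUSE_CANCER = "cancer"
CAUSE_OTHER = "other"
CAUSE_NONE = "none"


@dataclass
class SurvivalDataset:
    """Per-subject follow-up records.

    Wraps a :class:`pandas.DataFrame` with declared column roles:

    - ``time_col``: follow-up time in years, finite and > 0 (times of exactly
      zero are shifted to half the smallest positive time, with a warning);
    - ``status_col``: all-cause event indicator, 0/1;
    - ``cause_col``: optional true cause of death, one of ``"cancer"``,
      ``"other"`` for deaths and ``"none"`` for censored records;
    - ``covariate_cols``: model covariates;
    - ``age_col`` / ``diagnosis_date_col`` / ``strata_cols``: demographic keys
      used to look a subject up in a population rate table.
    """

    df: pd.DataFrame
    time_col: str = "time"
    status_col: str = "status"
    cause_col: str | None = None
    covariate_cols: Sequence[str] = ()
    age_col: str | None = None
    diagnosis_date_col: str | None = None
    strata_cols: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for col in self._declared_columns():
            if col not in df.columns:
                raise KeyError(f"declared column {col!r} not found in the data")
        t = df[self.time_col].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("follow-up times must be finite and >= 0")
        if (t == 0).any():
            pos = t[t > 0]
            if pos.size == 0:
                raise ValueError("all follow-up times are zero")
            shift = 0.5 * pos.min()
            warnings.warn(
                f"{int((t == 0).sum())} follow-up time(s) of exactly 0 shifted to {shift:g}",
                stacklevel=2,
            )
            t = np.where(t == 0, shift, t)
            df = df.copy()
            df[self.time_col] = t
        d = df[self.status_col].to_numpy()
        if not np.isin(d, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if self.cause_col is not None:
            cause = df[self.cause_col].to_numpy()
            ok = np.where(
                d.astype(int) == 1,
                np.isin(cause, (CAUSE_CANCER, CAUSE_OTHER)),
                np.isin(cause, (CAUSE_NONE,)),
            )
            if not ok.all():
                i = int(np.argmin(ok))
                raise ValueError(
                    f"row {i}: cause {cause[i]!r} inconsistent with status {d[i]} "
                    f"(deaths need 'cancer'/'other', censored records 'none')"
                )
        self.df = df

    def _declared_columns(self):
        cols = [self.time_col, self.status_col]
        if self.cause_col:
            cols.append(self.cause_col)
        cols += list(self.covariate_cols)
        if self.age_col:
            cols.append(self.age_col)
        if self.diagnosis_date_col:
            cols.append(self.diagnosis_date_col)
        cols += list(self.strata_cols.values())
        return cols

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def time(self) -> np.ndarray:
        return self.df[self.time_col].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.df[self.status_col].to_numpy(dtype=int)

    @property
    def cause(self) -> np.ndarray:
        if self.cause_col is None:
            raise ValueError("dataset has no cause-of-death column")
        return self.df[self.cause_col].to_numpy()

    @property
    def n_deaths(self) -> int:
        return int(self.status.sum())

    def subset(self, indices) -> "SurvivalDataset":
        """New dataset from (possibly repeated) row indices, e.g. a bootstrap resample."""
        return replace(self, df=self.df.iloc[np.asarray(indices)].reset_index(drop=True))

    def with_times(self, times) -> "SurvivalDataset":
        df = self.df.copy()
        df[self.time_col] = np.asarray(times, dtype=float)
        return replace(self, df=df)

    def expected_hazard_at_exit(self, rate_table) -> np.ndarray:
        """lambda_P for every subject at their own follow-up time (vectorised)."""
        if self.age_col is None or self.diagnosis_date_col is None:
            raise ValueError("dataset lacks age/diagnosis-date columns for rate-table lookup")
        sidx = rate_table.strata_indices_frame(self.df, self.strata_cols or None)
        age = self.df[self.age_col].to_numpy(dtype=float) + self.time
        period = self.df[self.diagnosis_date_col].to_numpy(dtype=float) + self.time
        return rate_table.rate_at(age, period, sidx)
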