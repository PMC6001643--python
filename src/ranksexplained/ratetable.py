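"""Population life tables: expected (background) mortality lookup.

A :class:`RateTable` is a dense grid of expected mortality hazards
``lambda_P`` indexed by attained age, calendar period and any number of
categorical strata (sex, deprivation, ...).  Cells are left-closed and
right-open, ``[a, a + w)``; a subject diagnosed at age ``a0`` in calendar
year ``p0`` experiences, at follow-up time ``t`` (years), the rate of the
cell containing attained age ``a0 + t`` and period ``p0 + t``.  Beyond the
final break on either axis the last cell's rate is carried forward (with a
logged warning) so that analyses extending past the table never abort.

The internal canonical unit is hazard per person-year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RateTable",
    "DemographicProfile",
    "load_rate_table",
    "expected_hazard_at",
    "expected_cumulative_hazard",
]


@dataclass(frozen=True)
class DemographicProfile:
    """Demographic keys linking a subject to a life table.

    ``age_at_diagnosis`` in (possibly fractional) years, ``diagnosis_date``
    as a fractional calendar year (e.g. ``2000.5`` for mid-2000), and the
    stratum values for every strata axis of the referenced table.
    """

    age_at_diagnosis: float
    diagnosis_date: float
    strata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.age_at_diagnosis) and self.age_at_diagnosis >= 0):
            raise ValueError(f"age_at_diagnosis must be finite and >= 0, got {self.age_at_diagnosis}")
        if not np.isfinite(self.diagnosis_date):
            raise ValueError("diagnosis_date must be finite")


def _cell_widths(breaks: np.ndarray) -> np.ndarray:
    if breaks.size == 1:
        return np.array([1.0])
    w = np.diff(breaks)
    return np.append(w, w[-1])


class RateTable:
    """Gridded expected-mortality hazards (per person-year).

    Parameters
    ----------
    age_breaks, period_breaks
        Ascending left edges of the age and calendar-period cells (years).
    strata_levels
        Mapping from strata axis name to its ordered levels.
    rates
        Array of shape ``(n_age, n_period, *[len(levels) per stratum])``,
        hazards per person-year, all finite and >= 0.
    """

    def __init__(
        self,
        age_breaks: Sequence[float],
        period_breaks: Sequence[float],
        strata_levels: Mapping[str, Sequence[Any]],
        rates: np.ndarray,
    ) -> None:
        self.age_breaks = np.asarray(age_breaks, dtype=float)
        self.period_breaks = np.asarray(period_breaks, dtype=float)
        for name, br in (("age", self.age_breaks), ("period", self.period_breaks)):
            if br.size == 0 or np.any(np.diff(br) <= 0):
                raise ValueError(f"{name}_breaks must be non-empty and strictly increasing")
        self.strata_levels = {k: list(v) for k, v in strata_levels.items()}
        self.strata_keys = tuple(self.strata_levels)
        shape = (self.age_breaks.size, self.period_breaks.size) + tuple(
            len(v) for v in self.strata_levels.values()
        )
        rates = np.asarray(rates, dtype=float)
        if rates.shape != shape:
            raise ValueError(f"rates shape {rates.shape} does not match grid shape {shape}")
        if not np.isfinite(rates).all() or (rates < 0).any():
            raise ValueError("all rates must be finite and >= 0")
        self.rates = rates
        self._age_widths = _cell_widths(self.age_breaks)
        self._period_widths = _cell_widths(self.period_breaks)
        self._level_index = {
            k: {lvl: i for i, lvl in enumerate(v)} for k, v in self.strata_levels.items()
        }

    # -- strata handling ---------------------------------------------------

    def stratum_index(self, strata: Mapping[str, Any]) -> tuple[int, ...]:
        """Axis indices for one stratum combination; unknown level -> error."""
        idx = []
        for key in self.strata_keys:
            if key not in strata:
                raise KeyError(f"profile is missing stratum {key!r} required by the rate table")
            try:
                idx.append(self._level_index[key][strata[key]])
            except KeyError:
                raise KeyError(
                    f"stratum {key}={strata[key]!r} not present in the rate table "
                    f"(levels: {self.strata_levels[key]})"
                ) from None
        return tuple(idx)

    def strata_indices_frame(self, df: pd.DataFrame, columns: Mapping[str, str] | None = None):
        """Vectorised stratum indices for a DataFrame (one tuple-column per axis)."""
        columns = columns or {k: k for k in self.strata_keys}
        out = []
        for key in self.strata_keys:
            col = df[columns[key]]
            mapping = self._level_index[key]
            vals = col.map(mapping)
            if vals.isna().any():
                bad = col[vals.isna()].iloc[0]
                raise KeyError(f"stratum {key}={bad!r} not present in the rate table")
            out.append(vals.to_numpy(dtype=np.intp))
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (one row per grid cell), loadable by load_rate_table."""
        import itertools

        rows = []
        axes = [self.age_breaks, self.period_breaks] + list(self.strata_levels.values())
        for combo in itertools.product(*(range(len(a)) for a in axes)):
            row = {"age": self.age_breaks[combo[0]], "period": self.period_breaks[combo[1]]}
            for key, k in zip(self.strata_keys, combo[2:]):
                row[key] = self.strata_levels[key][k]
            row["rate"] = self.rates[combo]
            rows.append(row)
        return pd.DataFrame(rows)

    # -- lookups -----------------------------------------------------------

    def _axis_cell(self, breaks: np.ndarray, widths: np.ndarray, values: np.ndarray, label: str):
        idx = np.searchsorted(breaks, values, side="right") - 1
        n_low = int(np.sum(idx < 0))
        n_high = int(np.sum(values >= breaks[-1] + widths[-1]))
        if n_low or n_high:
            logger.warning(
                "%d %s value(s) outside the rate-table range [%g, %g); nearest cell reused",
                n_low + n_high, label, breaks[0], breaks[-1] + widths[-1],
            )
        return np.clip(idx, 0, breaks.size - 1)

    def rate_at(self, age, period, strata_idx: tuple[np.ndarray, ...] | tuple[int, ...]):
        """Hazard per person-year at attained ``age`` and calendar ``period`` (vectorised)."""
        age = np.asarray(age, dtype=float)
        period = np.asarray(period, dtype=float)
        ai = self._axis_cell(self.age_breaks, self._age_widths, age, "age")
        pi = self._axis_cell(self.period_breaks, self._period_widths, period, "period")
        return self.rates[(ai, pi) + tuple(strata_idx)]

    def expected_hazard(self, profile: DemographicProfile, t) -> np.ndarray | float:
        """lambda_P at follow-up time(s) ``t`` >= 0 for one subject."""
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("follow-up time must be >= 0")
        si = self.stratum_index(profile.strata)
        out = self.rate_at(profile.age_at_diagnosis + t, profile.diagnosis_date + t, si)
        return float(out) if out.ndim == 0 else out

    def cumulative_expected_hazard(self, profile: DemographicProfile, t: float) -> float:
        """Exact integral of the piecewise-constant hazard over ``[0, t]``.

        The subject's attained age and calendar period advance together, so
        the integrand is constant between the times at which either axis
        crosses a break; the integral is the sum of rate x segment-length
        over those segments.
        """
        t = float(t)
        if t < 0:
            raise ValueError("follow-up time must be >= 0")
        if t == 0.0:
            return 0.0
        cuts = np.concatenate([
            self.age_breaks - profile.age_at_diagnosis,
            self.period_breaks - profile.diagnosis_date,
        ])
        cuts = np.unique(cuts[(cuts > 0) & (cuts < t)])
        edges = np.concatenate([[0.0], cuts, [t]])
        mids = 0.5 * (edges[:-1] + edges[1:])
        si = self.stratum_index(profile.strata)
        rates = self.rate_at(profile.age_at_diagnosis + mids, profile.diagnosis_date + mids, si)
        return float(np.sum(rates * np.diff(edges)))


# module-level operation aliases ------------------------------------------------

def expected_hazard_at(rt: RateTable, profile: DemographicProfile, t):
    """Expected hazard (per person-year) for ``profile`` at follow-up time ``t``."""
    return rt.expected_hazard(profile, t)


def expected_cumulative_hazard(rt: RateTable, profile: DemographicProfile, t: float) -> float:
    """Cumulative expected hazard (dimensionless) for ``profile`` over ``[0, t]``."""
    return rt.cumulative_expected_hazard(profile, t)


# loader ------------------------------------------------------------------------

_VALID_UNITS = ("per-year", "per-month", "probability")


def load_rate_table(
    path,
    axis_spec: Mapping[str, Any],
    rate_units: str = "per-year",
    sep: str | None = None,
) -> RateTable:
    """Load a long-format life table (one row per grid cell).

    Parameters
    ----------
    path
        Delimited text file with a header row.
    axis_spec
        Column mapping with keys ``"age"``, ``"period"``, ``"rate"`` and
        ``"strata"`` (a list of stratifier columns, possibly empty), e.g.
        ``{"age": "age", "period": "year", "strata": ["sex", "dep"], "rate": "rate"}``.
    rate_units
        ``"per-year"`` (stored as-is), ``"per-month"`` (multiplied by 12) or
        ``"probability"`` (annualised via ``-ln(1 - q) / width`` with the age
        cell width in years).
    sep
        Field separator; autodetected (comma or tab) when ``None``.
    """
    if rate_units not in _VALID_UNITS:
        raise ValueError(f"rate_units must be one of {_VALID_UNITS}, got {rate_units!r}")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    age_col, period_col, rate_col = axis_spec["age"], axis_spec["period"], axis_spec["rate"]
    strata_cols = list(axis_spec.get("strata", []))
    for col in [age_col, period_col, rate_col, *strata_cols]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path} (have {list(df.columns)})")

    age_breaks = np.unique(df[age_col].to_numpy(dtype=float))
    period_breaks = np.unique(df[period_col].to_numpy(dtype=float))
    strata_levels = {c: sorted(pd.unique(df[c]).tolist()) for c in strata_cols}

    key_cols = [age_col, period_col, *strata_cols]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].to_dict()
        raise ValueError(f"duplicated rate-table cell: {first}")
    n_expected = age_breaks.size * period_breaks.size * int(
        np.prod([len(v) for v in strata_levels.values()]) if strata_cols else 1
    )
    if len(df) != n_expected:
        have = set(map(tuple, df[key_cols].itertuples(index=False)))
        import itertools

        for combo in itertools.product(
            age_breaks, period_breaks, *[strata_levels[c] for c in strata_cols]
        ):
            if combo not in have:
                missing = dict(zip(key_cols, combo))
                raise ValueError(f"missing rate-table cell: {missing}")

    values = df[rate_col].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("rate column contains non-finite values")
    if (values < 0).any():
        bad = df.loc[values < 0, key_cols].iloc[0].to_dict()
        raise ValueError(f"negative rate at cell {bad}")

    widths = _cell_widths(age_breaks)
    if rate_units == "probability":
        if (values >= 1).any():
            raise ValueError("death probabilities must lie in [0, 1)")
        wi = widths[np.searchsorted(age_breaks, df[age_col].to_numpy(dtype=float))]
        values = -np.log1p(-values) / wi
    elif rate_units == "per-month":
        values = values * 12.0

    shape = (age_breaks.size, period_breaks.size) + tuple(len(strata_levels[c]) for c in strata_cols)
    rates = np.empty(shape)
    ai = np.searchsorted(age_breaks, df[age_col].to_numpy(dtype=float))
    pi = np.searchsorted(period_breaks, df[period_col].to_numpy(dtype=float))
    sidx = tuple(
        df[c].map({lvl: i for i, lvl in enumerate(strata_levels[c])}).to_numpy(dtype=np.intp)
        for c in strata_cols
    )
    rates[(ai, pi) + sidx] = values
    return RateTable(age_breaks, period_breaks, strata_levels, rates)


def hazard_to_probability(rate, width=1.0):
    """Inverse of the probability -> hazard conversion (for round-trip checks)."""
    return -np.expm1(-np.asarray(rate, dtype=float) * width)
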