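"""Domain types shared by every stage of the pipeline.

The study system is a set of spatial units (census blocks or districts) with
annual mean pollutant concentrations, a network of fixed monitoring stations
with daily concentration series, a row-stochastic residential-mobility matrix
with a reserved "outside the study area" category, and an annual exposure
series for that outside area.

Concentrations are µg/m³ throughout; coordinates are planar meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Reserved identifier for the area outside the study area.
OUTSIDE_LABEL = "__OUTSIDE__"

#: Recognised monitoring-station typologies.
STATION_TYPES = frozenset({"urban", "peri-urban", "traffic"})

#: Default minimum fraction of observed days required for an annual mean.
DEFAULT_MIN_COMPLETENESS = 0.75


@dataclass(frozen=True)
class SpatialUnit:
    """A spatial unit (census block / district) of the study area."""

    unit_id: str
    x: float
    y: float
    population: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"unit {self.unit_id!r}: coordinates must be finite"
            )
        if not (math.isfinite(self.population) and self.population >= 0):
            raise ValidationError(
                f"unit {self.unit_id!r}: population must be a non-negative count"
            )


@dataclass(frozen=True)
class MonitorStation:
    """A fixed air-quality monitoring station."""

    station_id: str
    type: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.type not in STATION_TYPES:
            raise ValidationError(
                f"station {self.station_id!r}: type {self.type!r} not one of "
                f"{sorted(STATION_TYPES)}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"station {self.station_id!r}: coordinates must be finite"
            )


@dataclass
class StudyArea:
    """The collection of spatial units plus the reserved outside label."""

    units: list[SpatialUnit]
    outside_label: str = OUTSIDE_LABEL

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise ValidationError("study area must contain at least one unit")
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate unit ids: {dupes}")
        if self.outside_label in ids:
            raise ValidationError(
                f"outside label {self.outside_label!r} collides with a unit id"
            )

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def frame(self) -> pd.DataFrame:
        """Units as a DataFrame indexed by unit_id."""
        return pd.DataFrame(
            {
                "x": [u.x for u in self.units],
                "y": [u.y for u in self.units],
                "population": [u.population for u in self.units],
            },
            index=pd.Index(self.unit_ids, name="unit_id"),
        )


def _check_contiguous_years(years: pd.Index) -> None:
    yrs = np.asarray(years, dtype=int)
    if len(yrs) and not np.array_equal(yrs, np.arange(yrs[0], yrs[-1] + 1)):
        raise ValidationError(f"years must form a contiguous range, got {list(yrs)}")


@dataclass
class AnnualConcentrationField:
    """Unit × year grid of annual mean concentrations (µg/m³).

    Missing cells are explicit NaN, never silent zeros. Stored values must be
    strictly positive and finite.
    """

    values: pd.DataFrame  # index: unit_id, columns: contiguous int years

    def __post_init__(self) -> None:
        df = self.values
        df.columns = df.columns.astype(int)
        df = df.sort_index(axis=1)
        _check_contiguous_years(df.columns)
        arr = df.to_numpy(dtype=float)
        bad = ~np.isnan(arr) & ~((arr > 0) & np.isfinite(arr))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"annual field: non-positive or non-finite value "
                f"{arr[i, j]!r} at unit {df.index[i]!r}, year {df.columns[j]}"
            )
        self.values = df

    @property
    def units(self) -> list[str]:
        return list(self.values.index)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.values.columns]

    def value(self, unit_id: str, year: int) -> float:
        """Single cell; NaN if flagged missing."""
        return float(self.values.at[unit_id, int(year)])

    def series(self, unit_id: str) -> pd.Series:
        return self.values.loc[unit_id]


@dataclass
class OutsideExposureSeries:
    """Annual mean exposure (µg/m³) for the area outside the study area."""

    values: pd.Series  # index: int year

    def __post_init__(self) -> None:
        s = self.values.copy()
        s.index = s.index.astype(int)
        s = s.sort_index()
        arr = s.to_numpy(dtype=float)
        bad = ~np.isnan(arr) & ~((arr > 0) & np.isfinite(arr))
        if bad.any():
            yr = s.index[int(np.argwhere(bad)[0][0])]
            raise ValidationError(f"outside series: non-positive value in year {yr}")
        self.values = s

    def value(self, year: int) -> float:
        if int(year) not in self.values.index:
            return float("nan")
        return float(self.values.loc[int(year)])


@dataclass
class DailyMonitorSeries:
    """Daily concentration series of one monitoring station.

    ``observations`` is indexed by date (strictly increasing); values are
    strictly positive µg/m³. Days without a measurement are simply absent.
    """

    station_id: str
    observations: pd.Series

    def __post_init__(self) -> None:
        s = self.observations
        if not isinstance(s.index, pd.DatetimeIndex):
            s = s.copy()
            s.index = pd.DatetimeIndex(s.index)
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValidationError(
                f"station {self.station_id!r}: dates must be strictly increasing"
            )
        arr = s.to_numpy(dtype=float)
        ok = (arr > 0) & np.isfinite(arr)
        if not ok.all():
            d = s.index[int(np.argmax(~ok))].date()
            raise ValidationError(
                f"station {self.station_id!r}: non-positive concentration on {d}"
            )
        self.observations = s

    def completeness(self) -> pd.Series:
        """Fraction of days observed, per calendar year."""
        counts = self.observations.groupby(self.observations.index.year).size()
        years = counts.index.astype(int)
        ndays = pd.Series(
            [366 if pd.Timestamp(year=y, month=1, day=1).is_leap_year else 365
             for y in years],
            index=years,
        )
        return (counts / ndays).rename("completeness")

    def annualize(
        self, min_completeness: float = DEFAULT_MIN_COMPLETENESS
    ) -> pd.Series:
        """Annual mean over observed days, NaN where completeness is below
        ``min_completeness``. Missingness is a flagged state, not an error."""
        return annualize(self, min_completeness)


def annualize(
    series: DailyMonitorSeries,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
) -> pd.Series:
    """Annualize a daily monitor series.

    Parameters
    ----------
    series:
        The daily series.
    min_completeness:
        Minimum fraction (in ``(0, 1]``) of calendar days that must be
        observed for a year's mean to be reported; years below the threshold
        are flagged NaN.

    Returns
    -------
    pandas.Series
        Annual means indexed by year, NaN where flagged missing.
    """
    if not (0 < min_completeness <= 1):
        raise ValidationError(
            f"min_completeness must be in (0, 1], got {min_completeness}"
        )
    obs = series.observations
    if obs.empty:
        return pd.Series(dtype=float, name=series.station_id)
    means = obs.groupby(obs.index.year).mean()
    comp = series.completeness()
    means = means.where(comp >= min_completeness)
    means.index = means.index.astype(int)
    return means.rename(series.station_id)


@dataclass
class MobilityMatrix:
    """Residential-mobility transition probabilities for one census period.

    Rows are indexed by *destination* (current residence); columns by
    *origin* (residence one census period of ``period_years`` earlier), so
    cell ``(N, i)`` is P(lived in i one period ago | lives in N now). The
    column set is the unit ids, optionally plus the reserved outside label.
    Every row sums to one.
    """

    probabilities: pd.DataFrame
    period_years: int = 1
    outside_label: str = OUTSIDE_LABEL

    def __post_init__(self) -> None:
        if self.period_years <= 0:
            raise ValidationError("period_years must be a positive integer")
        df = self.probabilities.astype(float)
        arr = df.to_numpy()
        if ((arr < 0) | (arr > 1) | ~np.isfinite(arr)).any():
            raise ValidationError("mobility probabilities must lie in [0, 1]")
        sums = arr.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-9
        if off.any():
            dest = df.index[int(np.argmax(off))]
            raise ValidationError(
                f"mobility row for destination {dest!r} sums to "
                f"{sums[int(np.argmax(off))]:.9f}, expected 1"
            )
        missing = [u for u in df.index if u not in df.columns]
        if missing:
            # a unit that never appears as an origin gets an explicit zero
            # column so the diagonal (sedentary probability) is well defined
            df = df.copy()
            for u in missing:
                df[u] = 0.0
            inner = sorted(c for c in df.columns if c != self.outside_label)
            if self.outside_label in df.columns:
                inner.append(self.outside_label)
            df = df[inner]
        self.probabilities = df

    @property
    def unit_ids(self) -> list[str]:
        return list(self.probabilities.index)

    @property
    def has_outside(self) -> bool:
        return self.outside_label in self.probabilities.columns

    def outside_mass(self) -> pd.Series:
        """Per-destination probability of having lived outside the area."""
        if not self.has_outside:
            return pd.Series(0.0, index=self.probabilities.index)
        return self.probabilities[self.outside_label]

    def degree_of_mobility(self) -> pd.Series:
        """Percentage of current residents who lived elsewhere one period
        earlier: ``100 * (1 - P_NN)`` per destination unit."""
        diag = pd.Series(
            np.diag(self.probabilities[self.probabilities.index].to_numpy()),
            index=self.probabilities.index,
        )
        return (100.0 * (1.0 - diag)).rename("degree_of_mobility")

    @classmethod
    def identity(
        cls, unit_ids: list[str], period_years: int = 1
    ) -> "MobilityMatrix":
        """Fully sedentary matrix: everyone lived where they live now."""
        eye = pd.DataFrame(
            np.eye(len(unit_ids)), index=list(unit_ids), columns=list(unit_ids)
        )
        eye.index.name = "dest_id"
        return cls(probabilities=eye, period_years=period_years)


@dataclass(frozen=True)
class LatencyWindow:
    """Latency window: reference year j and maximum lag Lmax (years)."""

    reference_year: int
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValidationError("max_lag must be non-negative")

    @property
    def years(self) -> list[int]:
        """Years j - Lmax ... j covered by the window."""
        return list(range(self.reference_year - self.max_lag, self.reference_year + 1))


@dataclass
class StudyBundle:
    """A validated set of study inputs, the unit every stage consumes."""

    area: StudyArea
    field: AnnualConcentrationField
    stations: list[MonitorStation]
    daily: dict[str, DailyMonitorSeries] = field(default_factory=dict)
    mobility: MobilityMatrix | None = None
    outside: OutsideExposureSeries | None = None

    @property
    def station_ids(self) -> list[str]:
        return [s.station_id for s in self.stations]
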