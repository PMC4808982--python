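"""Synthetic study-area generator.

Emulates the data regime the exposure framework assumes: a city whose annual
pollutant surface decomposes into a handful of temporal-trend clusters
(multiplicative log-linear trends), units that sit at fixed multiplicative
offsets from their cluster level (high between-unit, low within-unit
variability), monitoring stations whose daily series share their cluster's
annual level modulated by a seasonal cycle and lognormal daily noise, and a
row-stochastic residential-mobility matrix with an absorbing outside-area
category whose off-diagonal mass decays with distance between unit centroids.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
spec, so a given seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from . import io as _io
from .types import (
    OUTSIDE_LABEL,
    AnnualConcentrationField,
    DailyMonitorSeries,
    MobilityMatrix,
    MonitorStation,
    OutsideExposureSeries,
    SpatialUnit,
    StudyArea,
    StudyBundle,
)

#: Per-cluster annual multiplicative trend factors (a factor of 0.99 is a 1 %
#: decline per year). Defaults bracket the slow city-wide NO2 decline of the
#: 2000s, with cluster-to-cluster contrast.
_DEFAULT_SLOPES = (0.990, 0.985, 0.995, 0.992, 0.988, 0.998, 0.980)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study area.

    Defaults describe a Paris-like district-level configuration: 20 units,
    9 monitors in 7 trend clusters, annual means modelled 2002-2012 with a
    hidden 1992-2001 pre-period to reconstruct, a winter-peaking seasonal
    cycle (±25 %), lognormal daily noise (sd 0.2 on the log scale), unit
    offsets with log-sd 0.12, a 5-year census mobility matrix with about
    15.5 % of residents having moved (half of movers from outside the area).
    """

    n_units: int = 20
    n_stations: int = 9
    n_clusters_true: int = 7
    years_modeled: tuple[int, int] = (2002, 2012)
    years_hidden: tuple[int, int] = (1992, 2001)
    trend_slopes: tuple[float, ...] = _DEFAULT_SLOPES
    seasonal_amplitude: float = 0.25
    daily_noise_sd: float = 0.2
    unit_level_spread: float = 0.12
    mobility_intensity: float = 0.155
    outside_fraction: float = 0.5
    period_years: int = 5
    base_level_range: tuple[float, float] = (40.0, 90.0)
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_units, self.n_stations, self.n_clusters_true) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_stations < self.n_clusters_true:
            raise ConfigurationError(
                f"n_stations={self.n_stations} < n_clusters_true="
                f"{self.n_clusters_true}: every cluster needs a station"
            )
        if not (0 <= self.mobility_intensity < 1):
            raise ConfigurationError("mobility_intensity must lie in [0, 1)")
        if not (0 <= self.outside_fraction <= 1):
            raise ConfigurationError("outside_fraction must lie in [0, 1]")
        if len(self.trend_slopes) < self.n_clusters_true:
            raise ConfigurationError(
                f"need {self.n_clusters_true} trend slopes, got "
                f"{len(self.trend_slopes)}"
            )
        if not all(np.isfinite(s) and s > 0 for s in self.trend_slopes):
            raise ConfigurationError("trend slopes must be positive and finite")
        for lo, hi in (self.years_modeled, self.years_hidden):
            if hi < lo:
                raise ConfigurationError("year ranges must be (first, last)")
        if self.daily_noise_sd < 0 or self.seasonal_amplitude < 0:
            raise ConfigurationError("noise and amplitude must be non-negative")

    @property
    def modeled_years(self) -> list[int]:
        return list(range(self.years_modeled[0], self.years_modeled[1] + 1))

    @property
    def hidden_years(self) -> list[int]:
        return list(range(self.years_hidden[0], self.years_hidden[1] + 1))


@dataclass
class SyntheticTruth:
    """Hidden ground truth accompanying a synthetic bundle."""

    hidden_field: AnnualConcentrationField
    labels: pd.Series  # entity_id (units and stations) -> true cluster int
    cluster_levels: pd.DataFrame  # cluster × year annual level, all years
    unit_offsets: pd.Series  # unit_id -> multiplicative log offset


@dataclass
class SyntheticBundle:
    bundle: StudyBundle
    truth: SyntheticTruth
    spec: SimulationSpec = field(default_factory=SimulationSpec)


def _cluster_assignment(rng, n: int, k: int) -> np.ndarray:
    """Each of k clusters nonempty; remainder assigned uniformly."""
    base = np.arange(k)
    extra = rng.integers(0, k, size=n - k) if n > k else np.empty(0, dtype=int)
    labels = np.concatenate([base, extra])
    rng.shuffle(labels)
    return labels


def simulate_area(spec: SimulationSpec) -> SyntheticBundle:
    """Generate a full input bundle plus hidden ground truth.

    The annual field follows cluster-specific log-linear trends with fixed
    unit-level offsets; each station's daily series is its cluster's annual
    level times a seasonal cycle times lognormal daily noise; mobility rows
    are stochastic with diagonal ``1 - mobility_intensity`` (±25 % unit
    jitter) and a fraction ``outside_fraction`` of the moving mass assigned
    to the outside-area origin.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    k = spec.n_clusters_true

    unit_ids = [f"U{i:03d}" for i in range(1, spec.n_units + 1)]
    station_ids = [f"S{i:02d}" for i in range(1, spec.n_stations + 1)]

    # spatially coherent clusters: centres in a 10 km box, entities scattered
    centers = rng.uniform(1500.0, 8500.0, size=(k, 2))
    unit_lab = _cluster_assignment(rng, spec.n_units, k)
    stat_lab = _cluster_assignment(rng, spec.n_stations, k)
    unit_xy = centers[unit_lab] + rng.normal(0.0, 1200.0, size=(spec.n_units, 2))
    stat_xy = centers[stat_lab] + rng.normal(0.0, 1200.0, size=(spec.n_stations, 2))
    populations = rng.integers(800, 4000, size=spec.n_units).astype(float)

    units = [
        SpatialUnit(unit_id=u, x=float(xy[0]), y=float(xy[1]), population=float(p))
        for u, xy, p in zip(unit_ids, unit_xy, populations)
    ]
    area = StudyArea(units=units)
    types = np.array(["urban", "peri-urban", "traffic"])
    stat_type = types[rng.integers(0, 3, size=spec.n_stations)]
    stations = [
        MonitorStation(station_id=s, type=str(t), x=float(xy[0]), y=float(xy[1]))
        for s, t, xy in zip(station_ids, stat_type, stat_xy)
    ]

    # cluster annual levels over hidden + modelled years (log-linear trends)
    all_years = spec.hidden_years + spec.modeled_years
    y0 = spec.years_modeled[0]
    lo, hi = spec.base_level_range
    base = np.geomspace(lo, hi, k)
    rng.shuffle(base)
    slopes = np.log(np.asarray(spec.trend_slopes[:k], dtype=float))
    t = np.asarray(all_years, dtype=float) - y0
    log_levels = np.log(base)[:, None] + slopes[:, None] * t[None, :]
    cluster_levels = pd.DataFrame(
        np.exp(log_levels), index=pd.RangeIndex(k, name="cluster"), columns=all_years
    )

    offsets = rng.normal(0.0, spec.unit_level_spread, size=spec.n_units)
    log_field = log_levels[unit_lab, :] + offsets[:, None]
    field_all = pd.DataFrame(
        np.exp(log_field), index=pd.Index(unit_ids, name="unit_id"), columns=all_years
    )
    field = AnnualConcentrationField(values=field_all[spec.modeled_years].copy())
    hidden_field = AnnualConcentrationField(values=field_all[spec.hidden_years].copy())

    # daily station series over the modelled years
    dates = pd.date_range(
        f"{spec.years_modeled[0]}-01-01", f"{spec.years_modeled[1]}-12-31", freq="D"
    )
    doy = dates.day_of_year.to_numpy(dtype=float)
    seasonal = 1.0 + spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 15.0) / 365.25
    )
    year_pos = {y: i for i, y in enumerate(all_years)}
    date_year_idx = np.array([year_pos[y] for y in dates.year])
    daily: dict[str, DailyMonitorSeries] = {}
    for sid, lab in zip(station_ids, stat_lab):
        level = np.exp(log_levels[lab, date_year_idx])
        sd = spec.daily_noise_sd
        noise = np.exp(rng.normal(-0.5 * sd * sd, sd, size=len(dates)))
        vals = level * seasonal * noise
        daily[sid] = DailyMonitorSeries(
            station_id=sid, observations=pd.Series(vals, index=dates)
        )

    mobility = _simulate_mobility(rng, spec, unit_ids, unit_xy)

    # outside area: a constant multiplicative notch below the city geometric
    # mean (suburban background is lower than the dense core)
    outside_vals = 0.8 * np.exp(np.log(field_all.to_numpy()).mean(axis=0))
    outside = OutsideExposureSeries(
        values=pd.Series(outside_vals, index=all_years)
    )

    labels = pd.Series(
        np.concatenate([unit_lab, stat_lab]),
        index=pd.Index(unit_ids + station_ids, name="entity_id"),
        name="cluster",
    )
    truth = SyntheticTruth(
        hidden_field=hidden_field,
        labels=labels,
        cluster_levels=cluster_levels,
        unit_offsets=pd.Series(offsets, index=unit_ids, name="log_offset"),
    )
    bundle = StudyBundle(
        area=area,
        field=field,
        stations=stations,
        daily=daily,
        mobility=mobility,
        outside=outside,
    )
    return SyntheticBundle(bundle=bundle, truth=truth, spec=spec)


def _simulate_mobility(
    rng, spec: SimulationSpec, unit_ids: list[str], unit_xy: np.ndarray
) -> MobilityMatrix:
    n = len(unit_ids)
    if spec.mobility_intensity == 0.0:
        return MobilityMatrix.identity(unit_ids, period_years=spec.period_years)

    jitter = np.clip(rng.uniform(0.75, 1.25, size=n), 0.0, 0.999 / max(
        spec.mobility_intensity, 1e-12
    ))
    move = np.clip(spec.mobility_intensity * jitter, 0.0, 0.999)

    d = np.hypot(
        unit_xy[:, 0][:, None] - unit_xy[:, 0][None, :],
        unit_xy[:, 1][:, None] - unit_xy[:, 1][None, :],
    )
    w = 1.0 / (d + 500.0)  # 500 m smoothing keeps near-coincident units finite
    np.fill_diagonal(w, 0.0)

    prob = np.zeros((n, n + 1))
    for i in range(n):
        interior_mass = move[i] * (1.0 - spec.outside_fraction)
        if n > 1 and interior_mass > 0:
            prob[i, :n] = interior_mass * w[i] / w[i].sum()
        else:
            interior_mass = 0.0
        prob[i, n] = move[i] - interior_mass  # outside takes the remainder
        prob[i, i] = 1.0 - prob[i].sum()  # exact row sum of 1

    cols = list(unit_ids) + [OUTSIDE_LABEL]
    df = pd.DataFrame(prob, index=pd.Index(unit_ids, name="dest_id"), columns=cols)
    if not (df[OUTSIDE_LABEL] > 0).any():
        df = df.drop(columns=[OUTSIDE_LABEL])
    return MobilityMatrix(probabilities=df, period_years=spec.period_years)


def write_truth(synth: SyntheticBundle, outdir: str) -> dict[str, str]:
    """Write the ground-truth files under ``outdir``/truth for recovery tests."""
    tdir = os.path.join(outdir, "truth")
    os.makedirs(tdir, exist_ok=True)
    paths = {
        "hidden_annual": os.path.join(tdir, "hidden_annual.csv"),
        "labels": os.path.join(tdir, "labels.csv"),
    }
    _io.write_annual_field(synth.truth.hidden_field, paths["hidden_annual"])
    synth.truth.labels.reset_index().to_csv(paths["labels"], index=False)
    return paths


def write_synthetic(synth: SyntheticBundle, outdir: str) -> dict[str, str]:
    """Write the full input bundle plus truth files."""
    paths = _io.write_bundle(synth.bundle, outdir)
    paths.update(write_truth(synth, outdir))
    return paths
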