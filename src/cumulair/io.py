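"""Readers and writers for the tabular study-input schemas.

All files are plain delimiter-separated text (CSV). Schemas:

``units.csv``     unit_id, x, y, population
``annual.csv``    unit_id, year, value          (long form, µg/m³)
``stations.csv``  station_id, type, x, y
``daily.csv``     station_id, date, value       (ISO-8601 dates, µg/m³)
``mobility.csv``  dest_id, origin_id, probability, period_years
``outside.csv``   year, value

The mobility file is long form; rows are grouped by destination. The
``origin_id`` may be the reserved outside label. Row sums are accepted within
1e-6 of one (text round-trip precision) and renormalized exactly on read.

The run configuration is YAML (key-value with nested sections).
"""

from __future__ import annotations

import os
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import CrossRefError, SchemaError, ValidationError
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

_ROW_SUM_TOL = 1e-6

DEFAULT_CONFIG: dict[str, Any] = {
    "min_completeness": 0.75,
    "strict": True,
    "population_weighting": False,
    "clustering": {"k": "auto"},
    "latency": {"reference_year": None, "max_lag": 5},
    "reconstruction": {"trend": "linear", "max_horizon": 10},
    "outside_policy": "require_series",
    "denominator": "n_terms",
    "seed": 0,
}


def _read_table(path: str, columns: list[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise SchemaError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises many parser flavours
        raise SchemaError(f"{path}: unparseable ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(
            f"{path}, line {line}: column {col!r} value "
            f"{df[col][bad].iloc[0]!r} is not numeric"
        )
    return out


def read_units(path: str) -> StudyArea:
    df = _read_table(path, ["unit_id", "x", "y", "population"])
    units = [
        SpatialUnit(
            unit_id=str(r.unit_id),
            x=float(r.x),
            y=float(r.y),
            population=float(r.population),
        )
        for r in df.itertuples()
    ]
    return StudyArea(units=units)


def write_units(area: StudyArea, path: str) -> None:
    area.frame().reset_index().to_csv(path, index=False)


def read_annual_field(path: str) -> AnnualConcentrationField:
    df = _read_table(path, ["unit_id", "year", "value"])
    df["year"] = _numeric(df, "year", path).astype(int)
    df["value"] = _numeric(df, "value", path)
    wide = df.pivot_table(
        index="unit_id", columns="year", values="value", aggfunc="first"
    )
    if len(wide.columns):
        wide = wide.reindex(
            columns=range(int(wide.columns.min()), int(wide.columns.max()) + 1)
        )
    return AnnualConcentrationField(values=wide)


def write_annual_field(field: AnnualConcentrationField, path: str) -> None:
    long = (
        field.values.stack(future_stack=True)
        .rename("value")
        .rename_axis(["unit_id", "year"])
        .reset_index()
        .dropna(subset=["value"])
    )
    long.to_csv(path, index=False)


def read_stations(path: str) -> list[MonitorStation]:
    df = _read_table(path, ["station_id", "type", "x", "y"])
    return [
        MonitorStation(
            station_id=str(r.station_id), type=str(r.type), x=float(r.x), y=float(r.y)
        )
        for r in df.itertuples()
    ]


def write_stations(stations: list[MonitorStation], path: str) -> None:
    pd.DataFrame(
        {
            "station_id": [s.station_id for s in stations],
            "type": [s.type for s in stations],
            "x": [s.x for s in stations],
            "y": [s.y for s in stations],
        }
    ).to_csv(path, index=False)


def read_daily(path: str) -> dict[str, DailyMonitorSeries]:
    df = _read_table(path, ["station_id", "date", "value"])
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except Exception as exc:
        raise SchemaError(f"{path}: unparseable ISO-8601 date ({exc})") from exc
    df["value"] = _numeric(df, "value", path)
    out: dict[str, DailyMonitorSeries] = {}
    for sid, grp in df.groupby("station_id", sort=True):
        s = grp.set_index("date")["value"].sort_index()
        out[str(sid)] = DailyMonitorSeries(station_id=str(sid), observations=s)
    return out


def write_daily(daily: Mapping[str, DailyMonitorSeries], path: str) -> None:
    frames = []
    for sid in sorted(daily):
        s = daily[sid].observations
        frames.append(
            pd.DataFrame(
                {
                    "station_id": sid,
                    "date": s.index.strftime("%Y-%m-%d"),
                    "value": s.to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mobility(path: str) -> MobilityMatrix:
    df = _read_table(path, ["dest_id", "origin_id", "probability", "period_years"])
    if df.empty:
        raise SchemaError(f"{path}: mobility file has no rows")
    df["probability"] = _numeric(df, "probability", path)
    periods = df["period_years"].unique()
    if len(periods) != 1:
        raise ValidationError(
            f"{path}: mixed period_years values {sorted(periods)}; one matrix per file"
        )
    wide = df.pivot_table(
        index="dest_id", columns="origin_id", values="probability", aggfunc="sum"
    ).fillna(0.0)
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    sums = wide.sum(axis=1)
    off = (sums - 1.0).abs() > _ROW_SUM_TOL
    if off.any():
        dest = sums.index[off][0]
        raise ValidationError(
            f"{path}: mobility row for destination {dest!r} sums to "
            f"{sums[dest]:.6f}, expected 1 within {_ROW_SUM_TOL:g}"
        )
    # renormalize text-rounded rows only; leave float-exact rows untouched so
    # write-then-read round-trips are bitwise lossless
    needs = (sums - 1.0).abs() > 1e-12
    if needs.any():
        wide.loc[needs] = wide.loc[needs].div(sums[needs], axis=0)
    # interior unit columns first (sorted), outside last
    cols = sorted(c for c in wide.columns if c != OUTSIDE_LABEL)
    if OUTSIDE_LABEL in wide.columns:
        cols.append(OUTSIDE_LABEL)
    wide = wide.loc[sorted(wide.index), cols]
    return MobilityMatrix(probabilities=wide, period_years=int(periods[0]))


def write_mobility(matrix: MobilityMatrix, path: str) -> None:
    long = (
        matrix.probabilities.stack()
        .rename("probability")
        .rename_axis(["dest_id", "origin_id"])
        .reset_index()
    )
    long = long[long["probability"] > 0]
    long["period_years"] = matrix.period_years
    long.to_csv(path, index=False)


def read_outside(path: str) -> OutsideExposureSeries:
    df = _read_table(path, ["year", "value"])
    s = pd.Series(
        _numeric(df, "value", path).to_numpy(),
        index=_numeric(df, "year", path).astype(int).to_numpy(),
    )
    return OutsideExposureSeries(values=s)


def write_outside(series: OutsideExposureSeries, path: str) -> None:
    series.values.rename("value").rename_axis("year").reset_index().to_csv(
        path, index=False
    )


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load a YAML run configuration, merged over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def read_study_inputs(
    paths: Mapping[str, str], config: Mapping[str, Any] | None = None
) -> StudyBundle:
    """Read and cross-validate a full set of study inputs.

    Parameters
    ----------
    paths:
        Mapping with keys ``units``, ``annual`` (required) and ``stations``,
        ``daily``, ``mobility``, ``outside`` (optional unless ``strict``).
    config:
        Run configuration (see :data:`DEFAULT_CONFIG`). In strict mode all
        six inputs are required.

    Raises
    ------
    SchemaError, ValidationError, CrossRefError
        On schema violations, invariant violations, or unresolved ids.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    strict = bool(cfg.get("strict", True))

    required = ["units", "annual"]
    if strict:
        required += ["stations", "daily", "mobility", "outside"]
    for key in required:
        if key not in paths:
            raise CrossRefError(f"required input {key!r} not supplied")

    area = read_units(paths["units"])
    fld = read_annual_field(paths["annual"])
    stations = read_stations(paths["stations"]) if "stations" in paths else []
    daily = read_daily(paths["daily"]) if "daily" in paths else {}
    mobility = read_mobility(paths["mobility"]) if "mobility" in paths else None
    outside = read_outside(paths["outside"]) if "outside" in paths else None

    unit_ids = set(area.unit_ids)
    unknown = sorted(set(fld.units) - unit_ids)
    if unknown:
        raise CrossRefError(f"annual field references unknown units: {unknown}")
    station_ids = {s.station_id for s in stations}
    if len(station_ids) != len(stations):
        raise ValidationError("duplicate station ids in station registry")
    unknown = sorted(set(daily) - station_ids)
    if unknown:
        raise CrossRefError(f"daily series reference unknown stations: {unknown}")
    if mobility is not None:
        bad = sorted(set(mobility.unit_ids) - unit_ids)
        if bad:
            raise CrossRefError(f"mobility destinations unknown: {bad}")
        origins = set(mobility.probabilities.columns) - {mobility.outside_label}
        bad = sorted(origins - unit_ids)
        if bad:
            raise CrossRefError(f"mobility origins unknown: {bad}")
    return StudyBundle(
        area=area,
        field=fld,
        stations=stations,
        daily=daily,
        mobility=mobility,
        outside=outside,
    )


def write_bundle(bundle: StudyBundle, outdir: str) -> dict[str, str]:
    """Write every component of a bundle to ``outdir``; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "units": os.path.join(outdir, "units.csv"),
        "annual": os.path.join(outdir, "annual.csv"),
        "stations": os.path.join(outdir, "stations.csv"),
        "daily": os.path.join(outdir, "daily.csv"),
    }
    write_units(bundle.area, paths["units"])
    write_annual_field(bundle.field, paths["annual"])
    write_stations(bundle.stations, paths["stations"])
    write_daily(bundle.daily, paths["daily"])
    if bundle.mobility is not None:
        paths["mobility"] = os.path.join(outdir, "mobility.csv")
        write_mobility(bundle.mobility, paths["mobility"])
    if bundle.outside is not None:
        paths["outside"] = os.path.join(outdir, "outside.csv")
        write_outside(bundle.outside, paths["outside"])
    return paths
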