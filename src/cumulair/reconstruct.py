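"""Retrospective reconstruction of unit-level annual means.

The modelled annual concentration field typically starts years after the
monitoring network did, and epidemiological latency windows reach further
back still. This module (i) fits per-series log-linear temporal trends
(log concentration vs calendar year) to annualized station series and unit
series, (ii) calibrates each unit against its index monitor with a log-log
regression over the overlap years, and (iii) back-casts unit annual means
into the pre-period through the monitor:

    log E_N(y) = a_N + b_N * log S_m(y)

where S_m(y) is the index monitor's annual mean in year y, observed when
the monitor existed, otherwise extrapolated from its trend model. The
calibration reduces to plain ratio weighting when b_N = 1, stays positive
by construction, and is exactly invertible on data generated from the same
model class, which is what the recovery tests exploit.

A hold-out validation refits everything with a block of observed years
withheld and reports the back-cast error against the withheld values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ExtrapolationError
from .types import AnnualConcentrationField

logger = logging.getLogger(__name__)

#: Default maximum extrapolation horizon: years before the first observed
#: station year for which a back-cast is still allowed.
DEFAULT_MAX_HORIZON = 10

_MIN_FIT_YEARS = 3


@dataclass(frozen=True)
class TrendModel:
    """Log-linear temporal trend of one series: log value = a + b * year."""

    series_id: str
    intercept: float
    slope: float
    resid_sd: float
    years: tuple[int, ...]

    def predict(self, year: int | np.ndarray) -> float | np.ndarray:
        return np.exp(self.intercept + self.slope * np.asarray(year, dtype=float))


@dataclass(frozen=True)
class CalibrationModel:
    """Per-unit log-log calibration on the index monitor:
    log E_N = a + b * log S_m, with residual sd on the log scale."""

    unit_id: str
    station_id: str
    a: float
    b: float
    resid_sd: float
    years: tuple[int, ...]
    ratio_fallback: bool = False

    def predict(self, station_value: float | np.ndarray) -> float | np.ndarray:
        return np.exp(self.a + self.b * np.log(station_value))


@dataclass
class ReconstructedField:
    """Back-cast annual field plus per-cell log-scale uncertainty."""

    field: AnnualConcentrationField
    sd_log: pd.DataFrame


def _fit_loglinear(series_id: str, s: pd.Series) -> TrendModel | None:
    s = s.dropna()
    if len(s) < _MIN_FIT_YEARS:
        warnings.warn(
            f"series {series_id!r}: only {len(s)} usable years, "
            f"need {_MIN_FIT_YEARS}; excluded from trend fitting",
            stacklevel=3,
        )
        return None
    x = s.index.to_numpy(dtype=float)
    y = np.log(s.to_numpy(dtype=float))
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(s) - 2, 1)
    return TrendModel(
        series_id=series_id,
        intercept=float(res.intercept),
        slope=float(res.slope),
        resid_sd=float(np.sqrt((resid**2).sum() / dof)),
        years=tuple(int(v) for v in s.index),
    )


def fit_trends(series: Mapping[str, pd.Series]) -> dict[str, TrendModel]:
    """Ordinary least squares of log value on calendar year, per series.

    ``series`` maps a series id (station or unit) to a year-indexed Series
    of annual means. Series with fewer than three usable years are excluded
    with a warning.
    """
    out: dict[str, TrendModel] = {}
    for sid in series:
        m = _fit_loglinear(sid, series[sid])
        if m is not None:
            out[sid] = m
    return out


def station_annual_table(station_series: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Stack per-station annual means into a station × year table."""
    df = pd.DataFrame(station_series).T
    df.columns = df.columns.astype(int)
    return df.sort_index(axis=1)


def calibrate_units(
    field: AnnualConcentrationField,
    index_map: Mapping[str, str],
    station_annual: pd.DataFrame,
) -> dict[str, CalibrationModel]:
    """Per-unit OLS of log unit mean on log index-monitor mean.

    Overlap years are those where both the unit and its index monitor have
    values; units with fewer than three are excluded with a warning. A
    monitor with zero variance over the overlap makes the slope
    unidentifiable; such units fall back to a ratio model (b = 1,
    a = mean log ratio), which is logged.
    """
    out: dict[str, CalibrationModel] = {}
    for uid, sid in index_map.items():
        if sid not in station_annual.index:
            raise ConfigurationError(
                f"unit {uid!r}: index station {sid!r} has no annual series"
            )
        e = field.series(uid)
        s = station_annual.loc[sid]
        both = e.notna() & s.reindex(e.index).notna()
        years = [int(y) for y in e.index[both]]
        if len(years) < _MIN_FIT_YEARS:
            warnings.warn(
                f"unit {uid!r}: only {len(years)} overlap years with "
                f"station {sid!r}; excluded from calibration",
                stacklevel=2,
            )
            continue
        loge = np.log(e[both].to_numpy(dtype=float))
        logs = np.log(s.reindex(e.index)[both].to_numpy(dtype=float))
        if np.ptp(logs) <= 1e-12:
            a = float(np.mean(loge - logs))
            resid = loge - (a + logs)
            logger.warning(
                "unit %s: station %s has zero variance over overlap; "
                "ratio fallback (b=1)", uid, sid,
            )
            out[uid] = CalibrationModel(
                unit_id=uid, station_id=sid, a=a, b=1.0,
                resid_sd=float(np.sqrt((resid**2).sum() / max(len(years) - 1, 1))),
                years=tuple(years), ratio_fallback=True,
            )
            continue
        res = stats.linregress(logs, loge)
        resid = loge - (res.intercept + res.slope * logs)
        dof = max(len(years) - 2, 1)
        out[uid] = CalibrationModel(
            unit_id=uid, station_id=sid,
            a=float(res.intercept), b=float(res.slope),
            resid_sd=float(np.sqrt((resid**2).sum() / dof)),
            years=tuple(years),
        )
    return out


def backcast(
    calibrations: Mapping[str, CalibrationModel],
    station_annual: pd.DataFrame,
    target_years: list[int],
    trend_models: Mapping[str, TrendModel] | None = None,
    max_horizon: int = DEFAULT_MAX_HORIZON,
) -> ReconstructedField:
    """Reconstruct unit annual means for ``target_years``.

    For each unit, the index monitor's annual mean is taken from
    ``station_annual`` when observed, otherwise extrapolated from the
    station's trend model. Target years more than ``max_horizon`` years
    before the monitor's first observed year are refused.

    The per-cell uncertainty is the calibration residual sd on the log
    scale (a multiplicative standard error around the point estimate).
    """
    if not target_years:
        raise ConfigurationError("no target years requested")
    target_years = sorted(int(y) for y in target_years)
    full_span = list(range(target_years[0], target_years[-1] + 1))

    values: dict[str, dict[int, float]] = {}
    sds: dict[str, dict[int, float]] = {}
    for uid, cal in calibrations.items():
        srow = station_annual.loc[cal.station_id]
        observed = srow.dropna()
        first_obs = int(observed.index.min())
        trend = (trend_models or {}).get(cal.station_id)
        vals: dict[int, float] = {}
        sd: dict[int, float] = {}
        for y in target_years:
            if y < first_obs - max_horizon:
                raise ExtrapolationError(
                    f"unit {uid!r}: year {y} is beyond the {max_horizon}-year "
                    f"extrapolation horizon of station {cal.station_id!r} "
                    f"(first observed {first_obs})"
                )
            if y in observed.index:
                s_val = float(observed.loc[y])
            else:
                if trend is None:
                    raise ConfigurationError(
                        f"unit {uid!r}: station {cal.station_id!r} lacks year "
                        f"{y} and no trend model was supplied"
                    )
                s_val = float(trend.predict(y))
            vals[y] = float(cal.predict(s_val))
            sd[y] = cal.resid_sd
        values[uid] = vals
        sds[uid] = sd

    vdf = pd.DataFrame(values).T.reindex(columns=full_span)
    vdf.index.name = "unit_id"
    sdf = pd.DataFrame(sds).T.reindex(columns=full_span)
    sdf.index.name = "unit_id"
    return ReconstructedField(
        field=AnnualConcentrationField(values=vdf), sd_log=sdf
    )


@dataclass
class HoldoutReport:
    """Back-cast error against withheld observed years."""

    per_unit: pd.DataFrame  # columns: bias, mare, rmse
    aggregate: dict[str, float]
    holdout_years: tuple[int, ...]


def holdout_validate(
    field: AnnualConcentrationField,
    station_annual: pd.DataFrame,
    index_map: Mapping[str, str],
    holdout_years: list[int],
    max_horizon: int = DEFAULT_MAX_HORIZON,
) -> HoldoutReport:
    """Withhold a block of observed years, refit, back-cast, compare.

    Trend and calibration fits use only the remaining years; the withheld
    station observations are also hidden, so the withheld years are
    reconstructed purely through trend extrapolation and calibration, then
    compared with the withheld unit values. Reports per-unit and aggregate
    bias (mean of estimate - observed), mean absolute relative error and
    RMSE. Leaving fewer than three fit years is a configuration error.
    """
    holdout = sorted(int(y) for y in holdout_years)
    observed_years = [int(y) for y in field.years]
    bad = sorted(set(holdout) - set(observed_years))
    if bad:
        raise ConfigurationError(f"holdout years not observed: {bad}")
    fit_years = [y for y in observed_years if y not in set(holdout)]
    if len(fit_years) < _MIN_FIT_YEARS:
        raise ConfigurationError(
            f"holdout leaves only {len(fit_years)} fit years; "
            f"need at least {_MIN_FIT_YEARS}"
        )

    fit_field = AnnualConcentrationField(
        values=field.values[fit_years].copy()
    ) if _contiguous(fit_years) else None
    if fit_field is None:
        # non-contiguous remainder: keep full span but blank the holdout
        blanked = field.values.copy()
        blanked[holdout] = np.nan
        fit_field = AnnualConcentrationField(values=blanked)

    st_fit = station_annual.drop(columns=holdout, errors="ignore")
    trends = fit_trends({sid: st_fit.loc[sid] for sid in st_fit.index})
    cals = calibrate_units(fit_field, index_map, st_fit)
    recon = backcast(
        cals, st_fit, holdout, trend_models=trends, max_horizon=max_horizon
    )

    rows = {}
    all_err, all_rel = [], []
    for uid in cals:
        obs = field.values.loc[uid, holdout].to_numpy(dtype=float)
        est = recon.field.values.loc[uid, holdout].to_numpy(dtype=float)
        ok = ~np.isnan(obs)
        err = est[ok] - obs[ok]
        rel = np.abs(err) / obs[ok]
        rows[uid] = {
            "bias": float(err.mean()),
            "mare": float(rel.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
        }
        all_err.append(err)
        all_rel.append(rel)
    per_unit = pd.DataFrame(rows).T.sort_index()
    per_unit.index.name = "unit_id"
    err = np.concatenate(all_err)
    rel = np.concatenate(all_rel)
    aggregate = {
        "bias": float(err.mean()),
        "mare": float(rel.mean()),
        "rmse": float(np.sqrt((err**2).mean())),
    }
    return HoldoutReport(
        per_unit=per_unit, aggregate=aggregate, holdout_years=tuple(holdout)
    )


def _contiguous(years: list[int]) -> bool:
    return years == list(range(years[0], years[-1] + 1))
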