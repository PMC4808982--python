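"""Mobility-weighted single-year and cumulative exposure.

The residential-mobility matrix gives, for each destination unit N, the
probability that a current resident lived in each origin (another unit, the
same unit, or outside the study area) one census period earlier. Treating
residence as a Markov chain backwards in time, the probability distribution
of residence L years before the reference year is the matrix applied once
per elapsed census period, with the outside area absorbing (the census
records only where current residents came from, not return moves).

The mobility-weighted exposure of unit N at lag L is the expectation of the
concentration field at year j-L under that residence distribution, and the
cumulative exposure over a latency window is the average of those weighted
terms over L = 0..Lmax. The contrast with the plain average of the unit's
own concentrations quantifies the misclassification incurred by ignoring
residential mobility.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingExposureError, ValidationError
from .types import (
    AnnualConcentrationField,
    MobilityMatrix,
    OutsideExposureSeries,
    StudyArea,
)


class OutsidePolicy(str, Enum):
    """How exposure of the outside-area origin is handled.

    ``require_series``
        An outside-area annual exposure series must be supplied whenever any
        residence probability escapes the study area (the default).
    ``renormalize_interior``
        Drop the outside origin and renormalize rows over interior units,
        i.e. consider movements inside the study area only.
    ``impute_area_mean``
        Use the across-unit mean of the field as the outside exposure.
    """

    REQUIRE_SERIES = "require_series"
    RENORMALIZE_INTERIOR = "renormalize_interior"
    IMPUTE_AREA_MEAN = "impute_area_mean"


class Denominator(str, Enum):
    """Divisor of the cumulative sum over lags 0..Lmax: the number of terms
    (Lmax + 1, default — keeps a constant field invariant), or the literal
    Lmax."""

    N_TERMS = "n_terms"
    LITERAL_LMAX = "paper_literal"


@dataclass(frozen=True)
class CumulativeExposureResult:
    """Cumulative exposure of one unit over a latency window (µg/m³)."""

    unit_id: str
    reference_year: int
    max_lag: int
    with_mobility: float
    without_mobility: float
    relative_difference: float  # without - with, exactly
    degree_of_mobility: float  # 100 * (1 - P_NN), percent


def _transition_states(
    matrix: MobilityMatrix, policy: OutsidePolicy
) -> tuple[list[str], np.ndarray, bool]:
    """States and one-period destination←origin transition array.

    Rows/columns ordered as the matrix's units, with the absorbing outside
    state last when present.
    """
    policy = OutsidePolicy(policy)
    units = matrix.unit_ids
    probs = matrix.probabilities
    has_outside = matrix.has_outside

    if policy is OutsidePolicy.RENORMALIZE_INTERIOR and has_outside:
        inner = probs[units].to_numpy(dtype=float)
        sums = inner.sum(axis=1)
        if (sums <= 0).any():
            dest = units[int(np.argmax(sums <= 0))]
            raise ValidationError(
                f"destination {dest!r} has no interior origin mass; cannot "
                "renormalize over interior units"
            )
        return units, inner / sums[:, None], False

    if not has_outside:
        return units, probs[units].to_numpy(dtype=float), False

    n = len(units)
    p = np.zeros((n + 1, n + 1))
    p[:n, :n] = probs[units].to_numpy(dtype=float)
    p[:n, n] = probs[matrix.outside_label].to_numpy(dtype=float)
    p[n, n] = 1.0  # absorbing: once outside, stays outside
    return units + [matrix.outside_label], p, True


def residence_distribution(
    unit_id: str,
    lag: int,
    matrix: MobilityMatrix,
    policy: OutsidePolicy | str = OutsidePolicy.REQUIRE_SERIES,
) -> pd.Series:
    """Distribution of residence ``lag`` years before the reference year.

    Lag 0 is a point mass on ``unit_id``. The matrix is applied once per
    elapsed census period (``lag // period_years`` steps); residence is held
    fixed within a period. Probability mass that reaches the outside area
    stays there.
    """
    if lag < 0:
        raise ConfigurationError("lag must be non-negative")
    if unit_id not in matrix.unit_ids:
        raise ConfigurationError(f"unknown unit {unit_id!r} in mobility matrix")
    states, p, _ = _transition_states(matrix, OutsidePolicy(policy))
    v = np.zeros(len(states))
    v[states.index(unit_id)] = 1.0
    for _ in range(lag // matrix.period_years):
        v = v @ p
    return pd.Series(v, index=states, name=unit_id)


def _exposures_at(
    states: list[str],
    dist: np.ndarray,
    year: int,
    field: AnnualConcentrationField,
    outside: OutsideExposureSeries | None,
    policy: OutsidePolicy,
    outside_label: str,
) -> np.ndarray:
    vals = np.empty(len(states))
    for i, s in enumerate(states):
        if dist[i] <= 0.0:
            vals[i] = 0.0  # never read; avoids demanding unused cells
            continue
        if s == outside_label:
            if policy is OutsidePolicy.IMPUTE_AREA_MEAN:
                v = float(np.nanmean(field.values[year].to_numpy(dtype=float)))
            else:
                if outside is None:
                    raise MissingExposureError(
                        f"residence probability {dist[i]:.3g} falls outside the "
                        f"study area in year {year} but no outside exposure "
                        "series was supplied"
                    )
                v = outside.value(year)
        else:
            v = field.value(s, year)
        if np.isnan(v):
            raise MissingExposureError(
                f"missing exposure for {s!r} in year {year} "
                f"(residence probability {dist[i]:.3g})"
            )
        vals[i] = v
    return vals


def weighted_exposure(
    unit_id: str,
    year: int,
    lag: int,
    matrix: MobilityMatrix,
    field: AnnualConcentrationField,
    outside: OutsideExposureSeries | None = None,
    policy: OutsidePolicy | str = OutsidePolicy.REQUIRE_SERIES,
) -> float:
    """Mobility-weighted exposure of ``unit_id`` at ``year - lag`` (µg/m³).

    The dot product of the lag-``lag`` residence distribution with the
    exposure field at year ``year - lag``; outside-area mass uses the
    outside exposure series (or the chosen policy). A missing exposure cell
    carrying positive probability raises :class:`MissingExposureError`.
    """
    policy = OutsidePolicy(policy)
    dist = residence_distribution(unit_id, lag, matrix, policy)
    states = list(dist.index)
    d = dist.to_numpy()
    vals = _exposures_at(
        states, d, year - lag, field, outside, policy, matrix.outside_label
    )
    return float(d @ vals)


def cumulative_exposure(
    unit_id: str,
    reference_year: int,
    max_lag: int,
    matrix: MobilityMatrix,
    field: AnnualConcentrationField,
    outside: OutsideExposureSeries | None = None,
    policy: OutsidePolicy | str = OutsidePolicy.REQUIRE_SERIES,
    denominator: Denominator | str = Denominator.N_TERMS,
) -> CumulativeExposureResult:
    """Cumulative exposure of one unit over lags 0..``max_lag``.

    The with-mobility value averages the mobility-weighted terms, the
    without-mobility value averages the unit's own concentrations over the
    same years, and their difference is the mobility correction. With the
    default denominator both are divided by the number of terms
    (``max_lag + 1``); the ``paper_literal`` option divides by ``max_lag``
    and refuses ``max_lag = 0``.
    """
    denominator = Denominator(denominator)
    if max_lag < 0:
        raise ConfigurationError("max_lag must be non-negative")
    if denominator is Denominator.LITERAL_LMAX and max_lag == 0:
        raise ConfigurationError(
            "denominator 'paper_literal' divides by max_lag and cannot be "
            "used with max_lag = 0"
        )
    denom = float(max_lag + 1 if denominator is Denominator.N_TERMS else max_lag)

    with_sum = 0.0
    without_sum = 0.0
    for lag in range(max_lag + 1):
        with_sum += weighted_exposure(
            unit_id, reference_year, lag, matrix, field, outside, policy
        )
        own = field.value(unit_id, reference_year - lag)
        if np.isnan(own):
            raise MissingExposureError(
                f"missing exposure for {unit_id!r} in year {reference_year - lag}"
            )
        without_sum += own

    with_v = with_sum / denom
    without_v = without_sum / denom
    return CumulativeExposureResult(
        unit_id=unit_id,
        reference_year=reference_year,
        max_lag=max_lag,
        with_mobility=with_v,
        without_mobility=without_v,
        relative_difference=without_v - with_v,
        degree_of_mobility=float(matrix.degree_of_mobility()[unit_id]),
    )


def area_report(
    results: Iterable[CumulativeExposureResult],
    sort: bool = True,
) -> pd.DataFrame:
    """Per-unit report with the four standard columns, ranked by descending
    degree of mobility (ties broken by unit id)."""
    rows = list(results)
    df = pd.DataFrame(
        {
            "degree_of_mobility": [r.degree_of_mobility for r in rows],
            "cumulative_without_mobility": [r.without_mobility for r in rows],
            "cumulative_with_mobility": [r.with_mobility for r in rows],
            "relative_difference": [r.relative_difference for r in rows],
        },
        index=pd.Index([r.unit_id for r in rows], name="unit_id"),
    )
    if sort:
        df = df.sort_values(
            ["degree_of_mobility", "unit_id"],
            ascending=[False, True],
            kind="mergesort",
        )
    return df


def aggregate_exposure(
    report: pd.DataFrame,
    area: StudyArea | None = None,
    weighting: str = "unweighted",
) -> dict[str, float]:
    """Area-level aggregate of a per-unit report.

    ``weighting="population"`` weights units by their population (requires
    ``area``); ``"unweighted"`` is the plain mean.
    """
    cols = [
        "cumulative_without_mobility",
        "cumulative_with_mobility",
        "relative_difference",
        "degree_of_mobility",
    ]
    if weighting == "unweighted":
        w = np.ones(len(report))
    elif weighting == "population":
        if area is None:
            raise ConfigurationError("population weighting requires the study area")
        pops = area.frame()["population"]
        w = pops.reindex(report.index).to_numpy(dtype=float)
        if np.isnan(w).any() or w.sum() <= 0:
            raise ConfigurationError(
                "population weights missing or all zero for reported units"
            )
    else:
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return {c: float(report[c].to_numpy(dtype=float) @ w) for c in cols}


def render_report(report: pd.DataFrame) -> str:
    """Render a per-unit report as aligned text."""
    header = (
        f"{'unit':<12}{'mobility %':>12}{'without':>12}{'with':>12}{'diff':>10}"
    )
    lines = [header, "-" * len(header)]
    for uid, r in report.iterrows():
        lines.append(
            f"{str(uid):<12}{r['degree_of_mobility']:>12.1f}"
            f"{r['cumulative_without_mobility']:>12.2f}"
            f"{r['cumulative_with_mobility']:>12.2f}"
            f"{r['relative_difference']:>10.2f}"
        )
    return "\n".join(lines) + "\n"
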