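from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cumulair import (
    AnnualConcentrationField,
    MobilityMatrix,
    OutsideExposureSeries,
    SimulationSpec,
    simulate_area,
)

#: A three-cluster configuration with strong temporal contrast and no noise;
#: every stage of the pipeline is exactly recoverable on it.
NOISELESS_SPEC = SimulationSpec(
    n_units=10,
    n_stations=4,
    n_clusters_true=3,
    trend_slopes=(0.90, 1.08, 0.98),
    daily_noise_sd=0.0,
    seasonal_amplitude=0.0,
    rng_seed=7,
)

#: Strong slope contrast with small daily noise: clusters remain separable.
SEPARATED_SPEC = SimulationSpec(
    n_units=12,
    n_stations=5,
    n_clusters_true=3,
    trend_slopes=(0.85, 1.12, 0.97),
    daily_noise_sd=0.02,
    seasonal_amplitude=0.2,
    rng_seed=0,
)


@pytest.fixture(scope="session")
def noiseless_synth():
    return simulate_area(NOISELESS_SPEC)


@pytest.fixture(scope="session")
def default_synth():
    return simulate_area(SimulationSpec(rng_seed=11))


def random_field(
    rng: np.random.Generator,
    unit_ids: list[str],
    years: list[int],
    low: float = 30.0,
    high: float = 90.0,
) -> AnnualConcentrationField:
    vals = rng.uniform(low, high, size=(len(unit_ids), len(years)))
    return AnnualConcentrationField(
        values=pd.DataFrame(vals, index=list(unit_ids), columns=list(years))
    )


def random_mobility(
    rng: np.random.Generator,
    unit_ids: list[str],
    period_years: int = 1,
    with_outside: bool = False,
    concentration: float = 1.0,
) -> MobilityMatrix:
    """Row-stochastic matrix from a Dirichlet draw per destination."""
    cols = list(unit_ids) + (["__OUTSIDE__"] if with_outside else [])
    rows = rng.dirichlet(np.full(len(cols), concentration), size=len(unit_ids))
    df = pd.DataFrame(rows, index=list(unit_ids), columns=cols)
    return MobilityMatrix(probabilities=df, period_years=period_years)


def constant_outside(years: list[int], value: float) -> OutsideExposureSeries:
    return OutsideExposureSeries(
        values=pd.Series(float(value), index=list(years))
    )
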