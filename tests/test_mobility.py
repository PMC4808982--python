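"""Mobility-weighted exposure: recursion, policies, cumulation, reporting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cumulair import (
    AnnualConcentrationField,
    ConfigurationError,
    MissingExposureError,
    MobilityMatrix,
    OutsidePolicy,
    area_report,
    aggregate_exposure,
    cumulative_exposure,
    render_report,
    residence_distribution,
    weighted_exposure,
)
from conftest import constant_outside, random_field, random_mobility
from oracles import (
    cumulative_exposure_bruteforce,
    residence_distribution_bruteforce,
    weighted_exposure_bruteforce,
)


def matrix(rows, ids, cols=None, period=1):
    df = pd.DataFrame(rows, index=ids, columns=cols or ids, dtype=float)
    return MobilityMatrix(probabilities=df, period_years=period)


def field_of(rows, ids, years):
    df = pd.DataFrame(rows, index=ids, columns=years, dtype=float)
    return AnnualConcentrationField(values=df)


TOY = matrix([[0.8, 0.2], [0.5, 0.5]], ["N", "U"])


class TestResidenceDistribution:
    def test_lag_zero_is_a_point_mass(self):
        d = residence_distribution("N", 0, TOY)
        assert d["N"] == 1.0 and d["U"] == 0.0

    def test_identity_matrix_stays_put(self):
        m = MobilityMatrix.identity(["A", "B", "C"])
        for lag in (0, 1, 5):
            d = residence_distribution("B", lag, m)
            assert d["B"] == 1.0

    def test_two_step_toy_matches_path_enumeration(self):
        d = residence_distribution("N", 2, TOY)
        assert d["N"] == pytest.approx(0.74, abs=1e-12)
        assert d["U"] == pytest.approx(0.26, abs=1e-12)
        oracle = residence_distribution_bruteforce(TOY, "N", 2)
        for s in ("N", "U"):
            assert d[s] == pytest.approx(oracle[s], abs=1e-12)

    def test_outside_is_absorbing(self):
        m = matrix([[0.5, 0.0, 0.5], [0.0, 1.0, 0.0]], ["A", "B"],
                   cols=["A", "B", "__OUTSIDE__"])
        d1 = residence_distribution("A", 1, m)
        d5 = residence_distribution("A", 5, m)
        assert d5["__OUTSIDE__"] > d1["__OUTSIDE__"]
        assert d5["__OUTSIDE__"] == pytest.approx(1 - 0.5**5, abs=1e-12)

    def test_census_period_counts_elapsed_periods(self):
        m = matrix([[0.8, 0.2], [0.5, 0.5]], ["N", "U"], period=5)
        # lags within the first period leave residence unchanged
        for lag in range(5):
            assert residence_distribution("N", lag, m)["N"] == 1.0
        d = residence_distribution("N", 5, m)
        assert d["N"] == pytest.approx(0.8)
        d = residence_distribution("N", 10, m)
        assert d["N"] == pytest.approx(0.74)

    def test_renormalize_interior_removes_outside_mass(self):
        m = matrix([[0.6, 0.2, 0.2], [0.1, 0.7, 0.2]], ["A", "B"],
                   cols=["A", "B", "__OUTSIDE__"])
        d = residence_distribution("A", 1, m, policy="renormalize_interior")
        assert "__OUTSIDE__" not in d.index
        assert d.sum() == pytest.approx(1.0, abs=1e-12)
        assert d["A"] == pytest.approx(0.75)
        assert d["B"] == pytest.approx(0.25)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), lag=st.integers(0, 6))
    def test_distribution_is_always_a_probability_vector(self, seed, lag):
        rng = np.random.default_rng(seed)
        m = random_mobility(rng, ["A", "B", "C"], with_outside=True)
        d = residence_distribution("A", lag, m)
        assert (d.to_numpy() >= 0).all()
        assert d.sum() == pytest.approx(1.0, abs=1e-9)


class TestWeightedExposure:
    def test_constant_field_returns_the_constant(self):
        f = field_of([[40.0] * 3] * 2, ["N", "U"], [2000, 2001, 2002])
        v = weighted_exposure("N", 2002, 2, TOY, f)
        assert v == pytest.approx(40.0, rel=1e-12)

    def test_identity_matrix_returns_own_exposure(self):
        m = MobilityMatrix.identity(["N", "U"])
        f = field_of([[40.0, 42.0, 44.0], [60.0, 62.0, 64.0]],
                     ["N", "U"], [2000, 2001, 2002])
        assert weighted_exposure("N", 2002, 2, m, f) == 40.0

    def test_hand_computed_convex_combination(self):
        m = matrix([[0.8, 0.2], [0.5, 0.5]], ["N", "U"])
        f = field_of([[10.0, 10.0], [20.0, 20.0]], ["N", "U"], [2001, 2002])
        # one step back: 0.8*10 + 0.2*20 = 12
        assert weighted_exposure("N", 2002, 1, m, f) == pytest.approx(12.0, abs=1e-12)

    def test_missing_cell_with_positive_probability_raises(self):
        f = field_of([[10.0, 10.0], [np.nan, 20.0]], ["N", "U"], [2001, 2002])
        with pytest.raises(MissingExposureError, match="'U'.*2001"):
            weighted_exposure("N", 2002, 1, TOY, f)

    def test_require_series_policy_demands_outside_series(self):
        m = matrix([[0.7, 0.3]], ["A"], cols=["A", "__OUTSIDE__"])
        f = field_of([[10.0, 10.0]], ["A"], [2001, 2002])
        with pytest.raises(MissingExposureError, match="outside"):
            weighted_exposure("A", 2002, 1, m, f)
        v = weighted_exposure("A", 2002, 1, m, f,
                              outside=constant_outside([2001, 2002], 30.0))
        assert v == pytest.approx(0.7 * 10 + 0.3 * 30, abs=1e-12)

    def test_impute_area_mean_policy(self):
        m = matrix([[0.7, 0.3], [0.0, 1.0]], ["A", "B"],
                   cols=["A", "__OUTSIDE__"])
        f = field_of([[10.0, 10.0], [30.0, 30.0]], ["A", "B"], [2001, 2002])
        v = weighted_exposure("A", 2002, 1, m, f, policy="impute_area_mean")
        assert v == pytest.approx(0.7 * 10 + 0.3 * 20.0, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), lag=st.integers(0, 4))
    def test_convexity_over_randomized_inputs(self, seed, lag):
        """The weighted value lies within [min, max] of exposures receiving
        positive residence probability."""
        rng = np.random.default_rng(seed)
        ids = ["A", "B", "C", "D"]
        years = list(range(2000, 2006))
        m = random_mobility(rng, ids, with_outside=True)
        f = random_field(rng, ids, years)
        out = constant_outside(years, float(rng.uniform(10, 100)))
        d = residence_distribution("A", lag, m)
        vals = [f.value(s, 2005 - lag) if s != "__OUTSIDE__"
                else out.value(2005 - lag)
                for s in d.index if d[s] > 0]
        v = weighted_exposure("A", 2005, lag, m, f, outside=out)
        assert min(vals) - 1e-9 <= v <= max(vals) + 1e-9


class TestCumulativeExposure:
    def test_lag_zero_window_collapses_to_current_year(self):
        f = field_of([[40.0, 42.0], [60.0, 62.0]], ["N", "U"], [2001, 2002])
        r = cumulative_exposure("N", 2002, 0, TOY, f)
        assert r.with_mobility == r.without_mobility == 42.0

    def test_identity_mobility_equals_sedentary_estimate(self):
        m = MobilityMatrix.identity(["N", "U"])
        rng = np.random.default_rng(0)
        f = random_field(rng, ["N", "U"], list(range(1998, 2003)))
        r = cumulative_exposure("N", 2002, 4, m, f)
        assert r.with_mobility == r.without_mobility
        assert r.relative_difference == 0.0
        assert r.degree_of_mobility == 0.0

    def test_toy_matches_residence_history_enumeration(self):
        rng = np.random.default_rng(1)
        f = random_field(rng, ["N", "U"], list(range(2000, 2003)))
        r = cumulative_exposure("N", 2002, 2, TOY, f)
        expected = cumulative_exposure_bruteforce(TOY, f, None, "N", 2002, 2)
        assert r.with_mobility == pytest.approx(expected, abs=1e-12)

    def test_paper_literal_denominator_refuses_zero_window(self):
        f = field_of([[40.0, 42.0]], ["N"], [2001, 2002])
        m = MobilityMatrix.identity(["N"])
        with pytest.raises(ConfigurationError, match="max_lag"):
            cumulative_exposure("N", 2002, 0, m, f, denominator="paper_literal")

    def test_denominator_conventions_differ_by_known_factor(self):
        m = MobilityMatrix.identity(["N"])
        f = field_of([[40.0, 42.0, 44.0]], ["N"], [2000, 2001, 2002])
        r1 = cumulative_exposure("N", 2002, 2, m, f, denominator="n_terms")
        r2 = cumulative_exposure("N", 2002, 2, m, f, denominator="paper_literal")
        assert r2.with_mobility == pytest.approx(r1.with_mobility * 3 / 2, rel=1e-12)

    def test_relative_difference_is_exactly_without_minus_with(self):
        rng = np.random.default_rng(2)
        ids = ["A", "B", "C"]
        m = random_mobility(rng, ids)
        f = random_field(rng, ids, list(range(1998, 2003)))
        r = cumulative_exposure("A", 2002, 4, m, f)
        assert r.relative_difference == r.without_mobility - r.with_mobility


class TestAreaReport:
    def results(self):
        rng = np.random.default_rng(3)
        ids = [f"U{i}" for i in range(5)]
        m = random_mobility(rng, ids)
        f = random_field(rng, ids, list(range(1999, 2003)))
        return [cumulative_exposure(u, 2002, 3, m, f) for u in ids], ids

    def test_rows_sorted_by_descending_mobility(self):
        results, _ = self.results()
        rep = area_report(results)
        deg = rep["degree_of_mobility"].to_numpy()
        assert (np.diff(deg) <= 0).all()

    def test_single_unit_area(self):
        f = field_of([[40.0, 42.0]], ["N"], [2001, 2002])
        df = pd.DataFrame([[0.9, 0.1]], index=["N"], columns=["N", "__OUTSIDE__"])
        m = MobilityMatrix(probabilities=df)
        r = cumulative_exposure("N", 2002, 1, m, f,
                                outside=constant_outside([2001], 20.0))
        rep = area_report([r])
        assert len(rep) == 1
        assert rep["degree_of_mobility"].iloc[0] == pytest.approx(10.0)

    def test_population_weighted_aggregate(self):
        from cumulair import SpatialUnit, StudyArea
        results, ids = self.results()
        area = StudyArea(units=[SpatialUnit(u, 0.0, 0.0, float(i + 1))
                                for i, u in enumerate(ids)])
        rep = area_report(results)
        agg_u = aggregate_exposure(rep, weighting="unweighted")
        agg_p = aggregate_exposure(rep, area=area, weighting="population")
        w = np.array([ids.index(u) + 1 for u in rep.index], dtype=float)
        expected = float(rep["cumulative_with_mobility"].to_numpy() @ (w / w.sum()))
        assert agg_p["cumulative_with_mobility"] == pytest.approx(expected)
        assert agg_u["cumulative_with_mobility"] == pytest.approx(
            rep["cumulative_with_mobility"].mean()
        )

    def test_render_report_is_aligned_text(self):
        results, _ = self.results()
        text = render_report(area_report(results))
        lines = text.strip().splitlines()
        assert len(lines) == 2 + 5  # header + rule + one line per unit
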