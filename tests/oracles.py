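"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's recursive/vectorized code paths:
residence histories are enumerated path by path, and agglomerative merges
are found by scanning all cluster pairs at every step.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def enumerate_residence_histories(matrix, start: str, n_steps: int):
    """All residence histories of length ``n_steps`` backwards from ``start``.

    Yields ``(history, probability)`` where ``history[0] == start`` and
    ``history[t]`` is the residence t periods earlier. The outside state is
    absorbing: from outside the only continuation is outside.
    """
    probs = matrix.probabilities
    outside = matrix.outside_label
    states = list(probs.columns)

    def step(state):
        if state == outside:
            return [(outside, 1.0)]
        return [(s, float(probs.at[state, s])) for s in states]

    def rec(history, p):
        if len(history) == n_steps + 1:
            yield tuple(history), p
            return
        for nxt, q in step(history[-1]):
            if q > 0.0:
                yield from rec(history + [nxt], p * q)

    yield from rec([start], 1.0)


def residence_distribution_bruteforce(matrix, start: str, lag: int) -> pd.Series:
    """Residence distribution at ``lag`` years by path enumeration."""
    n_steps = lag // matrix.period_years
    out: dict[str, float] = {}
    for hist, p in enumerate_residence_histories(matrix, start, n_steps):
        out[hist[-1]] = out.get(hist[-1], 0.0) + p
    return pd.Series(out)


def _exposure(state, year, field, outside_series, outside_label):
    if state == outside_label:
        return float(outside_series.value(year))
    return float(field.value(state, year))


def weighted_exposure_bruteforce(
    matrix, field, outside_series, unit: str, year: int, lag: int
) -> float:
    """Expected exposure at year-lag over all enumerated histories."""
    n_steps = lag // matrix.period_years
    total = 0.0
    for hist, p in enumerate_residence_histories(matrix, unit, n_steps):
        total += p * _exposure(
            hist[-1], year - lag, field, outside_series, matrix.outside_label
        )
    return total


def cumulative_exposure_bruteforce(
    matrix, field, outside_series, unit: str, ref_year: int, max_lag: int
) -> float:
    """Average over lags 0..max_lag of the per-history expected exposure.

    Histories are enumerated once at full length; the state relevant to lag
    L is the one ``L // period_years`` steps back, so this exercises the
    whole residence-history distribution rather than per-lag marginals.
    """
    n_steps = max_lag // matrix.period_years
    total = 0.0
    for hist, p in enumerate_residence_histories(matrix, unit, n_steps):
        acc = 0.0
        for lag in range(max_lag + 1):
            state = hist[lag // matrix.period_years]
            acc += _exposure(
                state, ref_year - lag, field, outside_series, matrix.outside_label
            )
        total += p * acc / (max_lag + 1)
    return total


def average_linkage_bruteforce(ids: list[str], dist: np.ndarray):
    """Agglomerative average-linkage merges by exhaustive pair scanning.

    Cluster-to-cluster distance is the mean of all pairwise point distances.
    Ties break on the lexicographically smallest (sorted) member pair.
    Returns a list of ``(frozenset_a, frozenset_b, height)`` in merge order.
    """
    clusters: list[tuple[str, ...]] = [(i,) for i in ids]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [dist[ids.index(x), ids.index(y)] for x in a for y in b]
            )
            key = (d, tuple(sorted(a + b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (_d, _), a, b = best
        merges.append((frozenset(a), frozenset(b), float(_d)))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
    return merges


def scipy_linkage_merges(order: list[str], z: np.ndarray):
    """Convert a scipy linkage matrix to the oracle's merge representation."""
    n = len(order)
    members: dict[int, frozenset] = {i: frozenset([e]) for i, e in enumerate(order)}
    merges = []
    for step, (a, b, h, _cnt) in enumerate(z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb, float(h)))
        members[n + step] = fa | fb
    return merges
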