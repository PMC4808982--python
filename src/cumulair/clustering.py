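"""Grouping spatial units and monitoring stations by temporal similarity.

Units and stations live on different time supports (annual model output vs
daily measurements), so both are put on a common annual footing first. Each
entity is represented by its standardized annual-concentration profile, and
entities are grouped by hierarchical agglomerative clustering under
correlation distance (1 - Pearson r) with average linkage: a traffic station
can track a unit's temporal dynamics at a much higher absolute level, and
correlation distance is invariant to that scale.

Each unit is then assigned the spatially nearest station within its cluster
as its "index" monitor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, StationCoverageError
from .types import (
    AnnualConcentrationField,
    DailyMonitorSeries,
    MonitorStation,
    StudyArea,
    annualize,
)

logger = logging.getLogger(__name__)

_CONST_TOL = 1e-12


@dataclass
class FeatureSet:
    """Standardized annual profiles for units and stations.

    ``profiles`` rows have zero mean and unit (sample) variance over the
    common year range; entities with constant profiles are excluded and
    listed in ``excluded``.
    """

    profiles: pd.DataFrame  # entity_id × common years, standardized
    kind: pd.Series  # entity_id -> "unit" | "station"
    excluded: list[str] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.profiles.columns]


@dataclass
class ClusteringResult:
    labels: pd.Series  # entity_id -> cluster id (1..k)
    linkage_matrix: np.ndarray  # scipy linkage encoding of the dendrogram
    order: list[str]  # canonical entity order the linkage refers to
    k: int


@dataclass
class IndexAssignment:
    """Unit → index-station mapping plus the cluster labels behind it."""

    cluster_labels: pd.Series
    index_of: dict[str, str]


def build_features(
    annual_field: AnnualConcentrationField,
    daily_series: Mapping[str, DailyMonitorSeries],
    min_completeness: float = 0.75,
) -> FeatureSet:
    """Standardized annual profiles over the years shared by all entities.

    Stations are annualized from their daily series (years below the
    completeness threshold count as missing); units use the annual field
    directly. Entities whose profile is constant over the common years are
    flagged and excluded with a warning.
    """
    station_annual = {
        sid: annualize(s, min_completeness) for sid, s in daily_series.items()
    }
    rows: dict[str, pd.Series] = {u: annual_field.series(u) for u in annual_field.units}
    rows.update(station_annual)
    kind = pd.Series(
        {u: "unit" for u in annual_field.units}
        | {s: "station" for s in station_annual}
    )

    raw = pd.DataFrame(rows).T
    raw.columns = raw.columns.astype(int)
    common = raw.columns[raw.notna().all(axis=0)]
    if len(common) < 2:
        raise ConfigurationError(
            f"entities share only {len(common)} usable year(s); need at least 2"
        )
    raw = raw[common]

    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=1)
    constant = sd <= _CONST_TOL * mean.abs().clip(lower=1.0)
    excluded = sorted(raw.index[constant])
    if excluded:
        warnings.warn(
            f"constant profiles excluded from clustering: {excluded}",
            stacklevel=2,
        )
    keep = raw.index[~constant]
    prof = raw.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    prof.index.name = "entity_id"
    return FeatureSet(profiles=prof, kind=kind.loc[keep], excluded=list(excluded))


def correlation_distances(profiles: pd.DataFrame) -> np.ndarray:
    """Square matrix of 1 - Pearson r between profile rows."""
    # contiguous copy: BLAS summation order must not depend on the memory
    # layout the DataFrame happened to have, or permutation invariance breaks
    x = np.ascontiguousarray(profiles.to_numpy(dtype=float))
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def cluster(features: FeatureSet, k: int | str = "auto") -> ClusteringResult:
    """Agglomerative clustering of the standardized profiles.

    Correlation distance, average linkage. Entities are processed in
    lexicographic id order, which makes the result invariant to the order in
    which inputs were supplied. ``k="auto"`` selects the cut maximizing the
    mean silhouette over k in 2..min(10, n-1); ties go to the smaller k.
    """
    order = sorted(features.profiles.index)
    prof = features.profiles.loc[order]
    n = len(order)
    if n < 2:
        raise ConfigurationError("clustering needs at least 2 non-constant profiles")
    dist = correlation_distances(prof)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")

    if k == "auto":
        k = _auto_k(dist, z)
    k = int(k)
    if not (1 <= k <= n):
        raise ConfigurationError(f"k={k} outside 1..{n} (non-constant profiles)")
    flat = fcluster(z, t=k, criterion="maxclust") if k > 1 else np.ones(n, dtype=int)
    labels = pd.Series(flat, index=pd.Index(order, name="entity_id"), name="cluster")
    return ClusteringResult(labels=labels, linkage_matrix=z, order=order, k=k)


def _auto_k(dist: np.ndarray, z: np.ndarray) -> int:
    n = dist.shape[0]
    best_k, best_score = 2, -np.inf
    for kk in range(2, min(10, n - 1) + 1):
        flat = fcluster(z, t=kk, criterion="maxclust")
        if len(np.unique(flat)) < 2:
            continue
        score = silhouette_score(dist, flat, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score = kk, score
    return best_k


def dendrogram_text(result: ClusteringResult) -> str:
    """Plain-text dendrogram export: one merge per line with its height."""
    n = len(result.order)
    members: dict[int, list[str]] = {i: [e] for i, e in enumerate(result.order)}
    lines = ["# merge\theight\tmembers"]
    for step, (a, b, h, _cnt) in enumerate(result.linkage_matrix):
        merged = sorted(members[int(a)] + members[int(b)])
        members[n + step] = merged
        lines.append(f"{step + 1}\t{h:.6g}\t{','.join(merged)}")
    return "\n".join(lines) + "\n"


def assign_index(
    labels: pd.Series,
    area: StudyArea,
    stations: list[MonitorStation],
) -> IndexAssignment:
    """Map each unit to the spatially nearest station of its cluster.

    Distance is planar Euclidean; exact ties resolve to the
    lexicographically smallest station id (and are logged). Units whose
    cluster contains no station make the assignment impossible and raise
    :class:`StationCoverageError` listing them all.
    """
    st_by_id = {s.station_id: s for s in stations}
    unit_by_id = {u.unit_id: u for u in area.units}
    unit_ids = [u for u in labels.index if u in unit_by_id]
    station_ids = [s for s in labels.index if s in st_by_id]

    orphans = []
    index_of: dict[str, str] = {}
    for uid in unit_ids:
        lab = labels[uid]
        cands = [sid for sid in station_ids if labels[sid] == lab]
        if not cands:
            orphans.append(uid)
            continue
        u = unit_by_id[uid]
        ranked = sorted(
            cands,
            key=lambda sid: (
                float(np.hypot(st_by_id[sid].x - u.x, st_by_id[sid].y - u.y)),
                sid,
            ),
        )
        if len(ranked) > 1:
            d0 = np.hypot(st_by_id[ranked[0]].x - u.x, st_by_id[ranked[0]].y - u.y)
            d1 = np.hypot(st_by_id[ranked[1]].x - u.x, st_by_id[ranked[1]].y - u.y)
            if d0 == d1:
                logger.info(
                    "unit %s: distance tie between stations %s and %s; "
                    "choosing %s (lexicographic)",
                    uid, ranked[0], ranked[1], ranked[0],
                )
        index_of[uid] = ranked[0]
    if orphans:
        raise StationCoverageError(
            f"clusters without any station leave units unassigned: {sorted(orphans)}"
        )
    return IndexAssignment(cluster_labels=labels, index_of=index_of)
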