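"""Density-based clustering primitives (DBSCAN) implemented from scratch.

The clustering dialect is fixed so that results are reproducible and
comparable against reference implementations:

* Euclidean distance;
* closed-ball neighbourhoods (``distance <= eps``) that include the query
  point itself;
* a point is CORE when its eps-neighbourhood holds at least ``min_pts``
  points, BORDER when it is not core but lies within ``eps`` of some core
  point, and NOISE otherwise;
* border points reachable from several clusters are claimed by whichever
  cluster's expansion reaches them first under a deterministic
  ascending-id scan, so the output is independent of input order.

Noise points never carry a cluster id; in the vital-sign pipeline they are
interpreted as anomalous readings.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NOISE",
    "DataPoint",
    "DBSCANParams",
    "PointRole",
    "ClusteringResult",
    "distance",
    "eps_neighborhood",
    "point_role",
    "dbscan",
]

#: Sentinel label for points that belong to no cluster.
NOISE = -1

PointId = Hashable


@dataclass(frozen=True)
class DataPoint:
    """One observation embedded in feature space.

    ``coords`` holds the measured attribute values in their native units,
    one entry per attribute; ``time`` is carried as metadata only and never
    enters a distance computation.
    """

    id: PointId
    coords: tuple[float, ...]
    time: object | None = None

    def __post_init__(self) -> None:
        coords = tuple(float(c) for c in self.coords)
        if len(coords) == 0:
            raise ValueError("coords must be non-empty")
        if not all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinate in point {self.id!r}: {coords}")
        object.__setattr__(self, "coords", coords)

    @property
    def ndim(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class DBSCANParams:
    """Neighbourhood radius ``eps`` and core threshold ``min_pts``."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eps) and self.eps > 0):
            raise ValueError(f"eps must be a positive finite real, got {self.eps}")
        if int(self.min_pts) != self.min_pts or self.min_pts < 1:
            raise ValueError(f"min_pts must be an integer >= 1, got {self.min_pts}")
        object.__setattr__(self, "eps", float(self.eps))
        object.__setattr__(self, "min_pts", int(self.min_pts))


class PointRole(enum.Enum):
    CORE = "core"
    BORDER = "border"
    NOISE = "noise"


@dataclass
class ClusteringResult:
    """Labels and roles for every input point of one clustering run.

    ``labels`` maps each point id to a dense non-negative cluster id, or to
    :data:`NOISE`.  Every cluster contains at least one CORE point, and
    NOISE points never carry a cluster id.
    """

    labels: dict[PointId, int]
    roles: dict[PointId, PointRole]
    params: DBSCANParams

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.roles):
            raise ValueError("labels and roles must cover the same points")
        for pid, lab in self.labels.items():
            if (lab == NOISE) != (self.roles[pid] is PointRole.NOISE):
                raise ValueError(f"label/role mismatch for point {pid!r}")

    @property
    def n_clusters(self) -> int:
        return len({l for l in self.labels.values() if l != NOISE})

    @property
    def noise_ids(self) -> set[PointId]:
        return {p for p, l in self.labels.items() if l == NOISE}

    def clusters(self) -> dict[int, set[PointId]]:
        """Cluster id -> member ids (noise excluded)."""
        out: dict[int, set[PointId]] = {}
        for pid, lab in self.labels.items():
            if lab != NOISE:
                out.setdefault(lab, set()).add(pid)
        return out

    def core_ids(self) -> set[PointId]:
        return {p for p, r in self.roles.items() if r is PointRole.CORE}


# ---------------------------------------------------------------------------
# Point-set plumbing


def as_point_map(points: Iterable[DataPoint] | Mapping[PointId, DataPoint]) -> dict[PointId, DataPoint]:
    """Normalise a collection of points to an id -> DataPoint mapping."""
    if isinstance(points, Mapping):
        pmap = dict(points)
    else:
        pmap = {}
        for p in points:
            if p.id in pmap:
                raise ValueError(f"duplicate point id {p.id!r}")
            pmap[p.id] = p
    if not pmap:
        raise ValueError("empty dataset")
    dims = {p.ndim for p in pmap.values()}
    if len(dims) > 1:
        raise ValueError(f"points have mixed dimensionality: {sorted(dims)}")
    return pmap


def _sorted_ids(ids: Iterable[PointId]) -> list[PointId]:
    """Deterministic ordering of ids; falls back to string order for mixed types."""
    ids = list(ids)
    try:
        return sorted(ids)
    except TypeError:
        return sorted(ids, key=lambda i: (type(i).__name__, str(i)))


# ---------------------------------------------------------------------------
# Primitive operations


def distance(a: DataPoint, b: DataPoint) -> float:
    """Euclidean distance between two points of equal dimensionality."""
    if a.ndim != b.ndim:
        raise ValueError(f"dimensionality mismatch: {a.ndim} vs {b.ndim}")
    av = np.asarray(a.coords)
    bv = np.asarray(b.coords)
    return float(np.sqrt(np.sum((av - bv) ** 2)))


def eps_neighborhood(
    points: Iterable[DataPoint] | Mapping[PointId, DataPoint],
    q: PointId,
    eps: float,
) -> set[PointId]:
    """All ids within the closed ball of radius ``eps`` around ``q`` (incl. ``q``)."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    pmap = as_point_map(points)
    if q not in pmap:
        raise KeyError(f"unknown point id {q!r}")
    qv = np.asarray(pmap[q].coords)
    ids = list(pmap)
    X = np.asarray([pmap[i].coords for i in ids])
    d = np.sqrt(np.sum((X - qv) ** 2, axis=1))
    return {i for i, di in zip(ids, d) if di <= eps}


def point_role(
    points: Iterable[DataPoint] | Mapping[PointId, DataPoint],
    q: PointId,
    params: DBSCANParams,
) -> PointRole:
    """Role of ``q``: CORE, BORDER (within eps of a core) or NOISE."""
    pmap = as_point_map(points)
    if q not in pmap:
        raise KeyError(f"unknown point id {q!r}")
    neigh, core = _neighbourhoods(pmap, params)
    if core[q]:
        return PointRole.CORE
    if any(core[n] for n in neigh[q]):
        return PointRole.BORDER
    return PointRole.NOISE


def _neighbourhoods(
    pmap: Mapping[PointId, DataPoint], params: DBSCANParams
) -> tuple[dict[PointId, list[PointId]], dict[PointId, bool]]:
    """Closed-ball neighbour lists (sorted ids) and core flags for all points."""
    ids = _sorted_ids(pmap)
    X = np.asarray([pmap[i].coords for i in ids], dtype=float)
    # desk-scale n: the O(n^2) pairwise scan is exact and fast enough
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    within = np.sqrt(d2) <= params.eps
    neigh = {ids[i]: [ids[j] for j in np.flatnonzero(within[i])] for i in range(len(ids))}
    core = {i: len(neigh[i]) >= params.min_pts for i in ids}
    return neigh, core


def dbscan(
    points: Iterable[DataPoint] | Mapping[PointId, DataPoint],
    params: DBSCANParams,
) -> ClusteringResult:
    """Cluster ``points`` into maximal density-connected sets.

    Clusters are numbered densely from 0 in order of discovery under an
    ascending-id scan, which makes the labelling deterministic and
    independent of input order.  A single isolated point never forms a
    cluster (unless ``min_pts == 1``, in which case every point is core).
    """
    pmap = as_point_map(points)
    neigh, core = _neighbourhoods(pmap, params)

    labels: dict[PointId, int] = {}
    next_label = 0
    for seed in _sorted_ids(pmap):
        if not core[seed] or seed in labels:
            continue
        # breadth-first expansion from the unvisited core point
        labels[seed] = next_label
        queue: deque[PointId] = deque([seed])
        while queue:
            cur = queue.popleft()
            if not core[cur]:
                continue  # border points join but do not extend the cluster
            for nb in neigh[cur]:
                if nb not in labels:
                    labels[nb] = next_label
                    queue.append(nb)
        next_label += 1

    roles: dict[PointId, PointRole] = {}
    out_labels: dict[PointId, int] = {}
    for pid in pmap:
        if core[pid]:
            roles[pid] = PointRole.CORE
            out_labels[pid] = labels[pid]
        elif pid in labels:
            roles[pid] = PointRole.BORDER
            out_labels[pid] = labels[pid]
        else:
            roles[pid] = PointRole.NOISE
            out_labels[pid] = NOISE
    return ClusteringResult(labels=out_labels, roles=roles, params=params)
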