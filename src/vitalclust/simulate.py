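"""Seeded synthetic vital-sign datasets with known cluster structure.

Emulates the structure the pipeline targets: one or more dense Gaussian
clusters of normal readings (blood pressure, body temperature, pulse)
plus a handful of isolated anomalous readings placed at a guaranteed
distance from every cluster mean.  Ground-truth labels ride along so
recovery can be scored exactly.

The defaults model a stable adult inpatient: systolic 120±8 mmHg,
diastolic 80±6 mmHg, temperature 36.8±0.3 °C, pulse 72±6 beats/min,
120 readings over 24 hours, plus 6 anomalies at offset ≥ 60 feature
units from the cluster mean.  All draws flow from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .pipeline import VITAL_NAMES, VitalRecord

__all__ = [
    "ANOMALY",
    "ClusterSpec",
    "GeneratorSpec",
    "LabeledDataset",
    "DEFAULT_CLUSTER",
    "generate",
    "generate_partitioned",
]

#: Truth label for injected anomalous readings.
ANOMALY = "ANOMALY"

_EPOCH = datetime(2021, 1, 1)


@dataclass(frozen=True)
class ClusterSpec:
    """One dense cluster: per-vital mean and spread, and how many readings."""

    mean: tuple[float, float, float, float]  # systolic, diastolic, temperature, pulse
    spread: tuple[float, float, float, float]
    count: int

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("count must be positive")
        if any(s <= 0 for s in self.spread):
            raise ValueError("spreads must be positive")


DEFAULT_CLUSTER = ClusterSpec(
    mean=(120.0, 80.0, 36.8, 72.0),
    spread=(8.0, 6.0, 0.3, 6.0),
    count=120,
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic dataset.

    ``anomaly_offset`` is the minimum Euclidean distance (in raw feature
    units) every anomaly keeps from every cluster mean; placements are
    rejection-sampled with a bounded retry budget.
    """

    clusters: tuple[ClusterSpec, ...] = (DEFAULT_CLUSTER,)
    anomaly_count: int = 6
    anomaly_offset: float = 60.0
    time_span: timedelta = timedelta(hours=24)
    seed: int = 0
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("at least one cluster required")
        if self.anomaly_count < 0:
            raise ValueError("anomaly_count must be >= 0")
        if self.anomaly_offset <= 0:
            raise ValueError("anomaly_offset must be positive")


@dataclass
class LabeledDataset:
    """Records plus ground truth: record index -> cluster index or ANOMALY."""

    records: list[VitalRecord]
    truth: dict[int, int | str]

    def __post_init__(self) -> None:
        if set(self.truth) != set(range(len(self.records))):
            raise ValueError("truth must label every record exactly once")

    @property
    def anomaly_ids(self) -> set[int]:
        return {i for i, t in self.truth.items() if t == ANOMALY}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "time": [r.time.isoformat() for r in self.records],
                **{v: [r.vital(v) for r in self.records] for v in VITAL_NAMES},
            }
        )


def _draw_anomaly(rng: np.random.Generator, means: np.ndarray, offset: float, retries: int = 200) -> np.ndarray:
    """One anomalous reading >= offset from every cluster mean (rejection sampled)."""
    d = means.shape[1]
    for _ in range(retries):
        base = means[rng.integers(len(means))]
        direction = rng.standard_normal(d)
        direction /= np.linalg.norm(direction)
        radius = offset * (1.0 + rng.random())  # in [offset, 2*offset)
        cand = base + radius * direction
        if np.all(np.linalg.norm(means - cand, axis=1) >= offset) and np.all(cand > 0):
            return cand
    raise RuntimeError(
        f"could not place an anomaly >= {offset} from every cluster mean "
        f"after {retries} attempts; reduce anomaly_offset or cluster density"
    )


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a labeled dataset from the spec; byte-identical under the same seed.

    Per-cluster vitals are independent normals around the cluster mean;
    timestamps are uniform over ``time_span`` and sorted so acquisition
    order is chronological.  Every anomaly's distance to every cluster
    mean is asserted ``>= anomaly_offset`` at generation time.
    """
    rng = np.random.default_rng(spec.seed)
    means = np.asarray([c.mean for c in spec.clusters], dtype=float)

    rows: list[np.ndarray] = []
    labels: list[int | str] = []
    for ci, c in enumerate(spec.clusters):
        X = np.asarray(c.mean) + rng.standard_normal((c.count, 4)) * np.asarray(c.spread)
        X = np.abs(X)  # vitals are physically positive; reflect the rare negative tail
        rows.extend(X)
        labels.extend([ci] * c.count)
    for _ in range(spec.anomaly_count):
        a = _draw_anomaly(rng, means, spec.anomaly_offset)
        assert np.all(np.linalg.norm(means - a, axis=1) >= spec.anomaly_offset)
        rows.append(a)
        labels.append(ANOMALY)

    n = len(rows)
    offsets = np.sort(rng.random(n)) * spec.time_span.total_seconds()
    times = [_EPOCH + timedelta(seconds=float(s)) for s in offsets]
    # shuffle which reading lands on which timestamp so clusters interleave in time
    perm = rng.permutation(n)
    records = [
        VitalRecord(
            subject_id=spec.subject_id,
            time=times[k],
            systolic=float(rows[i][0]),
            diastolic=float(rows[i][1]),
            temperature=float(rows[i][2]),
            pulse=float(rows[i][3]),
        )
        for k, i in enumerate(perm)
    ]
    truth = {k: labels[i] for k, i in enumerate(perm)}
    return LabeledDataset(records=records, truth=truth)


def generate_partitioned(
    spec: GeneratorSpec,
    cut_coordinate: float,
    straddle_count: int = 6,
    straddle_spread: float = 2.0,
    straddle_gap: float = 1.0,
) -> LabeledDataset:
    """Add a sparse cluster straddling a partition cut on the first vital.

    The straddling cluster's readings are placed symmetrically around
    ``cut_coordinate`` on the first (systolic) axis, half strictly below
    and half strictly above, so a slab cut at that coordinate leaves fewer
    than MinPts members per side whenever ``straddle_count / 2 < MinPts``
    — exactly the situation where local clustering calls all of them
    noise and only pooled re-clustering can recover the class.  With
    ``straddle_count == 0`` this reduces to :func:`generate`.
    """
    base = generate(spec)
    if straddle_count == 0:
        return base
    if straddle_count < 2:
        raise ValueError("straddle_count must be 0 or >= 2")

    rng = np.random.default_rng(spec.seed + 1)
    new_cluster_index = len(spec.clusters)
    tpl = spec.clusters[0]
    n_low = straddle_count // 2
    records = list(base.records)
    truth = dict(base.truth)
    t0 = max(r.time for r in records)
    for k in range(straddle_count):
        side = -1.0 if k < n_low else 1.0
        x0 = cut_coordinate + side * (straddle_gap + straddle_spread * rng.random())
        others = np.asarray(tpl.mean[1:]) + rng.standard_normal(3) * np.asarray(tpl.spread[1:]) * 0.25
        idx = len(records)
        records.append(
            VitalRecord(
                subject_id=spec.subject_id,
                time=t0 + timedelta(seconds=60 * (k + 1)),
                systolic=float(x0),
                diastolic=float(abs(others[0])),
                temperature=float(abs(others[1])),
                pulse=float(abs(others[2])),
            )
        )
        truth[idx] = new_cluster_index
    return LabeledDataset(records=records, truth=truth)
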