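from datetime import datetime, timedelta

import numpy as np
import pytest

from vitalclust import ClusterSpec, DataPoint, DBSCANParams, GeneratorSpec, VitalRecord


def make_points(coords_list, ids=None):
    ids = ids if ids is not None else range(len(coords_list))
    return [DataPoint(id=i, coords=tuple(c)) for i, c in zip(ids, coords_list)]


def random_points(rng, n, d, scale=10.0):
    return make_points(rng.uniform(0, scale, size=(n, d)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blobs_and_outlier():
    """Two dense 2-d blobs separated far beyond eps plus one distant point.

    With eps=1.5, min_pts=3 the construction guarantees 2 clusters + 1 noise:
    within-blob spacing <= 1, blob separation 50, outlier 100 away.
    """
    blob_a = [(0, 0), (1, 0), (0, 1), (1, 1)]
    blob_b = [(50, 50), (51, 50), (50, 51), (51, 51)]
    outlier = [(150, 150)]
    return make_points(blob_a + blob_b + outlier), DBSCANParams(eps=1.5, min_pts=3)


def make_records(values, t0=datetime(2021, 1, 1), step_minutes=10, subject="S1"):
    """Records from (systolic, diastolic, temperature, pulse) tuples."""
    return [
        VitalRecord(
            subject_id=subject,
            time=t0 + timedelta(minutes=step_minutes * k),
            systolic=v[0],
            diastolic=v[1],
            temperature=v[2],
            pulse=v[3],
        )
        for k, v in enumerate(values)
    ]


@pytest.fixture
def tight_spec():
    """A compact generator spec used where runtime matters more than scale."""
    return GeneratorSpec(
        clusters=(ClusterSpec((120, 80, 36.8, 72), (4, 3, 0.2, 3), 40),),
        anomaly_count=2,
        anomaly_offset=60.0,
        seed=7,
    )
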