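"""Tests for partitioned clustering and the cross-partition merge rules."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalclust import (
    DBSCANParams,
    MergeVerdict,
    Partition,
    PartitionConfig,
    PointRole,
    absorb_noise,
    boundary_merge_test,
    cluster_partition,
    dbscan,
    distance,
    merge_all,
    merge_overlap,
    partition_data,
    partitioned_dbscan,
    recluster_noise,
)
from vitalclust.partition import LocalCluster

from conftest import make_points, random_points


class TestPartitionData:
    def test_single_partition_has_no_overlaps(self, rng):
        pts = random_points(rng, 10, 2)
        (p,) = partition_data(pts, 1)
        assert p.member_ids == {q.id for q in pts}
        assert not p.overlap_left and not p.overlap_right

    def test_line_halves_at_median_cut(self):
        pts = make_points([(float(i), 0.0) for i in range(10)])
        left, right = partition_data(pts, 2, overlap_width=0.0)
        assert left.member_ids == set(range(5))
        assert right.member_ids == set(range(5, 10))
        assert left.upper == right.lower == 4.5

    def test_degenerate_overlap_spans_everything(self):
        pts = make_points([(float(i), 0.0) for i in range(10)])
        left, right = partition_data(pts, 2, overlap_width=100.0)
        assert left.member_ids == right.member_ids == set(range(10))

    def test_overlap_contains_exactly_points_near_cut(self):
        pts = make_points([(float(i), 0.0) for i in range(10)])
        left, right = partition_data(pts, 2, overlap_width=1.0)
        # cut at 4.5; points 4 and 5 are within 1.0 of it
        assert left.overlap_right == right.overlap_left == {4, 5}

    def test_partitions_cover_all_points(self, rng):
        pts = random_points(rng, 37, 3)
        parts = partition_data(pts, 4, overlap_width=0.5)
        assert set().union(*(p.member_ids for p in parts)) == {q.id for q in pts}

    def test_more_partitions_than_points_rejected(self):
        with pytest.raises(ValueError):
            partition_data(make_points([(0.0,), (1.0,)]), 3)


class TestClusterPartition:
    def test_whole_dataset_partition_reduces_to_dbscan(self, two_blobs_and_outlier):
        pts, params = two_blobs_and_outlier
        (part,) = partition_data(pts, 1, eps_per_partition=params.eps)
        lc = cluster_partition(part, pts, params.min_pts)
        ref = dbscan(pts, params)
        assert {frozenset(c.members) for c in lc.clusters} == {
            frozenset(m) for m in ref.clusters().values()
        }
        assert lc.noise_ids == ref.noise_ids

    def test_straddling_blob_seen_from_both_sides(self):
        # dense blob centred on the cut between two slabs of background points
        blob = [(9.5 + 0.25 * k, 0.0) for k in range(5)]  # 9.5..10.5
        wings = [(0.0, 0.0), (1.0, 0.0), (19.0, 0.0), (20.0, 0.0)]
        pts = make_points(blob + wings)
        parts = partition_data(pts, 2, overlap_width=1.5, eps_per_partition=[1.0, 1.0])
        lcs = [cluster_partition(p, pts, 3) for p in parts]
        for lc in lcs:
            blob_clusters = [c for c in lc.clusters if set(range(5)) & c.members]
            assert len(blob_clusters) == 1

    def test_blob_inside_one_partition_invisible_to_other(self):
        blob = [(1.0 + 0.3 * k, 0.0) for k in range(5)]
        far = [(100.0, 0.0), (101.0, 0.0)]
        pts = make_points(blob + far)
        parts = partition_data(pts, 2, overlap_width=0.0, eps_per_partition=[1.0, 1.0])
        right = cluster_partition(parts[1], pts, 3)
        assert all(not (set(range(5)) & c.members) for c in right.clusters)

    def test_boundary_set_members_lie_near_cut(self):
        pts = make_points([(float(i), 0.0) for i in range(10)])
        parts = partition_data(pts, 2, overlap_width=0.0, eps_per_partition=[1.5, 1.5])
        lc = cluster_partition(parts[0], pts, 2)
        (cluster,) = lc.clusters
        cut = parts[0].upper
        for m in cluster.boundary_set:
            assert abs(pts[m].coords[0] - cut) <= 1.5
        assert cluster.boundary_set == {3, 4}


def _mk_cluster(pid, cid, members, cores, boundary=()):
    return LocalCluster(
        partition_id=pid,
        cluster_id=cid,
        members=frozenset(members),
        core_members=frozenset(cores),
        boundary_set=frozenset(boundary),
    )


class TestMergeOverlapRules:
    """The four cases for a point clustered twice in an overlap zone."""

    A = _mk_cluster(0, 0, {1, 2, 3}, {2})
    B = _mk_cluster(1, 0, {1, 5, 6}, {5})

    def test_core_on_either_side_merges(self):
        A = _mk_cluster(0, 0, {1, 2, 3}, {1, 2})
        assert merge_overlap(A, self.B, 1, PointRole.CORE, PointRole.BORDER).verdict is MergeVerdict.MERGE

        A2 = _mk_cluster(0, 0, {1, 2}, {1, 2})
        B2 = _mk_cluster(1, 0, {1, 9}, {1, 9})
        assert merge_overlap(A2, B2, 1, PointRole.CORE, PointRole.CORE).verdict is MergeVerdict.MERGE

    def test_border_in_both_may_join_either(self):
        dec = merge_overlap(self.A, self.B, 1, PointRole.BORDER, PointRole.BORDER)
        assert dec.verdict is MergeVerdict.ASSIGN_EITHER
        assert dec.target is None

    def test_member_one_side_noise_other_joins_its_cluster(self):
        dec = merge_overlap(self.A, None, 3, PointRole.BORDER, PointRole.NOISE)
        assert dec.verdict is MergeVerdict.ASSIGN_TO_ONE
        assert dec.target == (0, 0)
        dec = merge_overlap(None, self.B, 6, PointRole.NOISE, PointRole.BORDER)
        assert dec.target == (1, 0)

    def test_noise_in_both_stays_noise(self):
        dec = merge_overlap(None, None, 42, PointRole.NOISE, PointRole.NOISE)
        assert dec.verdict is MergeVerdict.NOISE

    def test_point_outside_cluster_rejected(self):
        with pytest.raises(ValueError):
            merge_overlap(self.A, self.B, 99, PointRole.BORDER, PointRole.BORDER)


class TestBoundaryMergeTest:
    def test_single_pair_statistic_is_the_distance(self):
        pts = make_points([(0.0, 0.0), (3.0, 4.0)])
        dec = boundary_merge_test({0}, {1}, eps_i=6.0, eps_j=5.5, points=pts)
        assert dec.statistic == pytest.approx(5.0)
        assert dec.verdict is MergeVerdict.MERGE

    def test_single_pair_beyond_eps_min_does_not_merge(self):
        pts = make_points([(0.0, 0.0), (3.0, 4.0)])
        dec = boundary_merge_test({0}, {1}, eps_i=6.0, eps_j=4.9, points=pts)
        assert dec.verdict is MergeVerdict.NOISE

    def test_statistic_equals_double_loop_mean(self, rng):
        for _ in range(10):
            pts = random_points(rng, 20, 3)
            pmap = {p.id: p for p in pts}
            E_A = set(rng.choice(20, size=rng.integers(1, 11), replace=False).tolist())
            E_B = set(rng.choice(20, size=rng.integers(1, 11), replace=False).tolist())
            dec = boundary_merge_test(E_A, E_B, 1.0, 1.0, pts)
            brute = np.mean([distance(pmap[p], pmap[q]) for p in E_A for q in E_B])
            assert dec.statistic == pytest.approx(brute, abs=1e-12)

    def test_symmetry_in_the_two_sets(self, rng):
        pts = random_points(rng, 12, 2)
        d1 = boundary_merge_test({0, 1, 2}, {7, 9}, 1.0, 2.0, pts)
        d2 = boundary_merge_test({7, 9}, {0, 1, 2}, 1.0, 2.0, pts)
        assert d1.statistic == pytest.approx(d2.statistic, abs=1e-15)
        assert d1.verdict == d2.verdict

    def test_statistic_within_pairwise_extremes(self, rng):
        pts = random_points(rng, 15, 2)
        pmap = {p.id: p for p in pts}
        E_A, E_B = {0, 1, 2, 3}, {8, 9, 10}
        dists = [distance(pmap[p], pmap[q]) for p in E_A for q in E_B]
        stat = boundary_merge_test(E_A, E_B, 1, 1, pts).statistic
        assert min(dists) <= stat <= max(dists)

    def test_empty_boundary_set_rejected(self):
        pts = make_points([(0.0,), (1.0,)])
        with pytest.raises(ValueError, match="non-empty"):
            boundary_merge_test(set(), {0}, 1, 1, pts)


class TestAbsorbNoise:
    def test_zero_distance_absorbs(self):
        pts = make_points([(5.0, 5.0), (5.0, 5.0)])
        dec = absorb_noise(0, {1}, eps_next=0.5, points=pts, target=(1, 0))
        assert dec.verdict is MergeVerdict.ASSIGN_TO_ONE and dec.statistic == 0.0

    def test_all_members_beyond_eps_never_absorb(self, rng):
        """A mean is bounded below by its smallest term."""
        pts = make_points([(0.0, 0.0)] + [(10.0 + float(k), 0.0) for k in range(5)])
        dec = absorb_noise(0, {1, 2, 3, 4, 5}, eps_next=9.0, points=pts)
        assert dec.verdict is MergeVerdict.NOISE

    def test_statistic_equals_loop_mean(self, rng):
        pts = random_points(rng, 12, 4)
        pmap = {p.id: p for p in pts}
        E_C = set(rng.choice(np.arange(1, 12), size=8, replace=False).tolist())
        dec = absorb_noise(0, E_C, eps_next=100.0, points=pts, target=(1, 0))
        brute = np.mean([distance(pmap[0], pmap[q]) for q in E_C])
        assert dec.statistic == pytest.approx(brute, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            absorb_noise(0, set(), 1.0, make_points([(0.0,)]))


class TestReclusterNoise:
    def test_empty_noise_yields_nothing(self):
        assert recluster_noise(set(), make_points([(0.0,)]), DBSCANParams(1, 2)) == []

    def test_split_sparse_cluster_recovered_when_pooled(self):
        # 6 points spaced 0.5 apart around x=10; any per-side count < 4
        sparse = make_points([(8.75 + 0.5 * k, 0.0) for k in range(6)])
        out = recluster_noise({p.id for p in sparse}, sparse, DBSCANParams(eps=1.1, min_pts=4))
        assert len(out) == 1
        assert out[0].members == {0, 1, 2, 3, 4, 5}

    def test_far_outlier_stays_noise(self):
        pts = make_points([(0.0, 0.0), (100.0, 100.0), (100.5, 100.0), (100.0, 100.5)])
        out = recluster_noise({0, 1, 2, 3}, pts, DBSCANParams(eps=1.0, min_pts=3))
        assert all(0 not in c.members for c in out)


class TestMergeAll:
    def test_single_partition_equals_plain_dbscan(self, rng):
        pts = random_points(rng, 50, 2, scale=6.0)
        params = DBSCANParams(eps=1.0, min_pts=4)
        a = partitioned_dbscan(pts, params, PartitionConfig(n_partitions=1))
        b = dbscan(pts, params)
        assert a.labels == b.labels and a.roles == b.roles

    def test_shared_core_point_merges_straddling_blob(self):
        blob = [(9.0 + 0.3 * k, 0.0) for k in range(8)]  # spans the cut near 10
        wings = [(0.0, 0.0), (0.5, 0.0), (0.2, 0.4), (20.0, 0.0), (20.5, 0.0), (20.2, 0.4)]
        pts = make_points(blob + wings)
        params = DBSCANParams(eps=1.0, min_pts=3)
        res = partitioned_dbscan(pts, params, PartitionConfig(n_partitions=2, overlap_width=1.0))
        blob_labels = {res.labels[i] for i in range(8)}
        assert len(blob_labels) == 1
        assert res.n_clusters == 3  # blob reported once, plus the two wings

    def test_disjoint_blobs_stay_separate(self):
        a = [(0.0 + 0.2 * k, 0.0) for k in range(5)]
        b = [(100.0 + 0.2 * k, 0.0) for k in range(5)]
        pts = make_points(a + b)
        res = partitioned_dbscan(
            pts, DBSCANParams(eps=0.5, min_pts=3), PartitionConfig(n_partitions=2, overlap_width=0.5)
        )
        assert res.n_clusters == 2
        assert {res.labels[i] for i in range(5)} != {res.labels[i] for i in range(5, 10)}

    def test_eq1_path_merges_cluster_cut_in_two(self):
        # one dense chain cut at its centre with no overlap zone:
        # only the boundary mean-distance criterion can reunite the halves
        chain = [(0.4 * k, 0.0) for k in range(12)]  # 0 .. 4.4, cut near 2.2
        pts = make_points(chain)
        params = DBSCANParams(eps=0.9, min_pts=3)
        res = partitioned_dbscan(pts, params, PartitionConfig(n_partitions=2, overlap_width=0.0))
        assert res.n_clusters == 1
        assert len({res.labels[i] for i in range(12)}) == 1

    def test_merge_verdicts_transitively_consistent(self):
        """Labels are constant within each merged class across three partitions."""
        chain = [(0.3 * k, 0.0) for k in range(30)]
        pts = make_points(chain)
        params = DBSCANParams(eps=0.7, min_pts=3)
        res = partitioned_dbscan(pts, params, PartitionConfig(n_partitions=3, overlap_width=0.7))
        assert res.n_clusters == 1

    def test_agrees_with_plain_dbscan_when_clusters_overlap_covered(self):
        """Well-witnessed clusters: partitioned result equals global DBSCAN up to relabeling."""
        rng = np.random.default_rng(5)
        blobs = [rng.normal(loc=(c, 0), scale=0.3, size=(12, 2)) for c in (0.0, 8.0, 16.0)]
        pts = make_points(np.vstack(blobs))
        params = DBSCANParams(eps=1.0, min_pts=4)
        plain = dbscan(pts, params)
        part = partitioned_dbscan(pts, params, PartitionConfig(n_partitions=2, overlap_width=1.0))
        assert part.noise_ids == plain.noise_ids
        mapping = {}
        for pid, lab in part.labels.items():
            if lab == -1:
                continue
            mapping.setdefault(lab, plain.labels[pid])
            assert mapping[lab] == plain.labels[pid]
        assert len(set(mapping.values())) == len(mapping)

    def test_trace_log_records_verdicts(self):
        chain = [(0.4 * k, 0.0) for k in range(12)]
        pts = make_points(chain)
        buf = io.StringIO()
        partitioned_dbscan(
            pts, DBSCANParams(eps=0.9, min_pts=3),
            PartitionConfig(n_partitions=2, overlap_width=0.0), trace=buf,
        )
        lines = [l for l in buf.getvalue().splitlines() if l]
        assert lines and all(len(l.split("\t")) == 6 for l in lines)
        assert any(l.endswith("merge") for l in lines)
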