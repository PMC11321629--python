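"""ward.D2 linkage and the stepwise hierarchical-averaging consensus."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import diseasemap as dm
from diseasemap.consensus_merge import MergeSchedule
from conftest import random_distance_matrix


def _points_distance(points):
    pts = np.asarray(points, dtype=float)
    d = np.abs(pts[:, None] - pts[None, :])
    return d / d.max()


class TestWardLinkage:
    def test_one_dimensional_toy_merge_order(self):
        d = _points_distance([0, 1, 10, 11])
        merges = dm.ward_linkage(d)
        assert {tuple(m[:2]) for m in merges[:2]} == {(0, 1), (2, 3)}

    def test_two_items_single_merge_at_distance(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        merges = dm.ward_linkage(d)
        assert merges == [(0, 1, pytest.approx(0.6))]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        d = random_distance_matrix(rng, 25).values
        merges = dm.ward_linkage(d)
        heights = [h for _, _, h in merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_ward_on_generic_data(self, seed):
        """Cross-check heights and cut partitions against scipy's ward linkage
        (which implements the same squared-update criterion)."""
        rng = np.random.default_rng(seed)
        d = random_distance_matrix(rng, 20).values
        merges = dm.ward_linkage(d)
        z = linkage(squareform(d), method="ward")
        assert np.allclose(sorted(h for _, _, h in merges), np.sort(z[:, 2]), atol=1e-9)
        sched = MergeSchedule([f"x{i}" for i in range(20)], merges)
        for k in (2, 4, 7):
            ours = sched.cut(k)
            theirs = fcluster(z, k, criterion="maxclust")
            # same partition up to label names
            pairs = {tuple(sorted({tuple(np.flatnonzero(ours == c)) for c in set(ours)}))}
            pairs2 = {tuple(sorted({tuple(np.flatnonzero(theirs == c)) for c in set(theirs)}))}
            assert pairs == pairs2

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        d = random_distance_matrix(rng, 12).values
        perm = rng.permutation(12)
        merges_a = MergeSchedule([f"x{i}" for i in range(12)], dm.ward_linkage(d))
        merges_b = MergeSchedule(
            [f"x{i}" for i in perm], dm.ward_linkage(d[np.ix_(perm, perm)])
        )
        cut_a = merges_a.cut(4)
        cut_b = merges_b.cut(4)
        part_a = {frozenset(np.array(merges_a.leaves)[cut_a == c]) for c in set(cut_a)}
        part_b = {frozenset(np.array(merges_b.leaves)[cut_b == c]) for c in set(cut_b)}
        assert part_a == part_b


class TestBuildSchedule:
    def test_closest_pair_merges_first(self):
        rng = np.random.default_rng(1)
        base = random_distance_matrix(rng, 15)
        near = dm.DistanceMatrix(
            base.disease_ids,
            np.clip(base.values + 0.002 * (random_distance_matrix(rng, 15).values - 0.5), 0, 1),
        )
        far = random_distance_matrix(rng, 15)
        fam = dm.matrix_family_distance([base, near, far], ["A", "B", "C"])
        assert fam.get("A", "B") < min(fam.get("A", "C"), fam.get("B", "C"))
        sched = dm.build_schedule(fam)
        assert tuple(sched.merges[0][:2]) == (0, 1)

    def test_two_matrices_single_merge(self):
        rng = np.random.default_rng(2)
        fam = dm.matrix_family_distance(
            [random_distance_matrix(rng, 8), random_distance_matrix(rng, 8)], ["a", "b"]
        )
        sched = dm.build_schedule(fam)
        assert len(sched.merges) == 1


def _const_matrix(ids, value):
    v = np.full((len(ids), len(ids)), value)
    np.fill_diagonal(v, 0.0)
    return dm.DistanceMatrix(ids, v)


class TestHierarchicalAverage:
    def test_identical_inputs_idempotent(self):
        rng = np.random.default_rng(3)
        m = random_distance_matrix(rng, 10)
        sched = MergeSchedule(["a", "b", "c"], [(0, 1, 0.1), (3, 2, 0.2)])
        cons = dm.hierarchical_average([m, m, m], sched)
        assert np.array_equal(cons.values, m.values)

    def test_hand_arithmetic_unbalanced_schedule(self):
        ids = ["d1", "d2"]
        a = _const_matrix(ids, 0.2)
        b = _const_matrix(ids, 0.4)
        c = _const_matrix(ids, 0.8)
        sched = MergeSchedule(["A", "B", "C"], [(0, 1, 0.1), (3, 2, 0.2)])
        cons = dm.hierarchical_average([a, b, c], sched)
        assert cons.values[0, 1] == pytest.approx(0.55)
        assert cons.weights == {"A": 0.25, "B": 0.25, "C": 0.5}

    def test_balanced_schedule_is_plain_mean(self):
        rng = np.random.default_rng(4)
        mats = [random_distance_matrix(rng, 6) for _ in range(4)]
        mats = [dm.DistanceMatrix(mats[0].disease_ids, m.values) for m in mats]
        sched = MergeSchedule(
            ["a", "b", "c", "d"], [(0, 1, 0.1), (2, 3, 0.1), (4, 5, 0.2)]
        )
        cons = dm.hierarchical_average(mats, sched)
        assert np.allclose(cons.values, np.mean([m.values for m in mats], axis=0))
        assert all(w == pytest.approx(0.25) for w in cons.weights.values())

    def test_convexity_reconstruction_exact(self):
        rng = np.random.default_rng(5)
        mats = [random_distance_matrix(rng, 9) for _ in range(5)]
        mats = [dm.DistanceMatrix(mats[0].disease_ids, m.values) for m in mats]
        fam = dm.matrix_family_distance(mats, list("abcde"))
        cons = dm.hierarchical_average(mats, dm.build_schedule(fam))
        rebuilt = sum(
            cons.weights[l] * m.values for l, m in zip("abcde", mats)
        )
        assert np.abs(cons.values - rebuilt).max() <= 1e-12
        assert sum(cons.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        sched = MergeSchedule(["a", "b"], [(0, 1, 0.1)])
        with pytest.raises(dm.FormatError):
            dm.hierarchical_average(
                [random_distance_matrix(rng, 4), random_distance_matrix(rng, 5)], sched
            )


class TestDimensionConsensus:
    def test_identical_dimensions_idempotent(self):
        rng = np.random.default_rng(7)
        m = random_distance_matrix(rng, 12)
        cons, fam = dm.dimension_consensus({f"dim{i}": m for i in range(6)})
        assert np.array_equal(cons.values, m.values)
        assert fam.values.max() == 0.0

    def test_entries_within_input_envelope(self, consensus_chain):
        dim_cons, consensus, _, _ = consensus_chain
        stack = np.stack([m.values for m in dim_cons.values()])
        assert (consensus.values >= stack.min(axis=0) - 1e-12).all()
        assert (consensus.values <= stack.max(axis=0) + 1e-12).all()

    def test_outlier_dimension_gets_isolated_weight(self):
        """An outlier merging last keeps weight 1/2; each member of a
        redundant pair ends up with less."""
        rng = np.random.default_rng(8)
        base = random_distance_matrix(rng, 12)
        family = {}
        for i in range(5):
            jitter = 0.002 * (random_distance_matrix(rng, 12).values - 0.5)
            family[f"redundant{i}"] = dm.DistanceMatrix(
                base.disease_ids, np.clip(base.values + jitter, 0, 1)
            )
        family["outlier"] = random_distance_matrix(rng, 12)
        cons, _ = dm.dimension_consensus(family)
        redundant_w = [v for k, v in cons.weights.items() if k != "outlier"]
        assert cons.weights["outlier"] == pytest.approx(0.5)
        assert max(redundant_w) < 0.5


@pytest.mark.parametrize("seed", range(10))
def test_metric_consensus_tightens_planted_clusters(seed):
    """Mean within-cluster consensus distance never exceeds the worst single
    metric's mean within-cluster distance."""
    tables, truth = dm.generate(dm.SyntheticConfig(n_diseases=30, seed=seed))
    inc = dm.to_incidence(tables["genes"])
    labels = truth.labels_for(inc.disease_ids)
    same = (labels[:, None] == labels[None, :]) & ~np.eye(len(labels), dtype=bool)
    mats = dm.all_metric_matrices(inc)
    cons, _ = dm.metric_consensus(mats)
    worst = max(m.values[same].mean() for m in mats.values())
    assert cons.values[same].mean() <= worst + 1e-12


def test_newick_export_parses_with_heights():
    sched = MergeSchedule(["A", "B", "C"], [(0, 1, 0.1), (3, 2, 0.3)])
    nwk = sched.to_newick()
    assert nwk.endswith(";") and "A:0.1" in nwk and "C:0.3" in nwk
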