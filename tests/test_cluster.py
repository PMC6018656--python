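import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from consensusclick.cluster import (
    ConstrainedWard,
    aggregate_subject,
    build_merge_tree,
    consensus_from_cluster,
    constrained_cut,
    merge_tree_to_dict,
)
from _oracles import (
    coarsest_admissible_tree_partition,
    labels_to_partition,
    min_variance_partition,
)


def click_frame(points, volunteers, labels=None):
    labels = labels or ["adult"] * len(points)
    return pd.DataFrame(
        {
            "subject_id": "S1",
            "volunteer_id": volunteers,
            "session_id": "1",
            "x": [p[0] for p in points],
            "y": [p[1] for p in points],
            "label": labels,
        }
    )


class TestMergeTree:
    def test_two_clicks_merge_at_ward_height(self):
        # for two singletons the Ward merge height equals their distance
        tree = build_merge_tree(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert tree.shape == (1, 4)
        assert tree[0, 2] == pytest.approx(5.0)

    def test_two_distant_pairs_merge_within_pair_first(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [500.0, 0.0], [501.0, 0.0]])
        tree = build_merge_tree(coords)
        first_two = {frozenset({int(tree[i, 0]), int(tree[i, 1])}) for i in range(2)}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_identical_coordinates_merge_at_height_zero(self):
        tree = build_merge_tree(np.array([[7.0, 7.0], [7.0, 7.0]]))
        assert tree[0, 2] == 0.0

    def test_single_click_degenerate_tree(self):
        assert build_merge_tree(np.array([[1.0, 2.0]])) is None
        assert merge_tree_to_dict(None) == {"n_leaves": 1, "merges": []}

    def test_zero_clicks_rejected(self):
        with pytest.raises(ValueError):
            build_merge_tree(np.empty((0, 2)))


class TestConstrainedCut:
    def test_distinct_volunteers_form_one_cluster(self):
        rng = np.random.default_rng(0)
        coords = rng.normal([500, 300], 3, size=(10, 2))
        tree = build_merge_tree(coords)
        labels = constrained_cut(tree, [f"v{i}" for i in range(10)])
        assert set(labels) == {0}

    def test_repeat_clicker_splits_tight_group(self):
        # u1 and u2 each click twice: the cut must pair by x-proximity,
        # giving two clusters of two with one click from each volunteer
        coords = np.array(
            [[100.0, 100.0], [110.0, 100.0], [101.0, 101.0], [111.0, 101.0]]
        )
        volunteers = ["u1", "u1", "u2", "u2"]
        labels = constrained_cut(build_merge_tree(coords), volunteers)
        partition = labels_to_partition(labels)
        assert partition == {frozenset({0, 2}), frozenset({1, 3})}

    def test_two_distant_groups_of_five_volunteers(self):
        rng = np.random.default_rng(1)
        group_a = rng.normal([100, 100], 2, size=(5, 2))
        group_b = rng.normal([500, 100], 2, size=(5, 2))
        coords = np.vstack([group_a, group_b])
        volunteers = [f"v{i}" for i in range(5)] * 2
        labels = constrained_cut(build_merge_tree(coords), volunteers)
        partition = labels_to_partition(labels)
        assert partition == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_single_click(self):
        assert list(constrained_cut(None, ["v1"])) == [0]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_coarsest_admissible_tree_partition(self, seed):
        """Greedy top-down cut equals exhaustive search over all
        volunteer-admissible tree-respecting partitions."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        coords = rng.uniform(0, 200, size=(n, 2))
        volunteers = [f"v{rng.integers(1, 5)}" for _ in range(n)]
        tree = build_merge_tree(coords)
        labels = constrained_cut(tree, volunteers)
        assert labels_to_partition(labels) == coarsest_admissible_tree_partition(
            tree, volunteers
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_min_variance_partition_when_well_separated(self, seed):
        """With inter-group separation >= 10x intra-group spread the cut
        equals the unrestricted variance-minimising admissible partition."""
        rng = np.random.default_rng(100 + seed)
        centres = np.array([[100.0, 100.0], [400.0, 120.0], [250.0, 400.0]])
        n_groups = int(rng.integers(2, 4))
        n_vols = int(rng.integers(2, 1 + 8 // n_groups))
        spread = 3.0  # separation >= 300 px, ~100x the spread
        coords, volunteers = [], []
        for v in range(n_vols):
            for c in range(n_groups):
                coords.append(rng.normal(centres[c], spread))
                volunteers.append(f"v{v}")
        coords = np.array(coords)
        labels = constrained_cut(build_merge_tree(coords), volunteers)
        oracle, _ = min_variance_partition(coords, volunteers)
        assert labels_to_partition(labels) == oracle

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_and_constraint_invariants(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(1, 30))
        coords = rng.uniform(0, 1000, size=(n, 2))
        volunteers = [f"v{rng.integers(1, 8)}" for _ in range(n)]
        tree = build_merge_tree(coords) if n > 1 else None
        labels = constrained_cut(tree, volunteers)
        # partition: every click in exactly one cluster
        assert len(labels) == n and (labels >= 0).all()
        sizes = np.bincount(labels)
        assert sizes.sum() == n
        # constraint: no volunteer twice within a cluster
        for k in range(labels.max() + 1):
            vols = [volunteers[i] for i in np.flatnonzero(labels == k)]
            assert len(set(vols)) == len(vols)


class TestConstrainedWardEstimator:
    def test_sklearn_api(self):
        est = ConstrainedWard()
        assert est.get_params() == {}
        cloned = clone(est)
        X = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 100.0]])
        labels = cloned.fit_predict(X, volunteers=["a", "a", "b"])
        assert hasattr(cloned, "labels_")
        assert cloned.n_clusters_ == len(set(labels))
        assert cloned.n_features_in_ == 2

    def test_no_volunteers_means_vacuous_constraint(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 100.0]])
        est = ConstrainedWard().fit(X)
        assert est.n_clusters_ == 1

    def test_dimension_and_length_validation(self):
        with pytest.raises(ValueError):
            ConstrainedWard().fit(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ConstrainedWard().fit(np.zeros((3, 2)), volunteers=["a"])

    def test_cluster_centers_are_medians(self):
        X = np.array([[10.0, 1.0], [12.0, 2.0], [11.0, 9.0]])
        est = ConstrainedWard().fit(X, volunteers=["a", "b", "c"])
        assert est.cluster_centers(X).tolist() == [[11.0, 2.0]]


class TestConsensusFromCluster:
    def test_probabilities_are_label_fractions(self):
        cluster = click_frame(
            [(float(i), 0.0) for i in range(10)],
            [f"v{i}" for i in range(10)],
            labels=["adult"] * 7 + ["chick"] * 3,
        )
        rec = consensus_from_cluster(cluster, n_yes_volunteers=10)
        assert rec.probability_of_adult == pytest.approx(0.7)
        assert rec.probability_of_chick == pytest.approx(0.3)
        assert rec.probability_of_egg == 0.0
        assert rec.probability_of_true_positive == 1.0
        assert rec.num_markings == 10

    def test_centre_is_coordinate_wise_median(self):
        cluster = click_frame([(10, 5), (12, 6), (11, 40)], ["a", "b", "c"])
        rec = consensus_from_cluster(cluster, 3)
        assert rec.x_centre == 11.0
        assert rec.y_centre == 6.0

    def test_even_cluster_median_averages_central_pair(self):
        cluster = click_frame([(10, 0), (14, 0), (11, 0), (13, 0)],
                              ["a", "b", "c", "d"])
        assert consensus_from_cluster(cluster, 4).x_centre == 12.0

    def test_markings_over_p_true_recovers_yes_voters(self):
        cluster = click_frame(
            [(float(i), 0.0) for i in range(7)], [f"v{i}" for i in range(7)]
        )
        rec = consensus_from_cluster(cluster, n_yes_volunteers=10)
        assert rec.probability_of_true_positive == pytest.approx(0.7)
        assert rec.num_markings / rec.probability_of_true_positive == pytest.approx(10)

    def test_zero_yes_voters_is_an_error(self):
        cluster = click_frame([(1, 1)], ["a"])
        with pytest.raises(ValueError):
            consensus_from_cluster(cluster, 0)

    def test_more_markings_than_yes_voters_is_an_error(self):
        cluster = click_frame([(1, 1), (2, 2)], ["a", "b"])
        with pytest.raises(ValueError):
            consensus_from_cluster(cluster, 1)


class TestAggregateSubject:
    def test_empty_input_empty_output(self):
        assert aggregate_subject(click_frame([], []), 5) == []

    def test_single_click_with_four_yes_voters(self):
        records = aggregate_subject(click_frame([(50, 50)], ["a"]), 4)
        assert len(records) == 1
        assert records[0].num_markings == 1
        assert records[0].probability_of_true_positive == 0.25

    def test_recovers_planted_targets(self, small_scene, ideal_raw_table):
        from consensusclick.io import read_raw_classifications
        import io

        data = read_raw_classifications(io.StringIO(ideal_raw_table.to_csv(index=False)))
        records = aggregate_subject(
            data.clicks, int(data.yes_denominators().iloc[0])
        )
        assert len(records) == len(small_scene.targets)
        assert all(r.num_markings == 10 for r in records)

    @pytest.mark.parametrize("seed", range(5))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 12
        clicks = click_frame(
            rng.uniform(100, 400, size=(n, 2)).tolist(),
            [f"v{rng.integers(1, 5)}" for _ in range(n)],
        )
        shifted = clicks.copy()
        shifted["x"] += 37.5
        shifted["y"] -= 12.25
        base = aggregate_subject(clicks, n)
        moved = aggregate_subject(shifted, n)
        assert len(base) == len(moved)
        for a, b in zip(base, moved):
            assert b.x_centre == pytest.approx(a.x_centre + 37.5)
            assert b.y_centre == pytest.approx(a.y_centre - 12.25)
            assert b.probability_of_adult == a.probability_of_adult
            assert b.num_markings == a.num_markings

    @pytest.mark.parametrize("seed", range(5))
    def test_integrality_of_yes_voter_recovery(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(1, 20))
        clicks = click_frame(
            rng.uniform(0, 1000, size=(n, 2)).tolist(),
            [f"v{rng.integers(1, 6)}" for _ in range(n)],
        )
        n_yes = n + int(rng.integers(0, 4))
        for rec in aggregate_subject(clicks, n_yes):
            ratio = rec.num_markings / rec.probability_of_true_positive
            assert abs(ratio - round(ratio)) < 1e-9
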