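import itertools

import numpy as np
import pytest

from genosig.metrics import (
    davies_bouldin,
    evaluate,
    homogeneity_completeness,
    silhouette,
    unsupervised_accuracy,
)
from tests.conftest import make_dataset


class TestUnsupervisedAccuracy:
    def test_relabeling_is_perfect(self):
        assert unsupervised_accuracy([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_half_agreement(self):
        assert unsupervised_accuracy([0, 0, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_identical(self):
        assert unsupervised_accuracy([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_string_true_labels(self):
        assert unsupervised_accuracy(["a", "a", "b", None], [5, 5, 2, 0]) == 1.0

    def test_no_labels_rejected(self):
        with pytest.raises(ValueError, match="no sequences"):
            unsupervised_accuracy([None, None], [0, 1])

    def test_extra_predicted_clusters_contribute_zero(self):
        # two true classes, four predicted clusters: only two can match
        acc = unsupervised_accuracy([0, 0, 1, 1], [0, 1, 2, 3])
        assert acc == 0.5

    def test_matches_exhaustive_permutation_search(self, rng):
        """Assignment-based ACC equals brute force over all injective maps
        for k <= 6 (100 random labelings)."""
        for trial in range(100):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(k, 30))
            true = rng.integers(0, k, n)
            pred = rng.integers(0, k, n)
            got = unsupervised_accuracy(true, pred)
            best = max(
                np.mean(np.array(p)[pred] == true)
                for p in itertools.permutations(range(k))
            )
            assert got == pytest.approx(best, abs=1e-12)

    def test_invariant_to_predicted_id_permutation(self, rng):
        true = rng.integers(0, 4, 40)
        pred = rng.integers(0, 4, 40)
        perm = rng.permutation(4)
        assert unsupervised_accuracy(true, pred) == pytest.approx(
            unsupervised_accuracy(true, perm[pred])
        )


class TestHomogeneityCompleteness:
    def test_perfect_clustering(self):
        h, c = homogeneity_completeness([0, 0, 1, 1], [1, 1, 0, 0])
        assert (h, c) == (1.0, 1.0)

    def test_single_cluster_over_balanced_classes(self):
        h, c = homogeneity_completeness([0, 0, 1, 1], [0, 0, 0, 0])
        assert h == 0.0
        assert c == 1.0

    def test_matches_hand_entropy_computation(self):
        # contingency [[1,1],[0,2]]: H(T)=H(P)=entropy of (2,2) and (1,3)
        true = [0, 0, 1, 1]
        pred = [0, 1, 1, 1]
        h_t = -sum(p * np.log(p) for p in (0.5, 0.5))
        h_p = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        # H(T|P): P=0 -> pure; P=1 -> (1/3, 2/3)
        h_t_given_p = 0.75 * -( (1/3) * np.log(1/3) + (2/3) * np.log(2/3))
        h_p_given_t = 0.5 * -((1/2) * np.log(1/2) + (1/2) * np.log(1/2))
        h, c = homogeneity_completeness(true, pred)
        assert h == pytest.approx(1 - h_t_given_p / h_t, abs=1e-9)
        assert c == pytest.approx(1 - h_p_given_t / h_p, abs=1e-9)

    def test_invariant_to_predicted_id_permutation(self, rng):
        true = rng.integers(0, 3, 30)
        pred = rng.integers(0, 3, 30)
        perm = rng.permutation(3)
        assert homogeneity_completeness(true, pred) == pytest.approx(
            homogeneity_completeness(true, perm[pred])
        )


two_blob_points = np.array(
    [[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]]
)
two_blob_labels = np.array([0, 0, 1, 1])


class TestDaviesBouldin:
    def test_hand_computed_two_blobs(self):
        # s_i = 0.5 each, centroid distance 10 -> DB = (0.5+0.5)/10 = 0.1
        assert davies_bouldin(two_blob_points, two_blob_labels) == pytest.approx(
            0.1, abs=1e-9
        )

    def test_duplicating_points_leaves_db_unchanged(self):
        doubled = np.vstack([two_blob_points, two_blob_points])
        labels = np.concatenate([two_blob_labels, two_blob_labels])
        assert davies_bouldin(doubled, labels) == pytest.approx(0.1, abs=1e-9)

    def test_translation_invariance(self):
        shifted = two_blob_points + np.array([100.0, -3.0])
        assert davies_bouldin(shifted, two_blob_labels) == pytest.approx(
            davies_bouldin(two_blob_points, two_blob_labels), abs=1e-9
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            davies_bouldin(two_blob_points, np.zeros(4, dtype=int))


class TestSilhouette:
    def test_hand_computed_two_blobs(self):
        # a = 1, b = mean(10, sqrt(101)) per point
        b = (10 + np.sqrt(101)) / 2
        expected = (b - 1) / b
        assert silhouette(two_blob_points, two_blob_labels) == pytest.approx(
            expected, abs=1e-9
        )

    def test_interleaved_clusters_score_near_zero(self):
        pts = np.array([[float(i), 0.0] for i in range(8)])
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert abs(silhouette(pts, labels)) < 0.2

    def test_separation_limit_approaches_one(self):
        scores = []
        for gap in (10.0, 1000.0):
            pts = np.array([[0, 0], [0, 1], [gap, 0], [gap, 1]])
            scores.append(silhouette(pts, np.array([0, 0, 1, 1])))
        assert scores[1] > scores[0] > 0.8

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(two_blob_points, np.zeros(4, dtype=int))


class TestEvaluate:
    def test_unlabeled_dataset_reports_intrinsic_only(self):
        ds = make_dataset(["ACGTACGT"] * 4)
        report = evaluate(ds, two_blob_labels, embedding=two_blob_points)
        assert report.acc is None and report.homogeneity is None
        assert report.db_index == pytest.approx(0.1, abs=1e-9)
        assert report.k_pred == 2

    def test_perfect_recovery_scores_one(self):
        ds = make_dataset(["ACGTACGT"] * 4, labels=["x", "x", "y", "y"])
        report = evaluate(ds, two_blob_labels, embedding=two_blob_points)
        assert report.acc == 1.0
        assert report.homogeneity == 1.0
        assert report.completeness == 1.0
        assert report.k_true == 2

    def test_fields_match_individual_metric_calls(self, rng):
        n = 30
        labels_true = [f"c{v}" for v in rng.integers(0, 3, n)]
        pred = rng.integers(0, 3, n)
        emb = rng.standard_normal((n, 4))
        ds = make_dataset(["ACGT" * 5] * n, labels=labels_true)
        report = evaluate(ds, pred, embedding=emb)
        assert report.acc == unsupervised_accuracy(labels_true, pred)
        h, c = homogeneity_completeness(labels_true, pred)
        assert (report.homogeneity, report.completeness) == (h, c)
        assert report.db_index == davies_bouldin(emb, pred)
        assert report.silhouette == silhouette(emb, pred)

    def test_json_roundtrip_keys(self, tmp_path, rng):
        ds = make_dataset(["ACGT" * 4] * 6, labels=["a"] * 3 + ["b"] * 3)
        pred = np.array([0, 0, 0, 1, 1, 1])
        report = evaluate(ds, pred, embedding=rng.standard_normal((6, 3)))
        p = tmp_path / "m.json"
        report.to_json(p)
        import json

        data = json.loads(p.read_text())
        assert set(data) == {
            "db_index",
            "silhouette",
            "homogeneity",
            "completeness",
            "acc",
            "n",
            "k_true",
            "k_pred",
        }
        assert data["acc"] == 1.0
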