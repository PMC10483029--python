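import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genosig.deep import (
    ClusterAssignment,
    ModelConfig,
    TrainParams,
    contrastive_consistency_loss,
    mi_clustering_loss,
    standardize_rows,
    train_model,
)
from genosig.deep import _mi_loss_and_posterior_grad, _ntxent_loss_and_grad
from genosig.metrics import unsupervised_accuracy


def brute_force_mi(p_orig, p_mimic):
    """Independent oracle: explicit double loop over the symmetrized joint."""
    n, k = p_orig.shape
    j = np.zeros((k, k))
    for i in range(n):
        j += np.outer(p_orig[i], p_mimic[i])
    j /= n
    j = (j + j.T) / 2
    a, b = j.sum(axis=1), j.sum(axis=0)
    mi = 0.0
    for x in range(k):
        for y in range(k):
            if j[x, y] > 0:
                mi += j[x, y] * (np.log(j[x, y]) - np.log(a[x]) - np.log(b[y]))
    return -mi


class TestMIClusteringLoss:
    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_diagonal_balanced_joint_attains_minus_log_k(self, k):
        """Perfectly consistent, balanced assignments give loss -log k."""
        n = 4 * k
        p = np.eye(k)[np.arange(n) % k]
        assert mi_clustering_loss(p, p) == pytest.approx(-np.log(k), abs=1e-9)

    def test_uniform_posteriors_give_zero(self):
        p = np.full((10, 4), 0.25)
        assert mi_clustering_loss(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_in_arguments(self, rng):
        p = rng.dirichlet(np.ones(3), size=20)
        q = rng.dirichlet(np.ones(3), size=20)
        assert mi_clustering_loss(p, q) == pytest.approx(
            mi_clustering_loss(q, p), abs=1e-12
        )

    @given(seed=st.integers(0, 1000), k=st.integers(2, 5))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_and_bounded_below(self, seed, k):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k), size=15)
        q = rng.dirichlet(np.ones(k), size=15)
        loss = mi_clustering_loss(p, q)
        assert loss == pytest.approx(brute_force_mi(p, q), abs=1e-9)
        assert loss >= -np.log(k) - 1e-9
        assert loss <= 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mi_clustering_loss(np.full((3, 2), 0.5), np.full((4, 2), 0.5))

    def test_non_stochastic_rows_rejected(self):
        bad = np.full((3, 2), 0.4)
        with pytest.raises(ValueError, match="sum to 1"):
            mi_clustering_loss(bad, bad)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.dirichlet(np.ones(3), size=6)
        q = rng.dirichlet(np.ones(3), size=6)
        _, d_p, _ = _mi_loss_and_posterior_grad(p, q)
        eps = 1e-6
        for i, a in ((0, 1), (3, 2)):
            pp = p.copy()
            pp[i, a] += eps
            num = (brute_force_mi(pp, q) - brute_force_mi(p, q)) / eps
            assert d_p[i, a] == pytest.approx(num, abs=1e-4)


class TestContrastiveLoss:
    def test_two_orthogonal_identical_pairs_closed_form(self):
        """Positives at cosine 1, negatives at 0, tau=0.5:
        loss = -log(e^2 / (e^2 + 2))."""
        z = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = -np.log(np.e**2 / (np.e**2 + 2.0))
        assert contrastive_consistency_loss(z, z, 0.5) == pytest.approx(
            expected, abs=1e-9
        )

    def test_rotation_invariance(self, rng):
        z1 = rng.standard_normal((6, 4))
        z2 = rng.standard_normal((6, 4))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        base = contrastive_consistency_loss(z1, z2, 0.3)
        rotated = contrastive_consistency_loss(z1 @ q, z2 @ q, 0.3)
        assert rotated == pytest.approx(base, abs=1e-9)

    def test_loss_decreases_as_positives_align(self):
        """With negatives fixed, raising the positives' cosine similarity
        lowers the loss (2-pair configuration)."""
        losses = []
        for ang in (np.pi / 2, np.pi / 4, 0.0):
            a = np.array([[1.0, 0.0], [0.0, 1.0]])
            b = np.array(
                [[np.cos(ang), np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            losses.append(contrastive_consistency_loss(a, b, 0.5))
        assert losses[0] > losses[1] > losses[2]

    def test_single_pair_rejected(self):
        z = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError, match="at least 2"):
            contrastive_consistency_loss(z, z, 0.5)

    def test_gradient_matches_finite_differences(self, rng):
        z1 = rng.standard_normal((4, 3))
        z2 = rng.standard_normal((4, 3))
        _, grad = _ntxent_loss_and_grad(z1, z2, 0.4)
        eps = 1e-6
        for i, d in ((0, 0), (2, 1)):
            zp = z1.copy()
            zp[i, d] += eps
            num = (
                contrastive_consistency_loss(zp, z2, 0.4)
                - contrastive_consistency_loss(z1, z2, 0.4)
            ) / eps
            assert grad[i, d] == pytest.approx(num, abs=1e-4)


class TestTrainModel:
    def test_zero_epochs_returns_valid_untrained_posterior(
        self, markov3_features, markov3_pairs
    ):
        cfg = ModelConfig(input_dim=256, n_clusters=3, seed=0)
        assignment, trace = train_model(
            markov3_features, markov3_pairs, cfg, TrainParams(epochs=0)
        )
        assert trace == []
        assert assignment.posterior.shape == (180, 3)
        assert np.allclose(assignment.posterior.sum(axis=1), 1.0)
        assert np.all(assignment.posterior >= 0)

    def test_strong_signal_recovery_across_seeds(self, markov3, markov3_features, markov3_pairs):
        """Compositionally extreme clusters are recovered near-perfectly for
        at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            cfg = ModelConfig(
                input_dim=256, n_clusters=3, hidden_dims=(64,), seed=seed
            )
            a, _ = train_model(
                markov3_features, markov3_pairs, cfg, TrainParams(epochs=30)
            )
            if unsupervised_accuracy(markov3.labels, a.hard_labels) == 1.0:
                hits += 1
        assert hits >= 9

    def test_loss_trace_improves_on_strong_signal(
        self, markov3_features, markov3_pairs
    ):
        cfg = ModelConfig(input_dim=256, n_clusters=3, hidden_dims=(64,), seed=1)
        _, trace = train_model(
            markov3_features, markov3_pairs, cfg, TrainParams(epochs=30)
        )
        assert len(trace) == 30
        assert trace[-1].total <= trace[0].total

    def test_reproducible_given_seed(self, markov3_features, markov3_pairs):
        cfg = ModelConfig(input_dim=256, n_clusters=3, hidden_dims=(32,), seed=9)
        a1, t1 = train_model(markov3_features, markov3_pairs, cfg, TrainParams(epochs=5))
        a2, t2 = train_model(markov3_features, markov3_pairs, cfg, TrainParams(epochs=5))
        assert np.array_equal(a1.posterior, a2.posterior)
        assert np.array_equal(a1.embedding, a2.embedding)
        assert t1 == t2

    def test_too_many_clusters_rejected(self, markov3_features, markov3_pairs):
        cfg = ModelConfig(input_dim=256, n_clusters=500, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            train_model(markov3_features, markov3_pairs, cfg, TrainParams(epochs=1))

    def test_hard_labels_are_argmax_with_low_tie(self):
        post = np.array([[0.5, 0.5], [0.2, 0.8]])
        a = ClusterAssignment(posterior=post, embedding=np.zeros((2, 2)))
        assert a.hard_labels.tolist() == [0, 1]


class TestStandardize:
    def test_rows_zero_mean_unit_variance(self, rng):
        x = rng.random((5, 20))
        s = standardize_rows(x)
        assert np.allclose(s.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(s.std(axis=1), 1.0)

    def test_constant_row_maps_to_zeros(self):
        s = standardize_rows(np.full((1, 8), 0.125))
        assert np.allclose(s, 0.0)
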