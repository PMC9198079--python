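"""Weak learners, tSVD, subdata partitioning and ensemble voting."""

import numpy as np
import pytest

from hammersound.models import (
    MODEL_IDS,
    ModelConfig,
    ModelTrainingError,
    SingleClassError,
    TrainedModel,
    WeakLearner,
    fit_lr,
    fit_tsvd,
    group_by_operation,
    partition_subdata,
    predict,
    train,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _penalized_loglik(X, y, w, b, C):
    z = X @ w + b
    ll = np.sum(y * z - np.logaddexp(0, z))
    return ll - 0.5 / C * np.dot(w, w)


class TestFitLR:
    def test_separable_data_predicts_correct_side(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        lr = fit_lr(X, y, l2_C=1000.0)
        p = lr.predict_proba(X)[:, 1]
        assert np.all(p[y == 1] > 0.9)
        assert np.all(p[y == 0] < 0.1)

    def test_label_flip_negates_weights(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        lr1 = fit_lr(X, y)
        lr2 = fit_lr(X, 1 - y)
        assert lr1.coef_[0] == pytest.approx(-lr2.coef_[0], abs=1e-5)
        assert lr1.intercept_[0] == pytest.approx(-lr2.intercept_[0], abs=1e-5)

    def test_returned_weights_beat_random_perturbations(self, rng):
        """Optimality spot check of the penalized log-likelihood."""
        X = rng.normal(size=(60, 4))
        y = (X @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(size=60) > 0).astype(int)
        C = 0.1
        lr = fit_lr(X, y, l2_C=C)
        w, b = lr.coef_[0], lr.intercept_[0]
        best = _penalized_loglik(X, y, w, b, C)
        for _ in range(1000):
            dw = rng.normal(0, 0.05, size=w.shape)
            db = rng.normal(0, 0.05)
            assert _penalized_loglik(X, y, w + dw, b + db, C) <= best + 1e-9

    def test_single_class_labels_raise(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(SingleClassError):
            fit_lr(X, np.ones(10, dtype=int))


class TestFitTSVD:
    def test_rank_deficient_matrix_truncates_basis(self, rng, caplog):
        import logging

        # rank-3 matrix embedded in 20 x 15
        A = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 15))
        with caplog.at_level(logging.WARNING, logger="hammersound.models"):
            basis = fit_tsvd(A, 10)
        assert basis.shape == (3, 15)
        assert any("rank" in r.message for r in caplog.records)

    def test_reconstruction_error_matches_full_svd_tail(self, rng):
        """||X - X_k||_F equals sqrt(sum of squared discarded singulars)."""
        X = rng.normal(size=(30, 12))
        for k in (1, 3, 7):
            basis = fit_tsvd(X, k)
            Xk = (X @ basis.T) @ basis
            _, s, _ = np.linalg.svd(X, full_matrices=False)
            expected = np.sqrt(np.sum(s[k:] ** 2))
            assert np.linalg.norm(X - Xk, "fro") == pytest.approx(expected, rel=1e-8)

    def test_basis_is_orthonormal(self, rng):
        X = rng.normal(size=(25, 40))
        basis = fit_tsvd(X, 10)
        assert np.allclose(basis @ basis.T, np.eye(10), atol=1e-8)

    def test_k_larger_than_min_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            fit_tsvd(rng.normal(size=(5, 8)), 6)


class TestPartitionSubdata:
    def test_30_examples_into_3_equal_disjoint_parts(self):
        y = np.array([0, 1] * 15)
        parts = partition_subdata(y, 3, seed=0)
        assert sorted(len(p) for p in parts) == [10, 10, 10]
        all_idx = np.concatenate(parts)
        assert len(np.unique(all_idx)) == 30

    def test_same_seed_gives_identical_partition(self):
        y = np.array([0, 1] * 20)
        p1 = partition_subdata(y, 4, seed=7)
        p2 = partition_subdata(y, 4, seed=7)
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2))

    def test_stratification_puts_both_classes_in_every_part(self):
        y = np.array([0] * 12 + [1] * 12)
        for seed in range(5):
            for part in partition_subdata(y, 4, seed=seed):
                assert set(y[part]) == {0, 1}

    def test_assignment_frequency_is_uniform(self):
        """Over many seeds each example lands in part 0 about half the time."""
        y = np.array([0, 1] * 8)
        counts = np.zeros(16)
        n_rep = 1000
        for seed in range(n_rep):
            part0 = partition_subdata(y, 2, seed=seed)[0]
            counts[part0] += 1
        freq = counts / n_rep
        assert np.all(np.abs(freq - 0.5) < 0.05)

    def test_more_parts_than_examples_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            partition_subdata(np.array([0, 1]), 3, seed=0)


class TestGroupByOperation:
    def test_subsets_partition_examples_by_single_operation(self):
        groups = ["a", "a", "b", "c", "b", "a"]
        subsets = group_by_operation(groups)
        assert len(subsets) == 3
        all_idx = sorted(int(i) for s in subsets for i in s)
        assert all_idx == list(range(6))
        for s in subsets:
            assert len({groups[i] for i in s}) == 1


def _grouped_data(rng, n_ops=5, per_op=16, d=12, effect=2.0):
    X, y, groups = [], [], []
    for j in range(n_ops):
        shift = rng.normal(0, 1.0, d)
        for i in range(per_op):
            label = i % 2
            X.append(shift + effect * label * np.eye(d)[0] + rng.normal(0, 0.5, d))
            y.append(label)
            groups.append(f"op{j}")
    return np.array(X), np.array(y), np.array(groups)


class TestTrain:
    def test_model_a_single_learner_on_worked_example_counts(self, rng):
        X = rng.normal(size=(17, 30))
        y = np.array([1] * 9 + [0] * 8)
        groups = np.array(["op0"] * 17)
        model = train(ModelConfig("A"), X, y, groups)
        assert model.n_learners == 1
        assert model.learners[0].projection is None

    def test_operationwise_models_build_one_learner_per_operation(self, rng):
        X, y, groups = _grouped_data(rng)
        for mid in ("E", "F"):
            model = train(ModelConfig(mid), X, y, groups)
            assert model.n_learners == 5
            scopes = {ln.training_scope for ln in model.learners}
            assert scopes == {f"op{j}" for j in range(5)}

    def test_random_split_models_build_one_learner_per_training_operation(self, rng):
        X, y, groups = _grouped_data(rng)
        for mid in ("C", "D"):
            model = train(ModelConfig(mid), X, y, groups)
            assert model.n_learners == 5

    def test_tsvd_presence_is_the_only_difference_between_pairs(self, rng):
        X, y, groups = _grouped_data(rng)
        m_e = train(ModelConfig("E"), X, y, groups)
        m_f = train(ModelConfig("F"), X, y, groups)
        assert m_e.n_learners == m_f.n_learners
        assert all(ln.projection is None for ln in m_e.learners)
        assert all(ln.projection is not None for ln in m_f.learners)
        assert [ln.training_scope for ln in m_e.learners] == [
            ln.training_scope for ln in m_f.learners
        ]

    def test_single_class_operation_skipped_with_remaining_learners(self, rng):
        X, y, groups = _grouped_data(rng, n_ops=3)
        y[groups == "op2"] = 1  # degenerate operation
        model = train(ModelConfig("E"), X, y, groups)
        assert model.n_learners == 2
        assert model.n_skipped == 1

    def test_all_single_class_subsets_error(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array([0] * 10 + [1] * 10)
        groups = np.array(["op0"] * 10 + ["op1"] * 10)  # each op single-class
        with pytest.raises(ModelTrainingError, match="single-class"):
            train(ModelConfig("E"), X, y, groups)

    def test_projection_recovers_full_model_when_k_covers_rank(self, rng):
        """With tsvd_k >= rank(X), model B's scores match model A's."""
        X = rng.normal(size=(40, 6))  # rank 6 <= k = 10
        y = (X[:, 0] > 0).astype(int)
        groups = np.array(["op%d" % (i % 4) for i in range(40)])
        cfg_a = ModelConfig("A", standardize=False)
        cfg_b = ModelConfig("B", tsvd_k=6, standardize=False)
        pa = predict(train(cfg_a, X, y, groups), X)
        pb = predict(train(cfg_b, X, y, groups), X)
        assert pa == pytest.approx(pb, abs=1e-5)

    def test_training_invariant_to_example_order(self, rng):
        X, y, groups = _grouped_data(rng)
        perm = rng.permutation(len(y))
        X_test = rng.normal(size=(10, X.shape[1]))
        for mid in MODEL_IDS:
            cfg = ModelConfig(mid, seed=3)
            p1 = predict(train(cfg, X, y, groups), X_test)
            p2 = predict(train(cfg, X[perm], y[perm], groups[perm]), X_test)
            assert p1 == pytest.approx(p2, abs=1e-6)


class TestPredict:
    def _const_model(self, probs, n_features=3):
        """Model whose learners output fixed probabilities (logit trick)."""
        learners = []
        for p in probs:
            lr = fit_lr(np.array([[-1.0], [-1.0], [1.0], [1.0]]),
                        np.array([0, 0, 1, 1]), l2_C=1e-6)
            # overwrite with a constant-output learner
            lr.coef_ = np.zeros((1, n_features))
            lr.intercept_ = np.array([np.log(p / (1 - p))])
            lr.n_features_in_ = n_features
            learners.append(
                WeakLearner(lr=lr, projection=None, mean_=None, scale_=None,
                            training_scope="t")
            )
        return TrainedModel(config=ModelConfig("E"), learners=learners,
                            n_features=n_features)

    def test_vote_is_arithmetic_mean_of_learner_probabilities(self):
        model = self._const_model([0.2, 0.4, 0.6])
        p = predict(model, np.zeros((2, 3)))
        assert p == pytest.approx([0.4, 0.4])

    def test_single_learner_vote_is_identity(self):
        model = self._const_model([0.3])
        assert predict(model, np.zeros((1, 3)))[0] == pytest.approx(0.3)

    def test_vote_stays_in_unit_interval_at_extremes(self):
        model = self._const_model([1 - 1e-12, 1 - 1e-12])
        p = predict(model, np.zeros((1, 3)))
        assert 0.0 <= p[0] <= 1.0
        assert p[0] == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        X, y, groups = _grouped_data(rng, n_ops=3)
        model = train(ModelConfig("A"), X, y, groups)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, rng.normal(size=(4, X.shape[1] + 1)))
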