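import numpy as np
import pytest

from leafstack.synthgen import FeatureTableSpec, generate_feature_table
from leafstack.hybrid_stack import (
    BASE_LEARNERS,
    BaseLearnerConfig,
    DNNModel,
    DNNTrainConfig,
    SoftmaxRegression,
    build_dnn,
    dnn_forward,
    fit_base,
    fit_hybrid,
    load_stack,
    oof_probabilities,
    predict,
    save_stack,
)


def split_table(X, y, seed=0, n_train=420, n_val=90):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    tr, va, te = idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]
    return (X[tr], y[tr]), (X[va], y[va]), (X[te], y[te])


class TestFitBase:
    def test_knn_one_neighbor_is_one_hot_on_training_rows(self, blob_table):
        X, y, _ = blob_table
        cfg = BaseLearnerConfig("knn", hyperparameters={"n_neighbors": 1})
        base = fit_base(cfg, X, y)
        P = base.predict_proba(X)
        assert np.allclose(P[np.arange(len(y)), y], 1.0)

    def test_lr_separable_blobs_training_accuracy_one(self):
        spec = FeatureTableSpec(n_per_class=100, n_classes=2, dim=5, separation=8.0, seed=7)
        X, y = generate_feature_table(spec)
        base = fit_base(BaseLearnerConfig("lr", seed=1), X, y)
        assert np.mean(base.predict(X) == y) == 1.0

    def test_rf_out_of_sample_accuracy(self, blob_table):
        """Simulation oracle: 100-tree RF on separation-6 blobs gets >= 0.95
        held-out accuracy."""
        X, y, _ = blob_table
        (Xtr, ytr), _, (Xte, yte) = split_table(X, y)
        base = fit_base(BaseLearnerConfig("rf", seed=0), Xtr, ytr)
        assert np.mean(base.predict(Xte) == yte) >= 0.95

    def test_probability_rows_stochastic_all_learners(self, blob_table):
        X, y, _ = blob_table
        for name in BASE_LEARNERS:
            base = fit_base(BaseLearnerConfig(name, seed=0), X[::4], y[::4])
            P = base.predict_proba(X[1::12])
            assert P.shape == (50, 3)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert P.min() >= 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_base(BaseLearnerConfig("rf"), np.zeros((10, 2)), np.zeros(10, int))

    def test_nan_rejected(self):
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError):
            fit_base(BaseLearnerConfig("rf"), X, y)

    def test_softmax_regression_matches_sklearn(self):
        """Independent cross-check: our gradient-descent multinomial fit
        agrees with scikit-learn's L2 logistic regression predictions."""
        from sklearn.linear_model import LogisticRegression

        spec = FeatureTableSpec(n_per_class=120, n_classes=3, dim=6, separation=3.0, seed=5)
        X, y = generate_feature_table(spec)
        ours = SoftmaxRegression(l2=1.0, seed=0).fit(X[::2], y[::2])
        theirs = LogisticRegression(C=1.0, max_iter=2000).fit(X[::2], y[::2])
        agree = np.mean(ours.predict(X[1::2]) == theirs.predict(X[1::2]))
        assert agree >= 0.97


class TestOOF:
    def test_no_row_scored_by_its_own_fold(self, blob_table):
        X, y, _ = blob_table
        pm = oof_probabilities(BaseLearnerConfig("lr", seed=0), X[::2], y[::2],
                               folds=5, seed=1)
        assert pm.fold_of_row.min() >= 0
        # every fold holds out a disjoint, exhaustive subset
        assert len(np.unique(pm.fold_of_row)) == 5
        assert pm.probs.shape == (300, 3)
        assert np.allclose(pm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_chance_level_probabilities_on_unseparated_data(self):
        spec = FeatureTableSpec(n_per_class=300, n_classes=4, dim=8, separation=0.0, seed=2)
        X, y = generate_feature_table(spec)
        pm = oof_probabilities(BaseLearnerConfig("lr", seed=0), X, y, folds=5, seed=0)
        assert abs(pm.probs.max(axis=1).mean() - 0.25) < 0.1

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValueError, match="folds"):
            oof_probabilities(BaseLearnerConfig("lr"), X, y, folds=5, seed=0)


class TestDNN:
    def test_architecture_constants(self):
        model = build_dnn(m=15, seed=0)
        assert model.layer_widths == [512, 256, 128, 15]
        assert model.weights[0].shape == (15, 512)
        assert model.dropout == 0.3

    def test_first_layer_512_for_any_class_count(self):
        for m in (2, 5, 15):
            assert build_dnn(m, seed=0).layer_widths[0] == 512

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            build_dnn(1, seed=0)

    def test_zero_weights_give_uniform_softmax(self):
        model = build_dnn(m=4, seed=0)
        for W in model.weights:
            W[:] = 0.0
        out = dnn_forward(model, np.random.default_rng(0).random((6, 4)))
        assert np.allclose(out, 0.25)

    def test_rows_sum_to_one_and_infer_deterministic(self):
        model = build_dnn(m=3, seed=1)
        P = np.random.default_rng(1).dirichlet(np.ones(3), size=20)
        o1 = dnn_forward(model, P, mode="infer")
        o2 = dnn_forward(model, P, mode="infer")
        assert np.array_equal(o1, o2)
        assert np.allclose(o1.sum(axis=1), 1.0, atol=1e-9)

    def test_hand_softmax_on_identity_single_layer(self):
        """softmax(0.9, 0.1) = (0.6900, 0.3100) to 4 decimals."""
        model = DNNModel(weights=[np.eye(2)], biases=[np.zeros(2)], dropout=0.0)
        out = dnn_forward(model, np.array([[0.9, 0.1]]))
        assert out[0, 0] == pytest.approx(0.6900, abs=5e-5)
        assert out[0, 1] == pytest.approx(0.3100, abs=5e-5)

    def test_train_mode_requires_rng_and_uses_dropout(self):
        model = build_dnn(m=3, seed=2)
        P = np.random.default_rng(2).dirichlet(np.ones(3), size=8)
        with pytest.raises(ValueError):
            dnn_forward(model, P, mode="train")
        r1 = dnn_forward(model, P, mode="train", rng=np.random.default_rng(0))
        r2 = dnn_forward(model, P, mode="train", rng=np.random.default_rng(1))
        assert not np.allclose(r1, r2)  # different dropout masks


class TestFitHybrid:
    def test_separable_blobs_recovery(self, blob_table):
        X, y, _ = blob_table
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(X, y)
        stack = fit_hybrid(BaseLearnerConfig("lr", seed=1), Xtr, ytr, Xva, yva, seed=42)
        labels, probs = predict(stack, Xte)
        assert np.mean(labels == yte) >= 0.95
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_chance_level_on_unseparated_blobs(self):
        spec = FeatureTableSpec(n_per_class=200, n_classes=3, dim=10, separation=0.0, seed=42)
        X, y = generate_feature_table(spec)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(X, y)
        stack = fit_hybrid(BaseLearnerConfig("lr", seed=1), Xtr, ytr, Xva, yva, seed=42)
        labels, _ = predict(stack, Xte)
        assert abs(np.mean(labels == yte) - 1 / 3) <= 0.1

    def test_end_to_end_determinism(self, blob_table):
        X, y, _ = blob_table
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(X, y)
        cfg = BaseLearnerConfig("lr", seed=3)
        s1 = fit_hybrid(cfg, Xtr, ytr, Xva, yva, seed=7)
        s2 = fit_hybrid(cfg, Xtr, ytr, Xva, yva, seed=7)
        assert s1.history == s2.history
        assert np.array_equal(predict(s1, Xte)[1], predict(s2, Xte)[1])

    def test_predictions_consistent_with_probabilities(self, blob_table):
        X, y, _ = blob_table
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(X, y)
        stack = fit_hybrid(BaseLearnerConfig("knn", seed=0), Xtr, ytr, Xva, yva, seed=0)
        labels, probs = predict(stack, Xte)
        assert set(labels) <= set(stack.classes)
        assert np.array_equal(labels, stack.classes[np.argmax(probs, axis=1)])

    def test_near_diagonal_confusion_on_separable_fixture(self, blob_table):
        from leafstack.metrics import confusion_matrix

        X, y, _ = blob_table
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(X, y)
        stack = fit_hybrid(BaseLearnerConfig("lr", seed=1), Xtr, ytr, Xva, yva, seed=42)
        labels, _ = predict(stack, Xte)
        cm = confusion_matrix(yte, labels, [0, 1, 2])
        off_diagonal = cm.sum() - np.trace(cm)
        assert off_diagonal / cm.sum() <= 0.05

    def test_signal_monotonicity(self):
        """Held-out accuracy is non-decreasing in the class separation,
        averaged over three seeds."""
        mean_acc = {}
        for sep in (0.0, 1.0, 6.0):
            accs = []
            for seed in (0, 1, 2):
                spec = FeatureTableSpec(n_per_class=120, n_classes=3, dim=10,
                                        separation=sep, seed=seed)
                X, y = generate_feature_table(spec)
                (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(
                    X, y, seed=seed, n_train=250, n_val=55
                )
                stack = fit_hybrid(BaseLearnerConfig("lr", seed=seed),
                                   Xtr, ytr, Xva, yva, seed=seed)
                labels, _ = predict(stack, Xte)
                accs.append(np.mean(labels == yte))
            mean_acc[sep] = np.mean(accs)
        assert mean_acc[0.0] <= mean_acc[1.0] <= mean_acc[6.0]

    def test_history_schema(self, blob_table):
        X, y, _ = blob_table
        (Xtr, ytr), (Xva, yva), _ = split_table(X, y)
        stack = fit_hybrid(BaseLearnerConfig("lr", seed=0), Xtr, ytr, Xva, yva, seed=0)
        h = stack.history
        n = len(h["epoch"])
        assert h["epoch"] == list(range(1, n + 1))
        assert all(len(h[k]) == n for k in ("train_loss", "train_acc", "val_loss", "val_acc"))
        assert all(np.isfinite(h["train_loss"]))

    def test_persistence_roundtrip(self, blob_table, tmp_path):
        X, y, _ = blob_table
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(X, y)
        stack = fit_hybrid(BaseLearnerConfig("lr", seed=0), Xtr, ytr, Xva, yva, seed=0)
        save_stack(stack, tmp_path / "model")
        again = load_stack(tmp_path / "model")
        assert np.array_equal(predict(stack, Xte)[1], predict(again, Xte)[1])

    def test_string_labels_roundtrip(self):
        spec = FeatureTableSpec(n_per_class=60, n_classes=3, dim=5, separation=6.0, seed=9)
        X, y = generate_feature_table(spec)
        names = np.array(["blight", "healthy", "mold"])[y]
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_table(
            X, names, seed=1, n_train=120, n_val=30
        )
        stack = fit_hybrid(BaseLearnerConfig("rf", seed=0), Xtr, ytr, Xva, yva, seed=0)
        labels, _ = predict(stack, Xte)
        assert set(labels) <= {"blight", "healthy", "mold"}
        assert np.mean(labels == yte) >= 0.9
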