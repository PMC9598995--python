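"""Multi-branch MLP: correctness of loss, gradients, metrics and training."""

import numpy as np
import pytest

from bindfeat.model import (
    EvalResult,
    WindowMLPClassifier,
    count_parameters,
    precision,
)


def make_blobs(n=400, d=10, signal_col=3, seed=0, shift=1.5, frac_pos=0.3):
    """Noisy features with one informative column."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < frac_pos).astype(int)
    X = rng.normal(0, 1, (n, d))
    X[:, signal_col] += shift * y
    return X, y


class TestPrecisionMetric:
    def test_basic_counts(self):
        res = precision([1, 1, 1, 1, 0], [1, 1, 1, 0, 0])
        assert (res.tp, res.fp, res.fn, res.tn) == (3, 1, 0, 1)
        assert res.precision == 0.75

    def test_perfect(self):
        assert precision([1, 0], [1, 0]).precision == 1.0

    def test_all_negative_predictions_undefined(self):
        """No positive predicted: precision is a distinguished None, not 0."""
        res = precision([0, 0, 0], [1, 0, 1])
        assert res.precision is None
        assert (res.fn, res.tn) == (2, 1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            precision([1, 0], [1, 0, 1])


class TestArchitecture:
    def test_softmax_rows_sum_to_one(self):
        X, y = make_blobs(n=64)
        clf = WindowMLPClassifier(hidden=(8, 4), branch_units=4, epochs=2,
                                  batch_size=32, random_state=0).fit(X, y)
        p = clf.predict_proba(np.random.default_rng(1).normal(0, 3, (50, 10)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_parameter_count_is_pure_function_of_config(self):
        X, y = make_blobs(n=32, d=12)
        slices = {"a": (0, 7), "b": (7, 12)}
        clf = WindowMLPClassifier(hidden=(6, 5), branch_units=3,
                                  block_slices=slices, epochs=0,
                                  random_state=0).fit(X, y)
        assert clf.n_parameters_ == count_parameters(
            {"a": 7, "b": 5}, (6, 5), 3
        )

    def test_branch_concat_width(self):
        X, y = make_blobs(n=32, d=12)
        slices = {"a": (0, 7), "b": (7, 12)}
        clf = WindowMLPClassifier(hidden=(6, 5), branch_units=3,
                                  block_slices=slices, epochs=0,
                                  random_state=0).fit(X, y)
        assert clf.params_["final/W"].shape == (2 * 3, 2)

    def test_window_input_flattened_per_block(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 31, 6))
        y = rng.integers(0, 2, 40)
        slices = {"x": (0, 4), "z": (4, 6)}
        clf = WindowMLPClassifier(hidden=(4, 3), branch_units=2,
                                  block_slices=slices, epochs=1,
                                  batch_size=16, random_state=0).fit(X, y)
        assert clf.params_["x/W1"].shape[0] == 31 * 4
        assert clf.params_["z/W1"].shape[0] == 31 * 2

    def test_same_seed_reproduces_training_exactly(self):
        X, y = make_blobs()
        kw = dict(hidden=(8, 4), branch_units=4, epochs=4, batch_size=64,
                  dropout=0.3, random_state=123)
        a = WindowMLPClassifier(**kw).fit(X, y)
        b = WindowMLPClassifier(**kw).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))
        assert a.history_["loss"] == b.history_["loss"]

    def test_sklearn_params_round_trip(self):
        clf = WindowMLPClassifier(hidden=(8, 4), lr=0.01)
        clone = WindowMLPClassifier(**clf.get_params())
        assert clone.get_params() == clf.get_params()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences everywhere
        (dropout off; batch-norm in training mode)."""
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (12, 9))
        y = rng.integers(0, 2, 12)
        w = np.where(y == 1, 3.0, 1.0)
        clf = WindowMLPClassifier(hidden=(5, 4), branch_units=3, dropout=0.0,
                                  block_slices={"a": (0, 6), "b": (6, 9)},
                                  epochs=0, random_state=7).fit(X, y)
        branches = clf._flatten_branches(X)
        _, grads = clf._loss_and_grads(branches, y, w, rng=None)
        eps = 1e-6
        for key, g in grads.items():
            flat = clf.params_[key].ravel()
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for j in idx:
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = clf._loss_and_grads(branches, y, w, rng=None)
                flat[j] = orig - eps
                lm, _ = clf._loss_and_grads(branches, y, w, rng=None)
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g.ravel()[j], rel=1e-4,
                                            abs=1e-7), key


class TestWeightedLoss:
    def test_unit_weights_equal_unweighted(self):
        """class_weight {1:1, 0:1} is exactly the unweighted loss."""
        X, y = make_blobs(n=128)
        kw = dict(hidden=(8, 4), branch_units=4, epochs=3, batch_size=64,
                  dropout=0.0, random_state=5)
        a = WindowMLPClassifier(class_weight=None, **kw).fit(X, y)
        b = WindowMLPClassifier(class_weight={1: 1.0, 0: 1.0}, **kw).fit(X, y)
        np.testing.assert_allclose(a.history_["loss"], b.history_["loss"],
                                   atol=1e-6)
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X),
                                   atol=1e-9)

    def test_constant_input_converges_to_weighted_prior(self):
        """On an uninformative (constant) input the weighted cross-entropy
        minimiser is the weighted class prior w1·π/(w1·π + w0·(1−π))."""
        n, frac = 200, 0.3
        X = np.ones((n, 5))
        y = (np.arange(n) < frac * n).astype(int)
        clf = WindowMLPClassifier(hidden=(8, 4), branch_units=4, dropout=0.0,
                                  class_weight={1: 10.0, 0: 1.0},
                                  epochs=200, batch_size=n, lr=5e-3,
                                  random_state=0).fit(X, y)
        expected = 10.0 * frac / (10.0 * frac + 1.0 * (1 - frac))
        p1 = clf.predict_proba(X)[:, 1]
        assert np.all(np.abs(p1 - expected) < 0.05)

    def test_learnable_signal_beats_prevalence(self):
        """Threshold-on-one-column labels are learnable within 50 epochs."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (500, 10))
        y = (X[:, 3] > 0.5).astype(int)
        clf = WindowMLPClassifier(hidden=(16, 8), branch_units=8,
                                  dropout=0.0, epochs=50, batch_size=128,
                                  random_state=3)
        clf.fit(X[:400], y[:400], validation_data=(X[400:], y[400:]))
        res = clf.evaluate(X[400:], y[400:])
        prevalence = y[400:].mean()
        assert res.precision is not None and res.precision > prevalence
        assert len(clf.history_["val_precision"]) == 50

    def test_recall_monotone_in_positive_weight(self):
        """Raising the positive class weight never lowers recall
        (checked over weights 1, 3, 10 with fixed seed; ties allowed)."""
        X, y = make_blobs(n=600, shift=1.0, seed=9)
        Xtr, ytr, Xte, yte = X[:450], y[:450], X[450:], y[450:]
        recalls = []
        for w in (1.0, 3.0, 10.0):
            clf = WindowMLPClassifier(hidden=(8, 4), branch_units=4,
                                      dropout=0.0, epochs=30, batch_size=128,
                                      class_weight={1: w, 0: 1.0},
                                      random_state=9).fit(Xtr, ytr)
            res = clf.evaluate(Xte, yte)
            recalls.append(res.tp / (res.tp + res.fn))
        assert recalls[0] <= recalls[1] + 1e-12
        assert recalls[1] <= recalls[2] + 1e-12


class TestValidation:
    def test_rejects_nonbinary_labels(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError):
            WindowMLPClassifier(epochs=1).fit(X, [0, 1, 2, 1])

    def test_rejects_nonfinite_input(self):
        X = np.zeros((4, 3))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            WindowMLPClassifier(epochs=1).fit(X, [0, 1, 0, 1])

    def test_nonfinite_loss_aborts_with_diagnostic(self, monkeypatch):
        """A NaN loss aborts training with a diagnostic, never trains on."""
        X, y = make_blobs(n=64)
        clf = WindowMLPClassifier(hidden=(8, 4), branch_units=4, epochs=10,
                                  batch_size=32, random_state=0)
        orig = WindowMLPClassifier._loss_and_grads

        def poisoned(self, branches, yy, ww, rng):
            loss, grads = orig(self, branches, yy, ww, rng)
            return np.nan, grads

        monkeypatch.setattr(WindowMLPClassifier, "_loss_and_grads", poisoned)
        with pytest.raises(RuntimeError, match="non-finite loss.*epoch 1"):
            clf.fit(X, y)
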