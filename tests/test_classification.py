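"""LDA against the explicit discriminant-function oracle, CV bookkeeping."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from myofuse.classification import (
    ConfusionMatrix,
    accuracy,
    fit_lda,
    leave_one_repetition_out_cv,
    predict,
)


def oracle_predict(X_train, y_train, X_test, labels, shrinkage=0.0):
    """Brute-force evaluation of delta_k(x) = x'S^-1 mu_k - mu_k'S^-1 mu_k/2 + ln pi_k."""
    X_train = np.asarray(X_train, float)
    n, d = X_train.shape
    mus, pis = [], []
    scatter = np.zeros((d, d))
    for lab in labels:
        Xi = X_train[np.array([yy == lab for yy in y_train])]
        mus.append(Xi.mean(axis=0))
        pis.append(len(Xi) / n)
        scatter += (Xi - Xi.mean(axis=0)).T @ (Xi - Xi.mean(axis=0))
    S = scatter / (n - len(labels))
    if shrinkage > 0:
        S = (1 - shrinkage) * S + shrinkage * np.trace(S) / d * np.eye(d)
    Sinv = np.linalg.inv(S)
    out = []
    for x in np.atleast_2d(X_test):
        deltas = [
            x @ Sinv @ mu - 0.5 * mu @ Sinv @ mu + np.log(pi)
            for mu, pi in zip(mus, pis)
        ]
        out.append(labels[int(np.argmax(deltas))])
    return np.array(out, dtype=object)


class TestFitPredict:
    def test_symmetric_1d_boundary_at_zero_and_tie_break(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = ["neg", "neg", "pos", "pos"]
        model = fit_lda(X, y, class_order=["neg", "pos"], shrinkage=0.0)
        assert predict(model, [[-0.01]])[0] == "neg"
        assert predict(model, [[0.01]])[0] == "pos"
        # exact midpoint: documented tie-break to the earliest class
        assert predict(model, [[0.0]])[0] == "neg"

    def test_duplicating_samples_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(30, 3)) + np.repeat(np.eye(3) * 4, 10, axis=0)
        y = np.repeat(["a", "b", "c"], 10)
        grid = rng.normal(size=(50, 3))
        base = predict(fit_lda(X, y), grid)
        doubled = predict(fit_lda(np.vstack([X, X]), np.concatenate([y, y])), grid)
        np.testing.assert_array_equal(base, doubled)

    @pytest.mark.parametrize("k,d", [(2, 1), (3, 2), (5, 10), (4, 7)])
    def test_matches_discriminant_formula_oracle(self, k, d, rng):
        X = rng.normal(size=(20 * k, d)) + 3 * rng.normal(size=(k, d)).repeat(20, axis=0)
        y = np.repeat([f"c{i}" for i in range(k)], 20)
        labels = sorted(set(y))
        X_test = rng.normal(size=(40, d), scale=3)
        model = fit_lda(X, y, shrinkage=0.0)
        np.testing.assert_array_equal(
            predict(model, X_test), oracle_predict(X, y, X_test, labels)
        )
        # and with the default shrinkage, against the same shrunk formula
        model_s = fit_lda(X, y)
        np.testing.assert_array_equal(
            predict(model_s, X_test),
            oracle_predict(X, y, X_test, labels, shrinkage=model_s.shrinkage),
        )

    def test_agrees_with_reference_lda_implementation(self, rng):
        """Independent cross-check against scikit-learn's LDA."""
        X = rng.normal(size=(90, 6)) + 2.5 * rng.normal(size=(3, 6)).repeat(30, axis=0)
        y = np.repeat(["a", "b", "c"], 30)
        X_test = rng.normal(size=(200, 6), scale=3)
        ours = predict(fit_lda(X, y, shrinkage=0.0), X_test)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X_test)
        assert np.mean(ours == ref) == 1.0

    def test_class_mean_classified_to_its_class(self, rng):
        means = np.eye(4) * 6
        X = np.vstack([m + rng.normal(0, 0.3, (15, 4)) for m in means])
        y = np.repeat(list("abcd"), 15)
        model = fit_lda(X, y)
        np.testing.assert_array_equal(predict(model, means), list("abcd"))

    def test_batch_equals_streaming_predictions(self, rng):
        X = rng.normal(size=(40, 3)) + np.repeat([[0, 0, 0], [4, 4, 4]], 20, axis=0)
        y = np.repeat(["a", "b"], 20)
        model = fit_lda(X, y)
        grid = rng.normal(size=(25, 3))
        batch = predict(model, grid)
        single = [predict(model, row[None, :])[0] for row in grid]
        np.testing.assert_array_equal(batch, single)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda(rng.normal(size=(4, 2)), ["a"] * 4)
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            fit_lda(rng.normal(size=(3, 2)), ["a", "a", "b"])
        model = fit_lda(rng.normal(size=(8, 3)), ["a", "b"] * 4)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((1, 5)))

    def test_affine_equivariance_up_to_shrinkage(self, rng):
        """Invertible per-feature affine maps leave predictions unchanged."""
        X = rng.normal(size=(60, 5)) + 4 * rng.normal(size=(3, 5)).repeat(20, axis=0)
        y = np.repeat(["a", "b", "c"], 20)
        grid = rng.normal(size=(80, 5), scale=3)
        base = predict(fit_lda(X, y), grid)
        scale = np.array([0.5, 2.0, 1.3, 0.8, 1.7])
        shift = np.array([3.0, -1.0, 0.0, 5.0, -2.0])
        mapped = predict(fit_lda(X * scale + shift, y), grid * scale + shift)
        np.testing.assert_array_equal(base, mapped)


class TestAccuracy:
    def test_identity_matrix_is_100(self):
        cm = ConfusionMatrix(labels=list("abc"), counts=np.eye(3, dtype=int) * 7)
        assert accuracy(cm) == pytest.approx(100.0)

    def test_uniform_matrix_is_chance(self):
        cm = ConfusionMatrix(labels=list("abcd"), counts=np.full((4, 4), 5))
        assert accuracy(cm) == pytest.approx(25.0)

    def test_hand_row_normalisation(self):
        cm = ConfusionMatrix(labels=list("ab"), counts=np.array([[8, 2], [1, 4]]))
        assert accuracy(cm) == pytest.approx(80.0)

    def test_empty_row_rejected(self):
        cm = ConfusionMatrix(labels=list("ab"), counts=np.array([[3, 1], [0, 0]]))
        with pytest.raises(ValueError, match="empty"):
            accuracy(cm)


class TestLeaveOneRepetitionOutCV:
    def test_perfect_separation_gives_identity_structure(self, rng):
        X = np.vstack([rng.normal(m, 0.05, (30, 2)) for m in ([0, 0], [10, 10])])
        y = np.repeat(["a", "b"], 30)
        reps = np.tile(np.repeat([1, 2, 3], 10), 2)
        cm = leave_one_repetition_out_cv(X, y, reps)
        np.testing.assert_array_equal(cm.counts, np.eye(2, dtype=int) * 30)

    def test_every_window_tested_exactly_once(self, rng):
        n = 90
        X = rng.normal(size=(n, 3)) + np.repeat(np.eye(3), 30, axis=0)
        y = np.repeat(list("abc"), 30)
        reps = np.tile([1, 2, 3], 30)
        cm = leave_one_repetition_out_cv(X, y, reps)
        assert cm.counts.sum() == n
        # row sums equal the per-class window counts
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [30, 30, 30])

    def test_permuted_labels_score_at_chance(self):
        """Shuffled labels on 4 balanced classes give ~25% at n=1000."""
        rng = np.random.default_rng(2024)
        n = 1000
        X = rng.normal(size=(n, 8))
        y = rng.permutation(np.repeat(list("abcd"), n // 4))
        reps = np.tile([1, 2, 3, 1], n // 4)[:n]
        cm = leave_one_repetition_out_cv(X, y, reps)
        assert accuracy(cm) == pytest.approx(25.0, abs=3.0)

    def test_missing_class_in_fold_is_labelled_error(self, rng):
        X = rng.normal(size=(6, 2))
        y = ["a", "a", "a", "b", "b", "b"]
        reps = [1, 2, 3, 1, 1, 1]  # class b absent when rep 1 held out
        with pytest.raises(ValueError, match="'b'.*repetition 1"):
            leave_one_repetition_out_cv(X, y, reps)
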