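import numpy as np
import pytest

from tvcgnet.classify_eval import (
    BENCHMARK_CONFUSION_COMMON,
    ConfusionMatrix,
    SVMConfig,
    aami_metrics,
    confusion,
    f_score,
    fitness,
    predict,
    train_classifier,
)


def _blobs(seed=0, n=50, d=4, spread=4.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n, d)) + spread * k for k in range(3)])
    y = np.array(["N"] * n + ["S"] * n + ["V"] * n, dtype=object)
    return X, y


class TestClassifier:
    def test_separated_blobs_train_perfectly(self):
        X, y = _blobs()
        model = train_classifier(X, y, SVMConfig())
        assert (predict(model, X) == y).all()

    def test_duplicated_training_set_same_decisions(self):
        X, y = _blobs(seed=1)
        probe = np.random.default_rng(9).standard_normal((40, X.shape[1]))
        m1 = train_classifier(X, y, SVMConfig())
        m2 = train_classifier(np.vstack([X, X]), np.concatenate([y, y]),
                              SVMConfig())
        np.testing.assert_array_equal(predict(m1, probe), predict(m2, probe))

    def test_raising_s_weight_does_not_hurt_s_recall(self):
        rng = np.random.default_rng(7)
        # imbalanced, overlapping toy: 200 N vs 20 S vs 60 V
        X = np.vstack([rng.standard_normal((200, 3)),
                       rng.standard_normal((20, 3)) + 1.2,
                       rng.standard_normal((60, 3)) - 1.2])
        y = np.array(["N"] * 200 + ["S"] * 20 + ["V"] * 60, dtype=object)

        def s_recall(w2):
            m = train_classifier(X, y, SVMConfig(class_weights=(1.0, w2, 1.0)))
            pred = predict(m, X)
            return np.mean(pred[y == "S"] == "S")

        assert s_recall(10.0) >= s_recall(1.0)

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train_classifier(X, np.array(["N"] * 5), SVMConfig())

    def test_nan_rejected(self):
        X, y = _blobs()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_classifier(X, y, SVMConfig())

    def test_predict_empty_and_dimension_checks(self):
        X, y = _blobs()
        model = train_classifier(X, y, SVMConfig())
        assert len(predict(model, np.empty((0, X.shape[1])))) == 0
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, X.shape[1] + 1)))

    def test_row_permutation_permutes_predictions(self):
        X, y = _blobs(seed=2)
        model = train_classifier(X, y, SVMConfig())
        probe = np.random.default_rng(3).standard_normal((25, X.shape[1]))
        perm = np.random.default_rng(4).permutation(25)
        np.testing.assert_array_equal(predict(model, probe)[perm],
                                      predict(model, probe[perm]))


class TestConfusion:
    def test_identity_diagonal(self):
        cm = confusion(["N", "S", "V"], ["N", "S", "V"])
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_total_conserved(self):
        rng = np.random.default_rng(5)
        true = rng.choice(["N", "S", "V"], 200)
        pred = rng.choice(["N", "S", "V"], 200)
        assert confusion(true, pred).total == 200

    def test_matches_naive_counting_loop(self):
        rng = np.random.default_rng(6)
        true = rng.choice(["N", "S", "V"], 300)
        pred = rng.choice(["N", "S", "V"], 300)
        cm = confusion(true, pred)
        classes = ("N", "S", "V")
        for i, t in enumerate(classes):
            for j, p in enumerate(classes):
                assert cm.counts[i, j] == sum(
                    1 for a, b in zip(true, pred) if a == t and b == p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["N"], ["N", "S"])


class TestAAMIMetrics:
    def test_identity_matrix_is_perfect(self):
        m = aami_metrics(ConfusionMatrix(np.eye(3, dtype=int) * 10))
        for c in "NSV":
            assert m.se[c] == 1.0
            assert m.positive_predictivity[c] == 1.0
            assert m.fpr[c] == 0.0
        assert m.accuracy == 1.0

    def test_benchmark_matrix_recovers_published_row(self):
        """The shipped inter-patient benchmark matrix must reproduce every
        published metric value after one-decimal half-up rounding."""
        m = aami_metrics(ConfusionMatrix(BENCHMARK_CONFUSION_COMMON))
        assert m.rounded_percent() == {
            "Acc": 92.4,
            "Se_N": 94.0, "+P_N": 98.0, "FPR_N": 17.4,
            "Se_S": 62.0, "+P_S": 53.0, "FPR_S": 2.1,
            "Se_V": 87.3, "+P_V": 59.4, "FPR_V": 4.1,
        }

    def test_tp_sum_equals_trace_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 50, size=(3, 3))
        counts[np.diag_indices(3)] += 1  # avoid all-zero rows
        m1 = aami_metrics(ConfusionMatrix(counts))
        m2 = aami_metrics(ConfusionMatrix(counts * 7))
        for c in "NSV":
            assert m1.se[c] == pytest.approx(m2.se[c])
            assert m1.positive_predictivity[c] == \
                pytest.approx(m2.positive_predictivity[c])

    def test_five_class_fusion_exclusion(self):
        # 2 F beats predicted as V must not count against V's precision
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 10  # N
        counts[1, 1] = 5   # S
        counts[2, 2] = 8   # V
        counts[3, 2] = 2   # F predicted as v -> excluded from V's FP
        m = aami_metrics(ConfusionMatrix(counts, ("N", "S", "V", "F", "Q")))
        assert m.positive_predictivity["V"] == 1.0
        assert m.fpr["V"] == 0.0

    def test_zero_denominator_flagged(self):
        counts = np.array([[5, 0, 0], [0, 0, 0], [0, 0, 3]])
        m = aami_metrics(ConfusionMatrix(counts))
        assert m.se["S"] == 0.0
        assert "Se_S" in m.zero_denominator_flags


class TestFScoreAndFitness:
    @pytest.mark.parametrize("x", [0.0, 0.3, 1.0])
    def test_harmonic_mean_identity(self, x):
        assert f_score(x, x) == pytest.approx(x)

    def test_arithmetic_example(self):
        assert f_score(0.62, 0.53) == pytest.approx(2 * 0.62 * 0.53 / 1.15)

    def test_degenerate_zero(self):
        assert f_score(0.0, 0.0) == 0.0

    def test_identity_matrix_fitness_one(self):
        assert fitness(ConfusionMatrix(np.eye(3, dtype=int) * 4)).mean == 1.0

    def test_single_column_predictions(self):
        counts = np.array([[10, 0, 0], [4, 0, 0], [6, 0, 0]])
        fit = fitness(ConfusionMatrix(counts))
        assert fit.per_class["S"] == 0.0
        assert fit.per_class["V"] == 0.0

    def test_benchmark_fitness_composes_from_per_class_f_scores(self):
        cm = ConfusionMatrix(BENCHMARK_CONFUSION_COMMON)
        m = aami_metrics(cm)
        expected = np.mean([
            f_score(m.se[c], m.positive_predictivity[c]) for c in "NSV"
        ])
        assert fitness(cm).mean == pytest.approx(expected)

    def test_weighted_mean(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 3)
        assert fitness(cm, weights={"N": 1, "S": 2, "V": 3}).mean == \
            pytest.approx(1.0)
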