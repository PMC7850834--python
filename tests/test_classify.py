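import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emdwave.classify import (
    EvalReport,
    WkNNModel,
    cross_validate,
    euclidean_distance,
    evaluate,
    inverse_square_weights,
    wknn_predict,
)
from emdwave.io_signals import ConfigurationError, DomainError, FeatureTable


def brute_force_wknn(train_X, train_y, query, k):
    """Independent oracle: explicit loops over the distance and 1/d² rules."""
    dists = []
    for row in train_X:
        s = 0.0
        for a, b in zip(row, query):
            s += (a - b) ** 2
        dists.append(math.sqrt(s))
    order = sorted(range(len(dists)), key=lambda i: dists[i])[:k]
    exact = [i for i in order if dists[i] == 0.0]
    votes = {}
    if exact:
        for i in exact:
            votes[train_y[i]] = votes.get(train_y[i], 0.0) + 1.0 / len(exact)
    else:
        for i in order:
            votes[train_y[i]] = votes.get(train_y[i], 0.0) + 1.0 / dists[i] ** 2
    best = max(votes.values())
    winners = sorted(lbl for lbl, v in votes.items() if v == best)
    if len(winners) > 1 and train_y[order[0]] in winners:
        return train_y[order[0]]
    return winners[0]


class TestDistanceAndWeights:
    @pytest.mark.parametrize("x, y, expected", [
        ((0, 0), (3, 4), 5.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 1, 1), (2, 2, 2), math.sqrt(3)),
    ])
    def test_euclidean_examples(self, x, y, expected):
        assert euclidean_distance(np.array(x), np.array(y)) == pytest.approx(
            expected
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            euclidean_distance(np.ones(3), np.ones(4))

    @pytest.mark.parametrize("d, w", [(2.0, 0.25), (1.0, 1.0), (0.5, 4.0)])
    def test_inverse_square_rule(self, d, w):
        assert inverse_square_weights(np.array([d]))[0] == pytest.approx(w)

    def test_exact_match_takes_all_weight(self):
        w = inverse_square_weights(np.array([0.0, 5.0]))
        assert list(w) == [1.0, 0.0]

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            inverse_square_weights(np.array([-1.0]))


class TestPredict:
    def test_single_training_point_always_wins(self, rng):
        model = WkNNModel(X=np.array([[1.0, 2.0]]), y=np.array(["high"]))
        for _ in range(5):
            label, _ = wknn_predict(model, rng.normal(size=2))
            assert label == "high"

    def test_hand_computed_two_point_example(self):
        # distances 1 and 3 -> weights 1 vs 1/9 -> the near point decides
        model = WkNNModel(X=np.array([[1.0], [3.0]]),
                          y=np.array(["high", "low"]), k=2)
        label, sums = wknn_predict(model, np.array([0.0]))
        assert label == "high"
        assert sums["high"] == pytest.approx(1.0)
        assert sums["low"] == pytest.approx(1.0 / 9.0)

    def test_exact_duplicate_returns_its_label(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array(["high", "low"] * 5)
        model = WkNNModel(X=X, y=y)
        for i in [0, 3, 7]:
            label, _ = wknn_predict(model, X[i])
            assert label == y[i]

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            X = rng.normal(size=(5, 3))
            y = rng.choice(["high", "low"], size=5)
            if len(set(y)) < 2:
                y[0] = "high" if y[1] == "low" else "low"
            query = rng.normal(size=3)
            for k in (1, 3, 5):
                model = WkNNModel(X=X, y=y, k=k)
                assert wknn_predict(model, query)[0] == brute_force_wknn(
                    X, list(y), query, k
                )

    def test_k1_equals_plain_nearest_neighbour(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.choice(["high", "low"], size=20)
        model = WkNNModel(X=X, y=y, k=1)
        for _ in range(20):
            q = rng.normal(size=4)
            nearest = np.argmin(np.linalg.norm(X - q, axis=1))
            assert wknn_predict(model, q)[0] == y[nearest]

    def test_invariant_to_training_row_permutation(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.choice(["high", "low"], size=12)
        perm = rng.permutation(12)
        a = WkNNModel(X=X, y=y)
        b = WkNNModel(X=X[perm], y=y[perm])
        for _ in range(10):
            q = rng.normal(size=3)
            assert wknn_predict(a, q)[0] == wknn_predict(b, q)[0]

    def test_duplicating_a_row_never_flips_away_from_it(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array(["high", "low"] * 4)
        q = rng.normal(size=2)
        base = WkNNModel(X=X, y=y)
        before, _ = wknn_predict(base, q)
        for i in range(8):
            dup = WkNNModel(X=np.vstack([X, X[i]]),
                            y=np.append(y, y[i]))
            after, _ = wknn_predict(dup, q)
            if before == y[i]:
                assert after == y[i]

    def test_dimension_mismatch_rejected(self, rng):
        model = WkNNModel(X=rng.normal(size=(3, 4)),
                          y=np.array(["high", "low", "high"]))
        with pytest.raises(DomainError):
            wknn_predict(model, np.ones(5))

    def test_empty_model_rejected(self):
        with pytest.raises(ConfigurationError):
            WkNNModel(X=np.empty((0, 3)), y=np.empty(0))


class TestEvaluate:
    def test_perfect_prediction(self):
        labels = ["high", "low"] * 4
        rep = evaluate(labels, labels)
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == (
            100.0, 100.0, 100.0
        )

    def test_eleven_positive_ten_negative_confusion(self):
        # TP=9 FN=2 TN=9 FP=1: the unique confusion matrix with 11
        # positives and 10 negatives giving 85.7 / 81.8 / 90.0
        rep = EvalReport(tp=9, fn=2, tn=9, fp=1)
        assert rep.accuracy == 85.7
        assert rep.sensitivity == 81.8
        assert rep.specificity == 90.0

    def test_degenerate_all_one_class(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = evaluate(["high"] * 4, ["low"] * 4)
            assert rep.accuracy == 0.0
            assert rep.specificity == 0.0
            assert math.isnan(rep.sensitivity)

    def test_unknown_label_rejected(self):
        with pytest.raises(DomainError):
            evaluate(["high", "meh"], ["high", "low"])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_metric_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        rep = EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)
        assert rep.accuracy == pytest.approx(
            round(100 * (tp + tn) / (tp + fp + tn + fn), 1)
        )
        if tp + fn:
            assert rep.sensitivity == pytest.approx(
                round(100 * tp / (tp + fn), 1)
            )
        if tn + fp:
            assert rep.specificity == pytest.approx(
                round(100 * tn / (tn + fp), 1)
            )


def table_from_arrays(X, y):
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    frame["label"] = y
    return FeatureTable(frame=frame, method="custom")


class TestCrossValidate:
    def test_separated_clusters_are_perfect_loo(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(10, 3)),
                       rng.normal(50, 0.1, size=(10, 3))])
        y = ["high"] * 10 + ["low"] * 10
        rep = cross_validate(table_from_arrays(X, y), scheme="loo")
        assert rep.accuracy == 100.0

    def test_random_labels_are_chance_level(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.permutation(["high"] * 20 + ["low"] * 20)
        rep = cross_validate(table_from_arrays(X, y), scheme="loo")
        assert 30.0 <= rep.accuracy <= 70.0

    def test_single_row_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = ["high"] * 4 + ["low"]
        with pytest.raises(ConfigurationError):
            cross_validate(table_from_arrays(X, y))

    def test_stratified_kfold_runs_and_is_seeded(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(10, 3)),
                       rng.normal(5, 1, size=(10, 3))])
        y = ["high"] * 10 + ["low"] * 10
        table = table_from_arrays(X, y)
        a = cross_validate(table, scheme="kfold", seed=3)
        b = cross_validate(table, scheme="kfold", seed=3)
        assert a.as_dict() == b.as_dict()
        assert a.n == 20
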