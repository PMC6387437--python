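"""Quality classifiers: kNN contracts, LDA, one-vs-one SVM, full pipeline."""

import numpy as np
import pytest

from eegqc.classification import (
    KNNQuality,
    LDAQuality,
    QualityClassifier,
    SVMQuality,
    euclidean_distance,
    inverse_square_weight,
)
from eegqc.labels import HIGH_Q, LOW_Q, MED_MUSC, MED_Q
from eegqc.simulate import generate_clean_segment, generate_muscular_artefact, mix_at_snr

FS = 250


class TestDistancePrimitives:
    @pytest.mark.parametrize(
        "x, y, expected",
        [((0, 0), (3, 4), 5.0), ((1, 2), (1, 2), 0.0), ((1, 1, 1), (2, 2, 2), np.sqrt(3))],
    )
    def test_euclidean(self, x, y, expected):
        assert euclidean_distance(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_euclidean_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance(np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize("d, w", [(5.0, 0.04), (1.0, 1.0), (0.5, 4.0)])
    def test_inverse_square_weight(self, d, w):
        assert inverse_square_weight(d) == pytest.approx(w)

    def test_zero_distance_weight_is_infinite(self):
        assert inverse_square_weight(0.0) == np.inf


def knn_oracle(X_train, y_train, x, k, weighted):
    """Exhaustive neighbour search with the declared vote/tie contracts."""
    rank = {LOW_Q: 0, MED_Q: 1, HIGH_Q: 2}
    dists = np.array([euclidean_distance(row, x) for row in X_train])
    kth = sorted(dists)[k - 1]
    idx = [i for i in range(len(dists)) if dists[i] <= kth]
    zero = [i for i in idx if dists[i] == 0]
    votes = {}
    if zero:
        for i in zero:
            votes[y_train[i]] = votes.get(y_train[i], 0) + 1
    else:
        for i in idx:
            w = 1.0 if not weighted else 1.0 / dists[i] ** 2
            votes[y_train[i]] = votes.get(y_train[i], 0) + w
    best = max(votes.values())
    return min((c for c, v in votes.items() if v == best), key=lambda c: rank[c])


class TestKNN:
    LABELS = [LOW_Q, MED_Q, HIGH_Q]

    def test_k1_returns_nearest_label(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        y = np.array([HIGH_Q, LOW_Q], dtype=object)
        model = KNNQuality(k=1).fit(X, y)
        assert model.predict([[1.0, 1.0]])[0] == HIGH_Q

    def test_majority_vote(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        y = np.array([MED_Q, MED_Q, HIGH_Q], dtype=object)
        model = KNNQuality(k=3, weights="uniform").fit(X, y)
        assert model.predict([[0.0, 0.0]])[0] == MED_Q

    def test_tie_breaks_toward_worse_quality(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([HIGH_Q, MED_Q], dtype=object)
        model = KNNQuality(k=2, weights="uniform").fit(X, y)
        assert model.predict([[0.0, 0.0]])[0] == MED_Q

    def test_exact_match_inherits_label(self):
        X = np.array([[1.0, 1.0], [5.0, 5.0], [6.0, 6.0]])
        y = np.array([HIGH_Q, LOW_Q, LOW_Q], dtype=object)
        model = KNNQuality(k=3, weights="inverse_square").fit(X, y)
        assert model.predict([[1.0, 1.0]])[0] == HIGH_Q

    def test_equal_distances_reduce_to_majority(self, rng):
        # all training points on a circle around the query
        angles = rng.uniform(0, 2 * np.pi, 9)
        X = np.column_stack([np.cos(angles), np.sin(angles)])
        y = np.array([MED_Q] * 5 + [HIGH_Q] * 4, dtype=object)
        weighted = KNNQuality(k=9, weights="inverse_square").fit(X, y)
        uniform = KNNQuality(k=9, weights="uniform").fit(X, y)
        q = [[0.0, 0.0]]
        assert weighted.predict(q)[0] == uniform.predict(q)[0] == MED_Q

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="k="):
            KNNQuality(k=5).fit(np.zeros((3, 2)), np.array([LOW_Q, MED_Q, HIGH_Q]))

    def test_predict_before_fit_rejected(self):
        with pytest.raises(Exception):
            KNNQuality(k=1).predict([[0.0]])

    @pytest.mark.parametrize("weights", ["uniform", "inverse_square"])
    def test_oracle_equivalence(self, weights):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            d = int(rng.integers(1, 11))
            k = int(rng.integers(1, min(n, 9) + 1))
            X = rng.standard_normal((n, d))
            y = rng.choice(self.LABELS, n).astype(object)
            if len(np.unique(y)) < 2:
                y[0] = LOW_Q if y[1] != LOW_Q else HIGH_Q
            model = KNNQuality(k=k, weights=weights).fit(X, y)
            queries = rng.standard_normal((5, d))
            got = model.predict(queries)
            for q, g in zip(queries, got):
                assert g == knn_oracle(X, y, q, k, weights == "inverse_square")

    def test_training_order_invariance(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.choice(self.LABELS, 40).astype(object)
        queries = rng.standard_normal((10, 4))
        base = KNNQuality(k=7).fit(X, y).predict(queries)
        for _ in range(5):
            perm = rng.permutation(40)
            got = KNNQuality(k=7).fit(X[perm], y[perm]).predict(queries)
            np.testing.assert_array_equal(got, base)


class TestLDA:
    def test_separated_gaussians(self, rng):
        X = np.concatenate([rng.normal(-5, 0.5, 100), rng.normal(5, 0.5, 100)])[:, None]
        y = np.array([LOW_Q] * 100 + [HIGH_Q] * 100, dtype=object)
        model = LDAQuality().fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_priors_are_class_proportions(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.array([LOW_Q] * 10 + [MED_Q] * 6 + [HIGH_Q] * 4, dtype=object)
        model = LDAQuality().fit(X, y)
        assert model.priors_[LOW_Q] == pytest.approx(0.5)
        assert model.priors_[MED_Q] == pytest.approx(0.3)
        assert model.priors_[HIGH_Q] == pytest.approx(0.2)

    def test_undersized_class_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="at least 2"):
            LDAQuality().fit(X, np.array([LOW_Q, LOW_Q, HIGH_Q], dtype=object))


class TestSVM:
    def test_three_classes_three_pairwise_classifiers(self, rng):
        X = np.concatenate(
            [rng.normal(c, 0.3, (20, 2)) for c in (-5.0, 0.0, 5.0)]
        )
        y = np.array([LOW_Q] * 20 + [MED_Q] * 20 + [HIGH_Q] * 20, dtype=object)
        model = SVMQuality().fit(X, y)
        assert model.n_pairwise_ == 3

    def test_separable_blobs_fit_perfectly(self, rng):
        X = np.concatenate([rng.normal(-3, 0.2, (30, 2)), rng.normal(3, 0.2, (30, 2))])
        y = np.array([MED_Q] * 30 + [HIGH_Q] * 30, dtype=object)
        model = SVMQuality().fit(X, y)
        assert (model.predict(X) == y).all()

    def test_circular_vote_tie_resolves_to_worst(self, rng):
        X = np.concatenate([rng.normal(c, 0.3, (10, 2)) for c in (-5.0, 0.0, 5.0)])
        y = np.array([LOW_Q] * 10 + [MED_Q] * 10 + [HIGH_Q] * 10, dtype=object)
        model = SVMQuality().fit(X, y)
        votes = np.array([[1.0, 1.0, 1.0]])  # one pairwise vote each
        model_votes = model._votes  # exercise the declared tie contract
        try:
            model._votes = lambda X_: votes
            assert model.predict([[0.0, 0.0]])[0] == LOW_Q
        finally:
            model._votes = model_votes


class TestPipeline:
    def test_prescreen_overrides_classifier(self, fitted_model, rng):
        x = rng.standard_normal(FS) * 15
        x[:200] = x[0]  # 80% identical samples
        assert fitted_model.predict(x[None, :])[0] == LOW_Q

    def test_clean_segment_predicted_high_quality(self, fitted_model):
        segs = np.stack(
            [generate_clean_segment(seed=900 + i).samples for i in range(20)]
        )
        pred = fitted_model.predict(segs)
        assert (pred == HIGH_Q).mean() >= 0.8

    def test_muscular_burst_refined(self, fitted_model):
        hits = 0
        for i in range(20):
            b = generate_clean_segment(seed=700 + i)
            v = generate_muscular_artefact(seed=800 + i)
            seg = mix_at_snr(b, v, 0.0)
            if fitted_model.predict(seg.samples[None, :])[0] == MED_MUSC:
                hits += 1
        assert hits >= 14  # strong bursts are mostly flagged muscular

    def test_unknown_classifier_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown classifier"):
            QualityClassifier(classifier="nope").fit(
                small_dataset.X, small_dataset.labels
            )

    def test_predict_scores_shape_and_low_override(self, fitted_model, rng):
        x = rng.standard_normal((2, FS)) * 15
        x[0, 5] = 400.0
        classes, scores = fitted_model.predict_scores(x)
        assert list(classes) == [LOW_Q, MED_Q, HIGH_Q]
        assert scores.shape == (2, 3)
        assert scores[0, 0] == 1.0
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)
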