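"""Quality classifiers and the end-to-end prediction pipeline.

Four three-class classifiers are supported over {LOW_Q, MED_Q, HIGH_Q}:
linear discriminant analysis, a linear one-vs-one support vector machine,
and k-nearest-neighbours in Euclidean and inverse-square-distance-weighted
flavours.  All class-vote ties break toward the worse quality — for a
quality gate, a false alarm is cheaper than passing an artefact downstream.

:class:`QualityClassifier` is the full pipeline as one scikit-learn
estimator operating on raw segment samples:

    prescreen → DC/notch → features → standardise → FCBF → classifier
    → muscular refinement (MED_Q segments may become MED_MUSC)

Standardisation statistics, the selected feature set, the classifier state
and the spectral reference are all fitted strictly on the training data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import SegmentFeaturizer
from .labels import CLASS_ORDER, HIGH_Q, LOW_Q, MED_MUSC, MED_Q, coarse_label
from .muscular import DEFAULT_N_GRID, ItakuraMuscularDetector
from .preprocessing import Segment, prescreen, remove_dc_and_notch
from .selection import FCBFSelector

_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}  # LOW_Q worst


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two equally shaped feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"feature-set mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def inverse_square_weight(d: float) -> float:
    """Neighbour weight 1/d²; d = 0 is handled by the exact-match rule in kNN."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return np.inf if d == 0 else 1.0 / (d * d)


def _worst(labels: Sequence[str]) -> str:
    return min(labels, key=lambda c: _RANK[c])


class KNNQuality(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour quality classifier with conservative tie rules.

    Parameters
    ----------
    k : int
        Neighbour count.
    weights : {"uniform", "inverse_square"}
        "uniform" votes by neighbour majority; "inverse_square" weights each
        neighbour by 1/d².  An exact feature match (d = 0) dominates: the
        query inherits the majority label among zero-distance neighbours.

    Notes
    -----
    Neighbour sets include every training point tied with the k-th smallest
    distance, so predictions are invariant to training-set order; class-vote
    ties break toward the worse quality.
    """

    def __init__(self, k: int = 7, weights: str = "inverse_square"):
        self.k = k
        self.weights = weights

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        if not 1 <= self.k <= len(X):
            raise ValueError(f"k={self.k} outside [1, n_train={len(X)}]")
        if self.weights not in ("uniform", "inverse_square"):
            raise ValueError(f"unknown weights {self.weights!r}")
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(np.unique(y), key=lambda c: _RANK[c]), dtype=object)
        return self

    def _vote(self, dists: np.ndarray) -> dict[str, float]:
        kth = np.partition(dists, self.k - 1)[self.k - 1]
        # include every point tied with the k-th distance: order-invariant
        neigh = np.flatnonzero(dists <= kth)
        zero = neigh[dists[neigh] == 0]
        votes: dict[str, float] = {}
        if len(zero):
            for lbl in self._y[zero]:
                votes[lbl] = votes.get(lbl, 0.0) + 1.0
            return votes
        for i in neigh:
            w = 1.0 if self.weights == "uniform" else 1.0 / dists[i] ** 2
            votes[self._y[i]] = votes.get(self._y[i], 0.0) + w
        return votes

    def _vote_matrix(self, X) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "_X")
        X = check_array(X)
        D = np.sqrt(
            np.maximum(
                (X**2).sum(1)[:, None] - 2 * X @ self._X.T + (self._X**2).sum(1)[None, :],
                0.0,
            )
        )
        out = np.empty((len(X), len(self.classes_)))
        preds = np.empty(len(X), dtype=object)
        for i in range(len(X)):
            votes = self._vote(D[i])
            total = sum(votes.values())
            out[i] = [votes.get(c, 0.0) / total for c in self.classes_]
            best = max(votes.values())
            preds[i] = _worst([c for c, v in votes.items() if v == best])
        return preds, out

    def predict(self, X) -> np.ndarray:
        return self._vote_matrix(X)[0]

    def predict_proba(self, X) -> np.ndarray:
        """Normalised vote fractions per class (used as ROC scores)."""
        return self._vote_matrix(X)[1]


class LDAQuality(ClassifierMixin, BaseEstimator):
    """LDA with class-proportion priors; Gaussian class conditionals with a
    shared covariance, prediction by the Bayes rule argmax P(X|l)P(l)."""

    def __init__(self):
        pass

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("LDA needs at least 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 training segments")
        self._lda = LinearDiscriminantAnalysis(solver="svd", tol=1e-6).fit(X, y)
        self.classes_ = np.array(sorted(classes, key=lambda c: _RANK[c]), dtype=object)
        self.priors_ = dict(zip(classes, counts / counts.sum()))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_lda")
        return self._lda.predict(check_array(X)).astype(object)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_lda")
        proba = self._lda.predict_proba(check_array(X))
        cols = [list(self._lda.classes_).index(c) for c in self.classes_]
        return proba[:, cols]


class SVMQuality(ClassifierMixin, BaseEstimator):
    """Linear one-vs-one SVM: L(L-1)/2 binary max-margin classifiers with a
    pairwise-vote majority; vote ties break toward the worse quality.

    Parameters
    ----------
    C : float
        Soft-margin regularisation parameter.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("SVM needs at least 2 classes")
        self._svc = SVC(kernel="linear", C=self.C, decision_function_shape="ovo").fit(X, y)
        if self._svc.fit_status_ != 0:
            raise RuntimeError("SVM solver did not converge")
        self.classes_ = np.array(sorted(classes, key=lambda c: _RANK[c]), dtype=object)
        self.n_pairwise_ = len(classes) * (len(classes) - 1) // 2
        return self

    def _votes(self, X) -> np.ndarray:
        """Pairwise-vote counts per class, ordered like ``classes_``."""
        check_is_fitted(self, "_svc")
        X = check_array(X)
        dec = self._svc.decision_function(X)
        svc_classes = list(self._svc.classes_)
        votes = np.zeros((len(X), len(svc_classes)))
        if len(svc_classes) == 2:
            # binary decision: positive favours the second class
            votes[:, 1] += dec > 0
            votes[:, 0] += dec <= 0
        else:
            pair = 0
            for i in range(len(svc_classes)):
                for j in range(i + 1, len(svc_classes)):
                    # ovo convention: positive favours the first class of the pair
                    votes[:, i] += dec[:, pair] > 0
                    votes[:, j] += dec[:, pair] <= 0
                    pair += 1
        cols = [svc_classes.index(c) for c in self.classes_]
        return votes[:, cols]

    def predict(self, X) -> np.ndarray:
        votes = self._votes(X)
        preds = np.empty(len(votes), dtype=object)
        for i, row in enumerate(votes):
            best = row.max()
            preds[i] = _worst([self.classes_[j] for j in np.flatnonzero(row == best)])
        return preds

    def predict_proba(self, X) -> np.ndarray:
        """Pairwise-vote fractions (not calibrated probabilities)."""
        votes = self._votes(X)
        return votes / votes.sum(axis=1, keepdims=True)


_CLASSIFIERS = {
    "lda": lambda self: LDAQuality(),
    "linear_svm": lambda self: SVMQuality(C=self.C),
    "knn_euclidean": lambda self: KNNQuality(k=self.k, weights="uniform"),
    "weighted_knn": lambda self: KNNQuality(k=self.k, weights="inverse_square"),
}


class QualityClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end single-channel EEG quality assessment.

    Operates directly on raw segment samples: ``X`` is an
    ``(n_segments, sampling_rate)`` array in μV; ``y`` holds the 4-level
    labels (MED_MUSC is folded into MED_Q for the 3-class classifier and
    re-split by the muscular refinement at prediction time).

    Parameters
    ----------
    classifier : {"weighted_knn", "knn_euclidean", "lda", "linear_svm"}
        The 3-class classifier.
    k : int
        Neighbour count for the kNN variants.
    C : float
        Regularisation parameter of the linear SVM.
    delta : float
        FCBF relevance threshold on SU(feature, class).
    n_bins : int
        Equal-frequency bins for FCBF discretisation.
    sampling_rate : int
        Hz; also the per-row sample count of X.
    notch_freq : float
        Mains notch frequency (50 or 60 Hz).
    constant_fraction : float
        Prescreen: maximal tolerated fraction of identical samples.
    amplitude_limit : float
        Prescreen: absolute amplitude bound in μV.
    amplitude_on : {"filtered", "raw"}
        Whether the amplitude rule sees the DC-removed or the raw samples.
    muscular : bool
        Calibrate and apply the Itakura muscular refinement (requires
        MED_MUSC examples in the training set).
    n_grid : sequence of float
        Candidate threshold multipliers for the muscular calibration.
    """

    def __init__(
        self,
        classifier: str = "weighted_knn",
        k: int = 7,
        C: float = 1.0,
        delta: float = 0.0,
        n_bins: int = 10,
        sampling_rate: int = 250,
        notch_freq: float = 50.0,
        constant_fraction: float = 0.70,
        amplitude_limit: float = 300.0,
        amplitude_on: str = "filtered",
        muscular: bool = True,
        n_grid: Sequence[float] = DEFAULT_N_GRID,
    ):
        self.classifier = classifier
        self.k = k
        self.C = C
        self.delta = delta
        self.n_bins = n_bins
        self.sampling_rate = sampling_rate
        self.notch_freq = notch_freq
        self.constant_fraction = constant_fraction
        self.amplitude_limit = amplitude_limit
        self.amplitude_on = amplitude_on
        self.muscular = muscular
        self.n_grid = n_grid

    # -- pipeline stages -----------------------------------------------------

    def _clean(self, X: np.ndarray) -> np.ndarray:
        """DC removal + notch per row."""
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            out[i] = remove_dc_and_notch(
                Segment(row, self.sampling_rate), self.notch_freq
            ).samples
        return out

    def _prescreen_mask(self, X_raw: np.ndarray, X_clean: np.ndarray) -> np.ndarray:
        amp = X_clean if self.amplitude_on == "filtered" else X_raw
        return np.array(
            [
                prescreen(
                    X_raw[i],
                    self.constant_fraction,
                    self.amplitude_limit,
                    amplitude_samples=amp[i],
                )
                == LOW_Q
                for i in range(len(X_raw))
            ]
        )

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        if self.classifier not in _CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.shape[1] != self.sampling_rate:
            raise ValueError(
                f"segments must hold sampling_rate={self.sampling_rate} samples"
            )
        y3 = np.array([coarse_label(l) for l in y], dtype=object)

        X_clean = self._clean(X)
        self.featurizer_ = SegmentFeaturizer(self.sampling_rate).fit(X_clean)
        F = self.featurizer_.transform(X_clean)
        self.scaler_ = StandardScaler().fit(F)
        Z = self.scaler_.transform(F)
        self.selector_ = FCBFSelector(
            delta=self.delta, n_bins=self.n_bins, feature_names=self.featurizer_.feature_names_
        ).fit(Z, y3)
        Zs = self.selector_.transform(Z)
        self.base_classifier_ = _CLASSIFIERS[self.classifier](self).fit(Zs, y3)

        self.reference_ = None
        if self.muscular and np.any(y == MED_MUSC):
            self.detector_ = ItakuraMuscularDetector(self.sampling_rate, self.n_grid).fit(
                X_clean, y
            )
            self.reference_ = self.detector_.reference_
        self.classes_ = np.asarray(
            [LOW_Q, MED_Q, MED_MUSC, HIGH_Q] if self.reference_ is not None
            else [LOW_Q, MED_Q, HIGH_Q],
            dtype=object,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _stages(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        check_is_fitted(self, "base_classifier_")
        X = np.asarray(check_array(X), dtype=float)
        X_clean = self._clean(X)
        override = self._prescreen_mask(X, X_clean)
        Zs = self.selector_.transform(self.scaler_.transform(self.featurizer_.transform(X_clean)))
        return X_clean, override, Zs

    def predict(self, X) -> np.ndarray:
        """4-level label per segment: prescreen override → classifier →
        muscular refinement of MED_Q segments."""
        X_clean, override, Zs = self._stages(X)
        pred = self.base_classifier_.predict(Zs)
        pred = np.where(override, LOW_Q, pred).astype(object)
        if self.reference_ is not None:
            med = (pred == MED_Q) & ~override
            if med.any():
                pred[med] = self.detector_.predict(X_clean[med])
        return pred

    def predict_scores(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-class scores over the 3 coarse classes (for one-vs-rest ROC).

        Prescreen-overridden segments score 1 for LOW_Q.  Returns
        ``(class_order, scores)`` with columns ordered LOW_Q, MED_Q, HIGH_Q.
        """
        _, override, Zs = self._stages(X)
        proba = self.base_classifier_.predict_proba(Zs)
        cols = {c: i for i, c in enumerate(self.base_classifier_.classes_)}
        scores = np.zeros((len(Zs), len(CLASS_ORDER)))
        for j, c in enumerate(CLASS_ORDER):
            if c in cols:
                scores[:, j] = proba[:, cols[c]]
        scores[override] = 0.0
        scores[override, CLASS_ORDER.index(LOW_Q)] = 1.0
        return np.asarray(CLASS_ORDER, dtype=object), scores

    def predict_segment(self, seg: Segment) -> str:
        """Convenience single-segment prediction."""
        return self.predict(seg.samples[None, :])[0]


# ---------------------------------------------------------------------------
# thin functional wrappers


def knn_predict(model: KNNQuality, x: np.ndarray) -> str:
    """Predict the quality label of one standardized, selected feature vector."""
    return model.predict(np.atleast_2d(x))[0]


def lda_fit(features, labels) -> LDAQuality:
    return LDAQuality().fit(features, labels)


def lda_predict(model: LDAQuality, x) -> str:
    return model.predict(np.atleast_2d(x))[0]


def svm_ovo_fit(features, labels, C: float = 1.0) -> SVMQuality:
    return SVMQuality(C=C).fit(features, labels)


def svm_ovo_predict(model: SVMQuality, x) -> str:
    return model.predict(np.atleast_2d(x))[0]


def predict_quality(model: QualityClassifier, seg: Segment) -> str:
    return model.predict_segment(seg)
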