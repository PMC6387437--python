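"""Cross-validated evaluation, parameter sweeps and a threshold baseline.

Performance is reported as a 3-class confusion matrix (LOW_Q / MED_Q /
HIGH_Q, with MED_MUSC counted as medium quality), per-class and total
accuracy, the muscular-refinement accuracy among segments classified as
medium quality, and one-vs-rest ROC AUC per class.  All model fitting —
standardisation, feature selection, classifier and muscular calibration —
happens strictly inside each training fold.

The threshold baseline reimplements the classical approach the classifier
is compared against: per-metric amplitude-statistic intervals calibrated on
clean training EEG, flagging any test segment that falls outside any
interval.  It only separates clean from contaminated segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold

from .classification import QualityClassifier
from .labels import CLASS_ORDER, HIGH_Q, LOW_Q, MED_MUSC, MED_Q, coarse_label
from .preprocessing import BandDefinition, bandpass_array
from .simulate import DatasetConfig, LabelledDataset, build_dataset


def roc_auc_one_vs_rest(scores: np.ndarray, labels: Sequence, positive_class) -> float:
    """AUC of *scores* for one class against the rest, by the rank statistic.

    Equivalent to the normalised Mann-Whitney U; tied scores contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([l == positive_class for l in labels])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative examples")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Aggregated test-fold performance of one cross-validation run."""

    confusion_matrix: pd.DataFrame  # rows true, cols predicted (coarse classes)
    per_class_accuracy: dict[str, float]
    total_accuracy: float
    med_musc_accuracy: Optional[float]
    auc_per_class: dict[str, float]
    fold_assignments: np.ndarray
    predictions: np.ndarray
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": f"accuracy_{c}", "value": self.per_class_accuracy[c]}
            for c in CLASS_ORDER
        ]
        rows.append({"metric": "total_accuracy", "value": self.total_accuracy})
        if self.med_musc_accuracy is not None:
            rows.append({"metric": "med_musc_accuracy", "value": self.med_musc_accuracy})
        for c, v in self.auc_per_class.items():
            rows.append({"metric": f"auc_{c}", "value": v})
        return pd.DataFrame(rows)


def _confusion(y_true3, y_pred3) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    for t, p in zip(y_true3, y_pred3):
        cm.loc[t, p] += 1
    return cm


def cross_validate(
    dataset: LabelledDataset,
    estimator: Optional[QualityClassifier] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Folds are stratified on the 4-level labels so MED_MUSC examples reach
    every training fold (the muscular calibration needs them).
    """
    estimator = estimator or QualityClassifier(
        classifier="weighted_knn", k=10, sampling_rate=dataset.sampling_rate
    )
    y = dataset.labels
    y3 = np.array([coarse_label(l) for l in y], dtype=object)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    preds = np.empty(len(y), dtype=object)
    scores = np.zeros((len(y), len(CLASS_ORDER)))
    for f, (tr, te) in enumerate(skf.split(dataset.X, y.astype(str))):
        for cls in np.unique(y):
            if cls not in y[tr]:
                raise ValueError(
                    f"class {cls} absent from training fold {f}; provide more data"
                )
        model = clone(estimator).fit(dataset.X[tr], y[tr])
        preds[te] = model.predict(dataset.X[te])
        _, s = model.predict_scores(dataset.X[te])
        scores[te] = s
        folds[te] = f

    pred3 = np.array([coarse_label(l) for l in preds], dtype=object)
    cm = _confusion(y3, pred3)
    per_class = {
        c: float(cm.loc[c, c] / cm.loc[c].sum()) if cm.loc[c].sum() else np.nan
        for c in CLASS_ORDER
    }
    total = float(np.trace(cm.to_numpy()) / cm.to_numpy().sum())

    # muscular refinement accuracy among segments classified medium-quality
    med_musc_acc = None
    med_pred = pred3 == MED_Q
    med_both = med_pred & (y3 == MED_Q)
    if med_both.any() and (y == MED_MUSC).any():
        med_musc_acc = float(np.mean(preds[med_both] == y[med_both]))

    auc = {
        c: roc_auc_one_vs_rest(scores[:, j], y3, c) for j, c in enumerate(CLASS_ORDER)
    }
    return EvaluationReport(cm, per_class, total, med_musc_acc, auc, folds, preds, seed)


def k_sweep(
    dataset: LabelledDataset,
    k_range: Sequence[int] = range(1, 21),
    n_folds: int = 5,
    seed: int = 0,
    classifier: str = "weighted_knn",
) -> pd.DataFrame:
    """Total CV accuracy as a function of the neighbour count k.

    Fold assignments are identical across k (they depend only on *seed*).
    Returns a table with columns ``k`` and ``total_accuracy``; the best k is
    the row with maximal accuracy (smallest k on ties).
    """
    rows = []
    for k in k_range:
        est = QualityClassifier(
            classifier=classifier, k=k, sampling_rate=dataset.sampling_rate
        )
        rep = cross_validate(dataset, est, n_folds=n_folds, seed=seed)
        rows.append({"k": k, "total_accuracy": rep.total_accuracy})
    return pd.DataFrame(rows)


DEFAULT_SNR_BINS = ((-10.0, 0.0), (0.0, 5.0), (5.0, 10.0), (10.0, 15.0))


def snr_sweep(
    base_config: Optional[DatasetConfig] = None,
    snr_bins: Sequence[tuple[float, float]] = DEFAULT_SNR_BINS,
    n_runs: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    estimator: Optional[QualityClassifier] = None,
) -> pd.DataFrame:
    """Detection accuracy of contaminated segments per SNR bin.

    Each run regenerates the dataset with a run-specific seed and runs a
    full cross-validation; contaminated segments are bucketed by their
    generation SNR and scored by the fraction predicted with their true
    label.  Clean segments are reported separately under the "clean" bin.
    Also reports, per bin, the fraction of misclassified segments that were
    labelled HIGH_Q (high-SNR artefacts fail mostly by looking clean).
    """
    base_config = base_config or DatasetConfig()
    rows = []
    for run in range(n_runs):
        ds = build_dataset(base_config, seed=seed + 1000 * run)
        rep = cross_validate(ds, estimator, n_folds=n_folds, seed=seed + run)
        correct = rep.predictions == ds.labels
        clean = np.isnan(ds.snrs)
        rows.append(
            {
                "run": run,
                "bin": "clean",
                "n": int(clean.sum()),
                "accuracy": float(correct[clean].mean()),
                "miss_high_q_fraction": np.nan,
            }
        )
        for lo, hi in snr_bins:
            m = ~clean & (ds.snrs >= lo) & (ds.snrs < hi if hi < 15 else ds.snrs <= hi)
            if not m.any():
                continue
            miss = m & ~correct
            rows.append(
                {
                    "run": run,
                    "bin": f"[{lo:g},{hi:g})",
                    "n": int(m.sum()),
                    "accuracy": float(correct[m].mean()),
                    "miss_high_q_fraction": (
                        float(np.mean(rep.predictions[miss] == HIGH_Q)) if miss.any() else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


_BASELINE_BANDS = (BandDefinition("alpha_ref", 8.0, 12.0), BandDefinition("beta_ref", 13.0, 35.0))


class ThresholdBaseline(BaseEstimator):
    """Percentile-interval artefact detector over amplitude statistics.

    Twelve metrics — maximum (absolute), standard deviation, kurtosis and
    skewness of the raw signal and of its 8–12 Hz and 13–35 Hz filtered
    versions — are bracketed by the [lo, hi] percentile interval observed on
    clean training segments.  A test segment is "contaminated" when any
    metric falls outside its interval; otherwise "clean".  Binary only.

    Parameters
    ----------
    sampling_rate : int
    percentiles : (float, float)
        Lower/upper percentile of the clean training interval.
    """

    def __init__(self, sampling_rate: int = 250, percentiles: tuple[float, float] = (0.5, 99.5)):
        self.sampling_rate = sampling_rate
        self.percentiles = percentiles

    def _metrics(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        versions = [X] + [bandpass_array(X, b, self.sampling_rate) for b in _BASELINE_BANDS]
        cols = []
        for V in versions:
            cols += [
                np.abs(V).max(axis=1),
                V.std(axis=1),
                stats.kurtosis(V, axis=1, fisher=False),
                stats.skew(V, axis=1),
            ]
        return np.column_stack(cols)

    def fit(self, X_clean, y=None):
        X_clean = np.asarray(X_clean, dtype=float)
        if len(X_clean) < 10:
            raise ValueError("need at least 10 clean training segments")
        M = self._metrics(X_clean)
        lo, hi = self.percentiles
        # order-statistic (non-interpolating) percentiles: every training
        # segment lies inside its own interval unless explicitly trimmed
        self.lower_ = np.percentile(M, lo, axis=0, method="lower")
        self.upper_ = np.percentile(M, hi, axis=0, method="higher")
        return self

    def predict(self, X) -> np.ndarray:
        M = self._metrics(np.asarray(X, dtype=float))
        outside = (M < self.lower_) | (M > self.upper_)
        return np.where(outside.any(axis=1), "contaminated", "clean")


def threshold_baseline(train_clean: np.ndarray, test: np.ndarray, sampling_rate: int = 250) -> np.ndarray:
    """Functional form of :class:`ThresholdBaseline`."""
    return ThresholdBaseline(sampling_rate).fit(train_clean).predict(test)
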