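"""Fast Correlation-Based Filter (FCBF) feature selection.

FCBF ranks features by their symmetrical uncertainty with the class label,

    SU(a, b) = 2 * IG(a|b) / (H(a) + H(b)),       IG(a|b) = H(a) - H(a|b),

drops those below a relevance threshold delta, and then removes redundant
features: a feature f_i is redundant when some stronger kept feature f_j has
SU(f_j, f_i) >= SU(f_i, class).  Entropies are in bits; continuous features
are discretised by equal-frequency binning first (FCBF is defined on discrete
variables).  Ties in the relevance ordering break lexicographically by
feature name so the selection never depends on column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_BINS = 10


def discretize(values: Sequence[float], n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency binning into at most *n_bins* integer codes.

    Values equal to a bin edge land in the lower bin; constant input maps to
    a single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty series")
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    inner = np.unique(qs[1:-1])  # duplicate quantiles collapse bins
    return np.searchsorted(inner, x, side="left").astype(np.int64)


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(a: Sequence, b: Sequence) -> float:
    """SU(a, b) in [0, 1] from the joint contingency table of two discrete series."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty series")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    h_a = _entropy_bits(joint.sum(axis=1))
    h_b = _entropy_bits(joint.sum(axis=0))
    if h_a + h_b == 0:
        return 0.0
    # H(a|b) = sum_b p(b) H(a|B=b)
    pb = joint.sum(axis=0) / joint.sum()
    h_a_given_b = 0.0
    for j in range(joint.shape[1]):
        col = joint[:, j]
        if col.sum() > 0:
            h_a_given_b += pb[j] * _entropy_bits(col)
    ig = h_a - h_a_given_b
    return float(2.0 * ig / (h_a + h_b))


@dataclass
class SelectedFeatureSet:
    """Outcome of an FCBF pass: kept features, relevance scores, audit trail."""

    kept_names: list[str]
    su_scores: dict[str, float]
    delta: float
    removal_reasons: dict[str, str] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        rows = []
        for name, su in sorted(self.su_scores.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "feature": name,
                    "su_class": su,
                    "kept": name in self.kept_names,
                    "reason": self.removal_reasons.get(name, ""),
                }
            )
        return pd.DataFrame(rows)


def fcbf_select(
    features: pd.DataFrame,
    labels: Sequence,
    delta: float = 0.0,
    n_bins: int = DEFAULT_BINS,
) -> SelectedFeatureSet:
    """Run FCBF on a named feature table against class labels.

    Relevant features (SU with the class >= delta) are processed in
    decreasing relevance order; later features redundant with an earlier
    kept one are removed.  With the default delta = 0 every feature passes
    the relevance gate and only the redundancy pass prunes.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection undefined for a single class")
    if len(features) != len(y):
        raise ValueError("features and labels length mismatch")

    disc = {name: discretize(features[name].to_numpy(), n_bins) for name in features.columns}
    su_class = {name: symmetrical_uncertainty(col, y) for name, col in disc.items()}

    reasons: dict[str, str] = {}
    relevant = []
    for name in features.columns:
        if su_class[name] >= delta and su_class[name] > 0:
            relevant.append(name)
        else:
            reasons[name] = f"irrelevant: SU(f, class)={su_class[name]:.4g} < delta={delta:.4g}"
    # descending relevance, lexicographic tie-break => column-order invariant
    order = sorted(relevant, key=lambda n: (-su_class[n], n))

    kept: list[str] = []
    for name in order:
        redundant_with = None
        for kept_name in kept:
            if symmetrical_uncertainty(disc[kept_name], disc[name]) >= su_class[name]:
                redundant_with = kept_name
                break
        if redundant_with is None:
            kept.append(name)
        else:
            reasons[name] = f"redundant with {redundant_with}"
    return SelectedFeatureSet(kept, su_class, delta, reasons)


class FCBFSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`fcbf_select`.

    Parameters
    ----------
    delta : float
        Relevance threshold on SU(feature, class).  0 keeps every relevant
        feature and relies on the redundancy pass.
    n_bins : int
        Equal-frequency bins used to discretise continuous features.
    feature_names : sequence of str, optional
        Names for the columns of X; defaults to ``f0..f{p-1}``.
    """

    def __init__(self, delta: float = 0.0, n_bins: int = DEFAULT_BINS, feature_names=None):
        self.delta = delta
        self.n_bins = n_bins
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        df = pd.DataFrame(X, columns=names)
        self.selection_ = fcbf_select(df, y, delta=self.delta, n_bins=self.n_bins)
        self.names_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        kept = set(self.selection_.kept_names)
        self.support_ = np.array([n in kept for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
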