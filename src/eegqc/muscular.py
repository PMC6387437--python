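"""Muscular-artefact discrimination via the Itakura spectral distance.

Medium-quality segments are re-examined against a reference spectrum built
from the clean (high-quality) training segments.  The dissimilarity measure
is the Itakura distance between two power spectra on the 0–40 Hz range,

    d_I(Pxx, Pyy) = log( mean_f Pxx/Pyy ) - mean_f log( Pxx/Pyy ),

which is non-negative (Jensen) and zero exactly when the spectra are
proportional.  We use the mean-based (normalised) form so identical spectra
give zero; the unnormalised sum form differs only by an additive constant on
a fixed grid and preserves ranking.

Muscular (EMG) bursts concentrate power at 20–45 Hz where resting EEG has
little, producing a strongly frequency-dependent spectral ratio and hence a
large distance; ocular artefacts reshape the already-strong low frequencies
far less.  A segment is flagged muscular when its distance to the averaged
clean spectrum exceeds a threshold T = mean + N·std of the clean-vs-clean
pairwise distances, with the multiplier N calibrated on the training set to
maximise balanced accuracy of muscular-vs-other discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import balanced_accuracy_score

from .features import spectrum_array
from .labels import MED_MUSC, MED_Q
from .preprocessing import Segment

#: Spectral floor before ratios/logs (μV²/Hz).
PSD_FLOOR = 1e-12
#: Frequency range of the comparison: 0 < f < 40 Hz.
F_MAX = 40.0
#: Default calibration grid for the threshold multiplier N.
DEFAULT_N_GRID = tuple(np.arange(0.0, 10.25, 0.25))


def itakura_distance(pxx: np.ndarray, pyy: np.ndarray) -> float:
    """Itakura distance between two PSDs on a shared grid (mean-based form)."""
    pxx = np.asarray(pxx, dtype=float)
    pyy = np.asarray(pyy, dtype=float)
    if pxx.shape != pyy.shape:
        raise ValueError(f"spectral grid mismatch: {pxx.shape} vs {pyy.shape}")
    ratio = np.maximum(pxx, PSD_FLOOR) / np.maximum(pyy, PSD_FLOOR)
    return float(np.log(ratio.mean()) - np.log(ratio).mean())


def _itakura_rows(P: np.ndarray, pyy: np.ndarray) -> np.ndarray:
    """Distance of each row of P to the single reference PSD pyy."""
    ratio = np.maximum(P, PSD_FLOOR) / np.maximum(pyy, PSD_FLOOR)
    return np.log(ratio.mean(axis=1)) - np.log(ratio).mean(axis=1)


def _restrict(freqs: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = (freqs > 0) & (freqs < F_MAX)
    return freqs[m], P[..., m]


@dataclass
class SpectralReference:
    """Clean-EEG reference spectrum plus the calibrated muscular threshold."""

    freqs: np.ndarray
    mean_clean_psd: np.ndarray
    pairwise_mean: float
    pairwise_std: float
    n_multiplier: Optional[float] = None
    threshold: Optional[float] = None

    @property
    def calibrated(self) -> bool:
        return self.threshold is not None

    def distance(self, psd_0_40: np.ndarray) -> float:
        """Itakura distance of a (0–40 Hz restricted) PSD to the clean mean."""
        return itakura_distance(psd_0_40, self.mean_clean_psd)


def _clean_psds(clean_segments: Sequence[Segment]) -> tuple[np.ndarray, np.ndarray]:
    fs = clean_segments[0].sampling_rate
    X = np.stack([s.samples for s in clean_segments])
    freqs, P = spectrum_array(X, fs)
    return _restrict(freqs, P)


def fit_reference(clean_segments: Sequence[Segment]) -> SpectralReference:
    """Build the clean reference: mean PSD and clean-vs-clean distance statistics.

    Pairwise distances are taken over all unordered clean pairs (i < j); the
    Itakura distance is mildly asymmetric, so the i→j direction is fixed for
    reproducibility.
    """
    if len(clean_segments) < 3:
        raise ValueError("need at least 3 clean segments to fit a spectral reference")
    freqs, P = _clean_psds(clean_segments)
    return _reference_from_psds(freqs, P)


def _reference_from_psds(freqs: np.ndarray, P: np.ndarray) -> SpectralReference:
    n = P.shape[0]
    dists = np.concatenate([_itakura_rows(P[i + 1 :], P[i]) for i in range(n - 1)])
    return SpectralReference(
        freqs=freqs,
        mean_clean_psd=P.mean(axis=0),
        pairwise_mean=float(dists.mean()),
        pairwise_std=float(dists.std(ddof=0)),
    )


def calibrate_N(
    reference: SpectralReference,
    distances: np.ndarray,
    is_muscular: np.ndarray,
    n_grid: Sequence[float] = DEFAULT_N_GRID,
) -> SpectralReference:
    """Choose the threshold multiplier N on training medium-quality segments.

    *distances* are Itakura distances of MED-level training segments to the
    clean mean spectrum; *is_muscular* marks which of them are muscular.
    For each candidate N the threshold is T = pairwise_mean + N*pairwise_std
    and the balanced accuracy of the rule ``distance > T`` is scored; the
    smallest N attaining the maximum wins.
    """
    distances = np.asarray(distances, dtype=float)
    is_muscular = np.asarray(is_muscular, dtype=bool)
    if not is_muscular.any():
        raise ValueError("no muscular segments in the training set; cannot calibrate N")
    best_n, best_score = None, -np.inf
    for n in n_grid:
        t = reference.pairwise_mean + n * reference.pairwise_std
        pred = distances > t
        score = balanced_accuracy_score(is_muscular, pred)
        if score > best_score + 1e-12:
            best_n, best_score = float(n), score
    t = reference.pairwise_mean + best_n * reference.pairwise_std
    return replace(reference, n_multiplier=best_n, threshold=float(t))


def refine_med_q(reference: SpectralReference, seg: Segment) -> str:
    """Upgrade a medium-quality segment to MED_MUSC when its spectral distance
    to the clean reference strictly exceeds the calibrated threshold."""
    if not reference.calibrated:
        raise ValueError("spectral reference is not calibrated (no threshold)")
    freqs, P = spectrum_array(seg.samples[None, :], seg.sampling_rate)
    _, P = _restrict(freqs, P)
    d = reference.distance(P[0])
    return MED_MUSC if d > reference.threshold else MED_Q


class ItakuraMuscularDetector(BaseEstimator):
    """Estimator facade over the spectral-reference workflow.

    fit(X, y) expects raw segment samples (n_segments, n_samples) and labels;
    HIGH_Q rows build the reference, MED_Q/MED_MUSC rows calibrate N.

    Parameters
    ----------
    sampling_rate : int
        Hz; row length of X.
    n_grid : sequence of float
        Candidate threshold multipliers.
    """

    def __init__(self, sampling_rate: int = 250, n_grid: Sequence[float] = DEFAULT_N_GRID):
        self.sampling_rate = sampling_rate
        self.n_grid = n_grid

    def fit(self, X, y):
        from .labels import HIGH_Q  # local import to avoid cycle noise

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        freqs, P = spectrum_array(X, self.sampling_rate)
        freqs, P = _restrict(freqs, P)
        clean = y == HIGH_Q
        if clean.sum() < 3:
            raise ValueError("need at least 3 HIGH_Q segments to fit the reference")
        ref = _reference_from_psds(freqs, P[clean])
        med = (y == MED_Q) | (y == MED_MUSC)
        dists = _itakura_rows(P[med], ref.mean_clean_psd)
        self.reference_ = calibrate_N(ref, dists, y[med] == MED_MUSC, self.n_grid)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Itakura distance of each segment to the clean mean spectrum."""
        X = np.asarray(X, dtype=float)
        freqs, P = spectrum_array(X, self.sampling_rate)
        _, P = _restrict(freqs, P)
        return _itakura_rows(P, self.reference_.mean_clean_psd)

    def predict(self, X) -> np.ndarray:
        """MED_MUSC / MED_Q per segment, by thresholded spectral distance."""
        d = self.decision_function(X)
        return np.where(d > self.reference_.threshold, MED_MUSC, MED_Q)
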