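"""Loading, segmentation, filtering and the rule-based low-quality prescreen.

A recording is cut into non-overlapping one-second windows (the pipeline's
atomic unit).  Each window has its DC offset removed and mains interference
suppressed by a notch filter; band-pass filtering into the five canonical EEG
bands feeds the feature extraction.  Two deterministic rules route obviously
unusable segments (saturation plateaus, out-of-range amplitudes) straight to
``LOW_Q`` without consulting the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .labels import LOW_Q


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band with edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges {self.f_lo}-{self.f_hi} Hz")


#: Canonical EEG bands (delta through gamma).
BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 28.0),
    BandDefinition("gamma", 28.0, 110.0),
)


@dataclass(frozen=True)
class Segment:
    """One second of single-channel EEG in μV at a known sampling rate."""

    samples: np.ndarray
    sampling_rate: int
    origin_index: int = 0
    channel_name: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or len(samples) != self.sampling_rate:
            raise ValueError(
                f"segment must hold exactly sampling_rate={self.sampling_rate} "
                f"samples (1 s window), got {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("segment contains non-finite samples")


def segment_recording(
    recording: Sequence[float], sampling_rate: int, channel_name: str = ""
) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping 1 s segments.

    The trailing remainder shorter than one second is discarded.  Raises
    ``ValueError`` when the recording is shorter than one second.
    """
    x = np.asarray(recording, dtype=float)
    if x.ndim != 1:
        raise ValueError("recording must be one-dimensional (single channel)")
    n_seg = len(x) // sampling_rate
    if n_seg < 1:
        raise ValueError(
            f"recording too short: {len(x)} samples < sampling_rate {sampling_rate}"
        )
    return [
        Segment(
            x[i * sampling_rate : (i + 1) * sampling_rate],
            sampling_rate,
            origin_index=i,
            channel_name=channel_name,
        )
        for i in range(n_seg)
    ]


def _notch_sos(notch_freq: float, sampling_rate: float, q: float = 15.0) -> np.ndarray:
    # quality factor 15: a full-scale mains sinusoid is suppressed >= 20 dB
    # within a single 1 s window (higher Q rings longer than the window and
    # cannot settle) while content 5 Hz away loses < 1 dB
    b, a = signal.iirnotch(notch_freq, q, fs=sampling_rate)
    return signal.tf2sos(b, a)


def remove_dc_and_notch(seg: Segment, notch_freq: float = 50.0) -> Segment:
    """Remove the DC offset and suppress mains interference.

    The notch is a quality-factor-30 IIR filter applied forward-backward
    (zero phase), so attenuation at the notch frequency is doubled and
    time-domain feature locations are not shifted.
    """
    nyq = seg.sampling_rate / 2
    if notch_freq >= nyq:
        raise ValueError(f"notch frequency {notch_freq} Hz >= Nyquist {nyq} Hz")
    x = seg.samples - seg.samples.mean()
    if np.any(x):
        x = signal.sosfiltfilt(_notch_sos(notch_freq, seg.sampling_rate), x)
        x = x - x.mean()
    return Segment(x, seg.sampling_rate, seg.origin_index, seg.channel_name)


def _bandpass_sos(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2
    if band.f_lo >= nyq:
        raise ValueError(f"band {band.name} lower edge {band.f_lo} Hz >= Nyquist {nyq} Hz")
    f_hi = min(band.f_hi, 0.99 * nyq)  # cap upper edge just below Nyquist
    return signal.butter(4, [band.f_lo, f_hi], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(seg: Segment, band: BandDefinition) -> Segment:
    """Zero-phase 4th-order Butterworth band-pass into an EEG band."""
    y = bandpass_array(seg.samples[None, :], band, seg.sampling_rate)[0]
    return Segment(y, seg.sampling_rate, seg.origin_index, seg.channel_name)


def bandpass_array(X: np.ndarray, band: BandDefinition, sampling_rate: float) -> np.ndarray:
    """Vectorised band-pass of a (n_segments, n_samples) array along axis 1."""
    X = np.asarray(X, dtype=float)
    sos = _bandpass_sos(band, sampling_rate)
    return signal.sosfiltfilt(sos, X, axis=-1)


def prescreen(
    samples: np.ndarray,
    constant_fraction_threshold: float = 0.70,
    amplitude_limit: float = 300.0,
    amplitude_samples: Optional[np.ndarray] = None,
) -> Optional[str]:
    """Rule-based low-quality override.

    Returns ``LOW_Q`` when either rule fires, ``None`` otherwise:

    * more than *constant_fraction_threshold* of the samples share one exact
      value (saturation plateaus, flat lines) — counted as the modal value's
      fraction of the raw samples;
    * any absolute amplitude exceeds *amplitude_limit* (default ±300 μV).

    The amplitude rule is checked on *amplitude_samples* when given (the
    pipeline passes the DC-removed segment there while keeping the constant
    check on the raw samples, since filtering destroys exact equality).
    """
    if constant_fraction_threshold <= 0 or amplitude_limit <= 0:
        raise ValueError("prescreen thresholds must be positive")
    x = np.asarray(samples, dtype=float)
    _, counts = np.unique(x, return_counts=True)
    if counts.max() / len(x) > constant_fraction_threshold:
        return LOW_Q
    amp = x if amplitude_samples is None else np.asarray(amplitude_samples, dtype=float)
    if np.any(np.abs(amp) > amplitude_limit):
        return LOW_Q
    return None
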