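"""SNR-controlled synthetic EEG with realistic artefact patterns.

Validation of a quality classifier needs ground truth, so this module
fabricates it: surrogate resting EEG (a 1/f background with an alpha peak)
is contaminated by three artefact families at a chosen signal-to-noise
ratio, yielding fully labelled one-second segments.

Artefact patterns
-----------------
* ocular (pattern 1): blinks — smooth biphasic pulses of 200–400 ms with
  spectral content below 5 Hz — and slow eye movements — half-period drifts
  of 0.5–1 s; both labelled MED_Q.  Real EOG templates would require
  recordings; these parametric templates match the spectral character of
  ocular activity (slow, high-amplitude, low-frequency).
* muscular (pattern 2): 20–45 Hz band-limited noise bursts of random
  duration 0.3–0.7 s at a random onset, labelled MED_MUSC.
* extreme values (pattern 3): 3–5 spikes of ±100–400 μV spaced 10–100 ms,
  joined by shape-preserving cubic interpolation (which never overshoots the
  spike amplitudes), labelled LOW_Q.

Mixing
------
The artefact v is superimposed on the clean carrier b as  b + λ·v  with

    λ = RMS(b) / ( RMS(v) · 10^(SNR_dB / 20) ),

so SNR 0 dB means equal RMS (λ = 1 when the RMS match) and negative SNRs
mean artefact-dominated segments.  RMS(v) is taken over the full 1 s window.
Patterns 1–2 use SNRs of 0–15 dB, pattern 3 uses −10–0 dB.  Clean carriers
and artefacts are drawn from independent seed streams, emulating signals
from different subjects.

The default dataset composition is 300 clean / 100 blink + 100 slow /
100 muscular / 300 extreme-value segments (900 total, 300 per quality
level), and a manifest of derived seeds makes every dataset bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .labels import HIGH_Q, LOW_Q, MED_MUSC, MED_Q
from .preprocessing import Segment


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


# ---------------------------------------------------------------------------
# clean EEG surrogate


def generate_clean_segment(seed, sampling_rate: int = 250) -> Segment:
    """One second of surrogate resting EEG.

    1/f background (power exponent 1) plus a band-limited alpha oscillation
    centred at 10 Hz (±1 Hz), with alpha holding 20–40% of total power and
    the whole segment scaled to an RMS of 10–30 μV.
    """
    if sampling_rate < 128:
        raise ValueError("sampling_rate must be >= 128 Hz")
    rng = _rng(seed)
    n = sampling_rate
    # spectrally shaped background: amplitude ∝ f^(-1/2) => power ∝ 1/f
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = shape * np.exp(1j * phases)
    background = np.fft.irfft(spec, n)
    background /= max(rms(background), 1e-12)

    # alpha component: narrow-band noise around 10 Hz
    alpha_raw = rng.standard_normal(n * 3)
    sos = signal.butter(4, [9.0, 11.0], btype="bandpass", fs=sampling_rate, output="sos")
    alpha = signal.sosfiltfilt(sos, alpha_raw)[n : 2 * n]
    alpha /= max(rms(alpha), 1e-12)

    alpha_rel = rng.uniform(0.2, 0.4)  # alpha share of total power
    x = np.sqrt(1 - alpha_rel) * background + np.sqrt(alpha_rel) * alpha
    x *= rng.uniform(10.0, 30.0) / max(rms(x), 1e-12)
    # resting EEG stays well under the ±100 μV artefact range; rescale the
    # rare high-crest draw (keeps RMS >= 10 μV since crest factors are < 9.5)
    peak = np.abs(x).max()
    if peak > 95.0:
        x *= 95.0 / peak
    return Segment(x, sampling_rate)


# ---------------------------------------------------------------------------
# artefact waveforms


def generate_muscular_artefact(seed, sampling_rate: int = 250) -> np.ndarray:
    """EMG-like burst: 20–45 Hz noise, duration 0.3–0.7 s, random onset."""
    if sampling_rate < 128:
        raise ValueError("sampling_rate must be >= 128 Hz")
    rng = _rng(seed)
    n = sampling_rate
    n_burst = int(
        rng.integers(int(np.ceil(0.3 * sampling_rate)), int(0.7 * sampling_rate) + 1)
    )
    onset = rng.integers(0, n - n_burst + 1)
    # steep (8th-order) band edges keep >= 90% of burst power inside 20-45 Hz
    # even after the short-burst spectral smearing of the PSD estimate
    sos = signal.butter(8, [20.0, 45.0], btype="bandpass", fs=sampling_rate, output="sos")
    noise = rng.standard_normal(n_burst + sampling_rate)
    burst = signal.sosfiltfilt(sos, noise)[sampling_rate // 2 : sampling_rate // 2 + n_burst]
    # soften burst edges; the taper stays positive inside the burst so the
    # support keeps the drawn 0.3-0.7 s length exactly
    burst = burst * signal.windows.tukey(n_burst + 2, alpha=0.2)[1:-1]
    v = np.zeros(n)
    v[onset : onset + n_burst] = burst
    return v


def generate_eog_artefact(seed, kind: str, sampling_rate: int = 250) -> np.ndarray:
    """Parametric ocular artefact template.

    kind="blink": smooth biphasic pulse, width 200–400 ms, content < 5 Hz.
    kind="slow": half-period drift lasting 0.5–1 s (slow eye movement).
    """
    if sampling_rate < 128:
        raise ValueError("sampling_rate must be >= 128 Hz")
    rng = _rng(seed)
    n = sampling_rate
    t = np.arange(n) / sampling_rate
    if kind == "blink":
        width = rng.uniform(0.2, 0.4)
        centre = rng.uniform(width / 2, 1 - width / 2)
        s = (t - centre) / (width / 4)
        # Gaussian-derivative-like biphasic pulse (dominant content < 5 Hz)
        v = -s * np.exp(-0.5 * s * s)
        if rng.random() < 0.5:
            v = -v
    elif kind == "slow":
        dur = rng.uniform(0.5, 1.0)
        onset = rng.uniform(0, 1 - dur) if dur < 1 else 0.0
        v = np.zeros(n)
        inside = (t >= onset) & (t < onset + dur)
        phase = (t[inside] - onset) / dur  # 0..1, half period
        v[inside] = np.sin(np.pi * phase)
        if rng.random() < 0.5:
            v = -v
    else:
        raise ValueError(f"unknown EOG artefact kind: {kind!r}")
    return v


def generate_extreme_values(seed, sampling_rate: int = 250, return_meta: bool = False):
    """Electrode-pop pattern: 3–5 spikes of ±100–400 μV, 10–100 ms apart,
    joined by shape-preserving cubic interpolation, zero elsewhere.

    Spike instants are snapped to the sample grid so the drawn amplitudes are
    attained exactly; PCHIP interpolation between spikes never overshoots
    them.  With ``return_meta=True`` also returns the spike sample indices
    and amplitudes.
    """
    if sampling_rate < 128:
        raise ValueError("sampling_rate must be >= 128 Hz")
    rng = _rng(seed)
    n = sampling_rate
    n_spikes = int(rng.integers(3, 6))
    # inter-spike gaps in whole samples, spanning 10–100 ms
    gap_lo = int(np.ceil(0.010 * sampling_rate))
    gap_hi = int(np.floor(0.100 * sampling_rate))
    gaps = rng.integers(gap_lo, gap_hi + 1, n_spikes - 1)
    span = int(gaps.sum())
    start = int(rng.integers(1, n - span - 1))
    idx = start + np.concatenate([[0], np.cumsum(gaps)])
    amps = rng.uniform(100.0, 400.0, n_spikes) * rng.choice([-1.0, 1.0], n_spikes)

    # zero anchors one sample outside the spike train keep the rest flat
    knots_i = np.concatenate([[idx[0] - 1], idx, [idx[-1] + 1]])
    knots_v = np.concatenate([[0.0], amps, [0.0]])
    interp = PchipInterpolator(knots_i, knots_v)
    v = np.zeros(n)
    inside = np.arange(knots_i[0], knots_i[-1] + 1)
    v[inside] = interp(inside)
    if return_meta:
        return v, {"spike_indices": idx, "amplitudes": amps}
    return v


def mix_at_snr(b: Segment, v: np.ndarray, snr_db: float) -> Segment:
    """Superimpose artefact v on clean carrier b at the requested SNR (dB)."""
    v = np.asarray(v, dtype=float)
    if len(v) != len(b.samples):
        raise ValueError("carrier and artefact lengths differ")
    rms_v = rms(v)
    if rms_v == 0:
        raise ValueError("artefact waveform has zero RMS")
    lam = rms(b.samples) / (rms_v * 10 ** (snr_db / 20.0))
    return Segment(b.samples + lam * v, b.sampling_rate, b.origin_index, b.channel_name)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class DatasetConfig:
    """Composition and SNR ranges of a synthetic labelled dataset.

    Defaults reproduce the published validation composition: 300 clean
    segments, 200 ocular (100 blink + 100 slow) at 0–15 dB, 100 muscular at
    0–15 dB, 300 extreme-value at −10–0 dB.
    """

    n_clean: int = 300
    n_blink: int = 100
    n_slow: int = 100
    n_muscular: int = 100
    n_extreme: int = 300
    snr_range_ocular: tuple[float, float] = (0.0, 15.0)
    snr_range_muscular: tuple[float, float] = (0.0, 15.0)
    snr_range_extreme: tuple[float, float] = (-10.0, 0.0)
    sampling_rate: int = 250

    def __post_init__(self):
        for name in ("n_clean", "n_blink", "n_slow", "n_muscular", "n_extreme"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("snr_range_ocular", "snr_range_muscular", "snr_range_extreme"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has lo > hi")


@dataclass
class LabelledDataset:
    """Segments + labels + per-segment SNR, with a replayable manifest."""

    X: np.ndarray  # (n_segments, n_samples) μV
    labels: np.ndarray  # 4-level quality labels
    snrs: np.ndarray  # dB; NaN for clean segments
    patterns: np.ndarray  # "clean" | "blink" | "slow" | "muscular" | "extreme"
    sampling_rate: int
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def segments(self) -> list[Segment]:
        return [
            Segment(row, self.sampling_rate, origin_index=i) for i, row in enumerate(self.X)
        ]


_PATTERN_LABEL = {
    "clean": HIGH_Q,
    "blink": MED_Q,
    "slow": MED_Q,
    "muscular": MED_MUSC,
    "extreme": LOW_Q,
}


def build_dataset(config: Optional[DatasetConfig] = None, seed: int = 0) -> LabelledDataset:
    """Generate a labelled dataset per *config*, reproducibly from *seed*.

    Clean carriers and artefact waveforms use independent child streams of
    the master seed, so a carrier never correlates with its own artefact.
    """
    config = config or DatasetConfig()
    fs = config.sampling_rate
    master = np.random.SeedSequence(seed)
    carrier_ss, artefact_ss, snr_ss = master.spawn(3)

    plan: list[tuple[str, Optional[tuple[float, float]]]] = (
        [("clean", None)] * config.n_clean
        + [("blink", config.snr_range_ocular)] * config.n_blink
        + [("slow", config.snr_range_ocular)] * config.n_slow
        + [("muscular", config.snr_range_muscular)] * config.n_muscular
        + [("extreme", config.snr_range_extreme)] * config.n_extreme
    )
    carrier_seeds = carrier_ss.spawn(len(plan))
    artefact_seeds = artefact_ss.spawn(len(plan))
    snr_rng = _rng(snr_ss)

    rows, labels, snrs, patterns = [], [], [], []
    for i, (pattern, snr_range) in enumerate(plan):
        carrier = generate_clean_segment(carrier_seeds[i], fs)
        if pattern == "clean":
            seg, snr = carrier, np.nan
        else:
            snr = float(snr_rng.uniform(*snr_range))
            if pattern == "muscular":
                v = generate_muscular_artefact(artefact_seeds[i], fs)
            elif pattern == "extreme":
                v = generate_extreme_values(artefact_seeds[i], fs)
            else:
                v = generate_eog_artefact(artefact_seeds[i], pattern, fs)
            seg = mix_at_snr(carrier, v, snr)
        rows.append(seg.samples)
        labels.append(_PATTERN_LABEL[pattern])
        snrs.append(snr)
        patterns.append(pattern)

    manifest = {
        "seed": seed,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
    }
    return LabelledDataset(
        X=np.stack(rows),
        labels=np.asarray(labels, dtype=object),
        snrs=np.asarray(snrs),
        patterns=np.asarray(patterns, dtype=object),
        sampling_rate=fs,
        manifest=manifest,
    )
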