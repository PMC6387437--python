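"""Readers and writers for recordings, feature tables and fitted models.

EDF recordings are read through :mod:`mne` (an optional dependency); plain
one-column text/CSV recordings need the sampling rate supplied by the
caller.  Fitted :class:`~eegqc.classification.QualityClassifier` models are
persisted with joblib together with a format-version tag.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1


def read_recording_csv(path, column: Optional[str] = None) -> np.ndarray:
    """Read a single-channel recording from a one-column text/CSV file (μV)."""
    df = pd.read_csv(path)
    if column is not None:
        series = df[column]
    elif df.shape[1] == 1:
        series = df.iloc[:, 0]
    else:
        raise ValueError(f"{path} has {df.shape[1]} columns; pass column=")
    return series.to_numpy(dtype=float)


def read_recording_edf(path, channel: str) -> tuple[np.ndarray, int]:
    """Read one channel from an EDF file; returns (samples in μV, rate in Hz)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0] * 1e6  # mne uses volts internally
    return data, int(round(raw.info["sfreq"]))


def write_segment_table(path, origin_indices, labels, extra: Optional[dict] = None) -> None:
    """Write the per-segment prediction/prescreen table as CSV."""
    table = {"origin_index": origin_indices, "label": labels}
    if extra:
        table.update(extra)
    pd.DataFrame(table).to_csv(path, index=False)


def write_feature_matrix(path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model, path) -> None:
    """Persist a fitted pipeline (standardisation, selection, classifier,
    spectral reference and configuration) as a single versioned archive."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]


def write_dataset(dataset, directory) -> None:
    """Write a synthetic dataset as segments.csv / labels.csv / manifest."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dataset.X).to_csv(directory / "segments.csv", index=False)
    pd.DataFrame(
        {"label": dataset.labels, "snr_db": dataset.snrs, "pattern": dataset.patterns}
    ).to_csv(directory / "labels.csv", index=False)
    (directory / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2))
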