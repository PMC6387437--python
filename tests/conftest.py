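"""Shared fixtures: small synthetic datasets and a fitted pipeline.

Everything is generated programmatically at test time; session scope keeps
the expensive end-to-end fits to one per run.
"""

import numpy as np
import pytest

import eegqc as q

FS = 250


@pytest.fixture(scope="session")
def small_dataset():
    """Compact labelled dataset with strong (low-SNR) artefacts."""
    cfg = q.DatasetConfig(
        n_clean=60,
        n_blink=20,
        n_slow=20,
        n_muscular=25,
        n_extreme=40,
        snr_range_ocular=(0.0, 5.0),
        snr_range_muscular=(0.0, 5.0),
    )
    return q.build_dataset(cfg, seed=42)


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    """Weighted-kNN pipeline trained on the small dataset."""
    model = q.QualityClassifier(classifier="weighted_knn", k=7, sampling_rate=FS)
    return model.fit(small_dataset.X, small_dataset.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def clean_segment():
    return q.generate_clean_segment(seed=5, sampling_rate=FS)
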