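"""Feature extraction: amplitude statistics, spectra, entropies, scaling."""

import numpy as np
import pandas as pd
import pytest

from eegqc.features import (
    SegmentFeaturizer,
    StandardizationParams,
    entropy_features,
    feature_matrix,
    frequency_features,
    spectrum,
    standardize,
    time_features,
)
from eegqc.preprocessing import Segment, remove_dc_and_notch

FS = 250


def _seg(x):
    return Segment(np.asarray(x, dtype=float), FS)


def _sine(freq, amplitude=50.0):
    t = np.arange(FS) / FS
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestTimeFeatures:
    def test_constant_segment_degenerates_to_zero(self):
        seg = remove_dc_and_notch(_seg(np.full(FS, 7.0)))
        feats = time_features(seg)
        assert feats["std_raw"] == 0.0
        assert feats["max_abs_raw"] == 0.0

    def test_gaussian_moments(self):
        # aggregate over many draws: Pearson kurtosis -> 3, skewness -> 0
        rng = np.random.default_rng(0)
        kurts, skews = [], []
        for _ in range(100):
            feats = time_features(_seg(rng.standard_normal(FS)))
            kurts.append(feats["kurtosis_raw"])
            skews.append(feats["skewness_raw"])
        assert abs(np.mean(kurts) - 3.0) < 0.5
        assert abs(np.mean(skews)) < 0.2

    def test_symmetric_wave_has_zero_skewness(self):
        tri = np.abs(np.linspace(-1, 1, FS)) * 2 - 1  # symmetric triangular wave
        assert abs(time_features(_seg(tri))["skewness_raw"]) < 1e-6


class TestSpectrum:
    def test_sine_peak_location(self):
        f, p = spectrum(_seg(_sine(10.0)))
        assert abs(f[np.argmax(p)] - 10.0) <= f[1] - f[0]

    def test_psd_nonnegative_and_1hz_grid(self, clean_segment):
        f, p = spectrum(clean_segment)
        assert np.all(p >= 0)
        assert f[1] - f[0] <= 1.0

    def test_parseval_consistency(self):
        f, p = spectrum(_seg(_sine(10.0)))
        df = f[1] - f[0]
        assert abs(p.sum() * df / _sine(10.0).var() - 1.0) < 0.05
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(50):
            x = rng.standard_normal(FS)
            x -= x.mean()
            f, p = spectrum(_seg(x))
            ratios.append(p.sum() * df / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_white_noise_flat_band_power(self):
        rng = np.random.default_rng(11)
        per_hz = []
        for _ in range(50):
            x = rng.standard_normal(FS)
            x -= x.mean()
            f, p = spectrum(_seg(x))
            bands = [(4, 8), (8, 13), (13, 28), (28, 110)]
            per_hz.append(
                [p[(f >= lo) & (f < hi)].mean() for lo, hi in bands]
            )
        mean_per_hz = np.mean(per_hz, axis=0)
        assert np.all(np.abs(mean_per_hz / mean_per_hz.mean() - 1.0) < 0.3)

    def test_zero_segment_zero_psd(self):
        _, p = spectrum(_seg(np.zeros(FS)))
        np.testing.assert_allclose(p, 0.0, atol=1e-20)


class TestFrequencyFeatures:
    def test_relative_powers_sum_to_one(self, clean_segment):
        f, p = spectrum(clean_segment)
        feats = frequency_features(p, f)
        rel = sum(feats[f"rel_power_{b}"] for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert abs(rel - 1.0) < 1e-9

    def test_sine_concentrates_in_alpha(self):
        f, p = spectrum(_seg(_sine(10.0)))
        assert frequency_features(p, f)["rel_power_alpha"] >= 0.95

    def test_white_noise_flatness(self):
        rng = np.random.default_rng(7)
        flats = []
        for _ in range(50):
            x = rng.standard_normal(FS)
            f, p = spectrum(_seg(x - x.mean()))
            flats.append(frequency_features(p, f)["spectral_flatness"])
        assert np.mean(flats) >= 0.8

    def test_zero_psd_defined_fallbacks(self):
        f = np.arange(126.0)
        feats = frequency_features(np.zeros(126), f)
        assert feats["rel_power_alpha"] == 0.0
        assert np.isfinite(feats["log_power_alpha"])

    def test_negative_psd_rejected(self):
        f = np.arange(126.0)
        with pytest.raises(ValueError):
            frequency_features(np.full(126, -1.0), f)


class TestEntropyFeatures:
    def test_flat_psd_maximal_spectral_entropy(self, clean_segment):
        feats = entropy_features(clean_segment, psd=np.ones(126))
        assert abs(feats["spectral_entropy"] - 1.0) < 1e-9

    def test_sine_spectral_entropy_low(self):
        seg = _seg(_sine(10.0))
        f, p = spectrum(seg)
        assert entropy_features(seg, psd=p)["spectral_entropy"] <= 0.3

    def test_constant_segment_all_zero(self):
        feats = entropy_features(_seg(np.full(FS, 3.0)), psd=np.zeros(126))
        assert feats["shannon_entropy"] == 0.0
        assert feats["svd_entropy"] == 0.0
        assert feats["spectral_entropy"] == 0.0


class TestInvariants:
    def test_determinism(self, clean_segment):
        a = feature_matrix(clean_segment.samples[None, :], FS)
        b = feature_matrix(clean_segment.samples[None, :].copy(), FS)
        pd.testing.assert_frame_equal(a, b)

    def test_scale_covariance(self, clean_segment):
        x = clean_segment.samples
        a = feature_matrix(x[None, :], FS).iloc[0]
        b = feature_matrix(2 * x[None, :], FS).iloc[0]
        assert np.isclose(b["std_raw"], 2 * a["std_raw"], rtol=1e-9)
        assert np.isclose(b["max_abs_raw"], 2 * a["max_abs_raw"], rtol=1e-9)
        for name in (
            "skewness_raw",
            "kurtosis_raw",
            "spectral_entropy",
            "rel_power_alpha",
            "spectral_flatness",
        ):
            assert np.isclose(b[name], a[name], atol=1e-6), name

    @pytest.mark.parametrize(
        "make",
        [
            lambda: np.zeros(FS),
            lambda: np.full(FS, 5.0),
            lambda: np.eye(1, FS, 100).ravel() * 300,  # single spike
            lambda: np.where(np.arange(FS) < 200, 300.0, -300.0),  # saturated
        ],
        ids=["zero", "constant", "spike", "saturated"],
    )
    def test_no_nan_on_degenerate_inputs(self, make):
        out = feature_matrix(make()[None, :], FS)
        assert np.all(np.isfinite(out.to_numpy()))


class TestStandardization:
    def _features(self, rng, n=20):
        return pd.DataFrame(
            {"a": rng.standard_normal(n) * 5 + 3, "b": rng.standard_normal(n), "c": 2.0}
        )

    def test_training_set_standardizes_to_unit_stats(self, rng):
        feats = self._features(rng)
        params = StandardizationParams.fit(feats)
        z = standardize(feats, params)
        assert np.all(np.abs(z.mean()) < 1e-9)
        for col in ("a", "b"):
            assert abs(z[col].std(ddof=0) - 1.0) < 1e-9

    def test_zero_variance_feature_maps_to_zero(self, rng):
        feats = self._features(rng)
        z = standardize(feats, StandardizationParams.fit(feats))
        assert np.all(z["c"] == 0.0)

    def test_training_mean_maps_to_zero(self, rng):
        feats = self._features(rng)
        params = StandardizationParams.fit(feats)
        probe = pd.DataFrame({k: [params.means[k]] for k in feats.columns})
        assert np.all(np.abs(standardize(probe, params).iloc[0]) < 1e-12)

    def test_missing_feature_rejected(self, rng):
        feats = self._features(rng)
        params = StandardizationParams.fit(feats)
        with pytest.raises(ValueError, match="missing"):
            standardize(feats[["a", "b"]], params)

    def test_featurizer_is_sklearn_transformer(self, small_dataset):
        tr = SegmentFeaturizer(FS).fit(small_dataset.X[:10])
        out = tr.transform(small_dataset.X[:10])
        assert out.shape == (10, len(tr.feature_names_))
        assert list(tr.get_feature_names_out()) == tr.feature_names_
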