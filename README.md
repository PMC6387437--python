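# eegqc — single-channel EEG quality assessment

`eegqc` grades one-second windows of single-channel EEG on a three-level
quality scale and tells muscular contamination apart from other artefacts.
It is aimed at consumer/wearable EEG settings (dry electrodes, one or two
channels, no reference montage) where recordings must be screened
automatically before any downstream analysis, and at anyone who needs a
reproducible, fully synthetic benchmark for artefact detectors.

## Method

Each 1 s segment runs through a fixed pipeline:

1. **Prescreen** — deterministic rules route unusable segments straight to
   `LOW_Q`: more than 70 % of samples sharing one exact value (saturation,
   flat lines), or any amplitude beyond ±300 μV.
2. **Preprocessing** — DC removal and a zero-phase mains notch (50/60 Hz),
   then band-pass decompositions into δ (0.5–4), θ (4–8), α (8–13),
   β (13–28) and γ (28–110 Hz).
3. **Features** — ~60 named measures per segment: max |x|, σ, kurtosis and
   skewness on the raw and band-filtered signal; band powers (absolute, log,
   relative), peak frequency, spectral centroid, 95 % spectral edge,
   flatness, γ/(δ+θ+α+β) ratio and cepstral coefficients from a multitaper
   PSD; Shannon, spectral and SVD entropies; Hjorth parameters and related
   waveform morphology.
4. **Selection** — fast correlation-based filtering (FCBF): keep features
   with symmetrical uncertainty `SU(f, class) = 2·IG(f|class)/(H(f)+H(class))`
   above δ, then drop any feature `f_i` for which a stronger kept `f_j` has
   `SU(f_j, f_i) ≥ SU(f_i, class)`.
5. **Classification** — weighted kNN by default (votes `1/d²` over the k
   nearest standardized feature vectors), with Euclidean kNN, LDA and a
   linear one-vs-one SVM as alternatives; all ties break toward the worse
   quality.
6. **Muscular refinement** — a segment classified `MED_Q` is upgraded to
   `MED_MUSC` when the Itakura distance between its spectrum and the mean
   clean-EEG spectrum,

   `d_I(Pxx, Pyy) = log( mean_f Pxx/Pyy ) − mean_f log( Pxx/Pyy )`  over 0 < f < 40 Hz,

   exceeds `T = μ + N·σ` of the clean-vs-clean pairwise distances, with N
   calibrated on the training set.

Because labelled recordings are rarely shareable, the package also ships a
synthetic benchmark: surrogate resting EEG (1/f background + alpha peak)
contaminated by parametric blinks, slow eye movements, 20–45 Hz EMG bursts
and extreme-value spike trains, superimposed as `b + λ·v` with
`λ = RMS(b) / (RMS(v)·10^(SNR/20))` so the contamination level is exact.

## Worked example

```python
import eegqc as q

ds = q.build_dataset(seed=0)                  # 900 labelled synthetic segments
est = q.QualityClassifier(classifier="weighted_knn", k=10)
rep = q.cross_validate(ds, est, n_folds=5, seed=0)
print(rep.confusion_matrix)
print(f"total accuracy: {rep.total_accuracy:.3f}")
print(f"muscular refinement accuracy: {rep.med_musc_accuracy:.3f}")
```

prints

```
        LOW_Q  MED_Q  HIGH_Q
LOW_Q     291      9       0
MED_Q       6    151     143
HIGH_Q      0     70     230
total accuracy: 0.747
muscular refinement accuracy: 0.834
```

Rows are true classes, columns predictions. Strongly contaminated segments
(LOW_Q, mixed at −10…0 dB) are almost always caught; medium-quality errors
concentrate at high SNR (faint artefacts mixed at up to 15 dB) and are
almost always mistaken for clean EEG — the benign failure direction for a
quality gate. On the harder-contamination regime (artefacts at ≤ 5 dB) the
same pipeline reaches ≈ 0.88 total accuracy; see `docs/methods.md` for what
limits the slow-eye-movement class.

The same steps are available from a shell:

```bash
eegqc simulate --out data --seed 3
eegqc train --input recording.csv --labels data/labels.csv \
            --model model.joblib --sampling-rate 250 --classifier weighted_knn --k 7
eegqc predict --model model.joblib --input recording.csv \
              --sampling-rate 250 --out pred.csv
eegqc evaluate --seed 0 --k 10
```

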