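# thermoseg

Per-pixel tumor segmentation from intraoperative cold-stress thermal
infrared video.

During neurosurgery, the exposed cortex can be filmed with a thermal camera
while a cold saline wash perturbs its temperature.  Healthy parenchyma and
tumor tissue re-warm with different dynamics and carry differently
synchronized cardiac-band perfusion oscillations, so the tumor boundary can
be recovered pixel by pixel from the thermal video alone.  `thermoseg` is a
research tool for this analysis, aimed at groups working on intraoperative
thermography: it covers the full pipeline from raw video to segmentation
metrics, and ships a synthetic video generator so every stage is testable
without patient data (clinical recordings of this kind are not publicly
deposited).

## The method

A recording consists of a baseline phase (BL, 60 s), a cold-saline
injection, and a recovery phase (REC, 120 s) sampled at 5 Hz.  The
surgeon-drawn tumor boundary is transferred from the visible-light image to
the thermal grid by a least-squares affine transform fitted to paired
control points.  Each pixel trace T(t) then yields:

- **Time-domain features** — the recovery fit
  `T(t) = a·(1 − e^{b·t}) + c` (kept when the goodness of fit R > 0.8),
  the session temperature variation Δ, the pre-injection temperature
  T_INI, and per-phase SD, kurtosis, skewness, 90th percentile and sample
  entropy SampEn(m = 2, r = 0.2·SD).
- **Frequency-domain features** — the wavelet coherence (analytic Morlet,
  ω₀ = 6) between the pixel trace and the mean trace of a randomized
  subset of tumor pixels, averaged over time in 60 frequency bands
  spanning [0.015, 2] Hz, separately for BL and REC.

Per patient, features are screened with Welch t-tests (Bonferroni
corrected) and fed to four RBF-SVM model families (TD/FD × BL/BL+REC)
under a 20/20/60 train/test/validation split with class-balanced train and
test sets and 10-fold cross-validation; accuracy, sensitivity and
specificity are reported on the untouched validation pixels.

## Worked example

```python
import thermoseg as ts

cfg = ts.ScenarioConfig()                  # 64x64 px, 5 Hz, default classes
video, mask = ts.generate_video(cfg)       # 950 frames + ground-truth mask
report = ts.run_patient(video, mask, seed=0)
for family, res in report.results.items():
    print(f"{family:10s} acc={res.accuracy:6.2f} "
          f"sens={res.sensitivity:6.2f} spec={res.specificity:6.2f}")
```

prints

```
td_bl      acc= 67.78 sens= 52.92 spec= 69.51
td_bl+rec  acc= 98.74 sens=100.00 spec= 98.59
fd_bl      acc= 96.14 sens= 95.72 spec= 96.18
fd_bl+rec  acc= 99.10 sens= 97.28 spec= 99.32
```

Baseline-only time-domain features barely separate the classes (the
baseline temperature distributions overlap), while the coherence features
of the full session segment the lesion almost perfectly: the percentages
are the validation-set accuracy, the true-positive rate over tumor pixels,
and the true-negative rate over healthy pixels.  `report.td_tests` holds
the per-feature t-statistics, and
`ts.max_discriminative_band([report.fd_t_rec], ts.make_band_layout())`
returns the coherence band that best separates the classes — on the default
scenario it falls in the cardiac band around 0.7 Hz.

The same steps are available from the shell:

```bash
thermoseg simulate --out demo/
thermoseg features-fd --video demo/ --mask demo/mask.png --out demo/fd.parquet
thermoseg classify --features demo/fd.parquet --family fd_bl+rec --seed 7 --out demo/run/
thermoseg cohort --n-patients 5 --out demo/cohort/
```

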