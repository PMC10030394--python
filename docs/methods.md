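# Methods

`thermoseg` implements a per-pixel segmentation pipeline for intraoperative
cold-stress thermal infrared video of exposed cortex, together with a
synthetic video generator that reproduces the statistical structure the
pipeline exploits.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Recording model and protocol

A recording is a 3-D temperature array (frames × rows × cols, °C) sampled
uniformly (5 Hz by default) and annotated with three protocol phases: a
baseline (BL, 60 s), a cold-saline injection instant, and a recovery phase
(REC, 120 s).  The injection is modelled as an instantaneous step drop
followed by a 10 s transient gap between BL and REC that no feature window
touches; the gap duration is a package choice, as is representing the
injection transient by a linear ramp from the baseline level to the
post-stress level.

## Synthetic video generator

Each pixel belongs to one of two classes (healthy cortex / tumor) defined by
the surgeon-drawn polygon.  The per-pixel trace is

    baseline level                         (BL)
    linear drop to c = baseline − drop     (gap)
    c + a · (1 − e^{b·t})                  (REC, t from recovery onset)
    + cardiac oscillation + vasomotor fluctuation + sensor noise

with per-pixel baseline levels drawn i.i.d. Gaussian around the class mean
(no spatial smoothing by default, keeping pixels exchangeable under the
random split protocol; a smoothing option exists but is off), and per-pixel
log-normal jitter (10 % relative SD) on the recovery amplitude `a` and rate
`b` to model within-class heterogeneity of perfusion.

Default class parameters (°C, 1/s): healthy baseline 33.5 ± 1.0, tumor
32.5 ± 1.0 — tumors of glial origin run 0.5–2 °C cooler than surrounding
parenchyma, and the ± 1.0 spatial spread keeps the two distributions
overlapping, as clinical per-patient baseline tables do.  Cold-stress drop
4.0 for both classes (≈ 10 °C saline on ≈ 33 °C cortex brings pixels a few
degrees below baseline).  Recovery: healthy a = 4.0, b = −0.12 (τ ≈ 8 s,
full re-warming), tumor a = 3.5, b = −0.02 (τ ≈ 50 s, incomplete
re-warming) — tumor tissue reacts sluggishly to the perturbation.  These
choices produce the two signatures the time-domain analysis keys on: the
post-stress level `c` is lower in tumor, and the recovery-phase standard
deviation is higher in tumor (a slow ramp spread across the whole window
disperses more than a fast saturating one).

The cardiac component is a narrowband process: a sinusoid at f_c = 0.71 Hz
(the centre of the band the frequency-domain analysis singles out) whose
phase performs a random walk (SD 0.3 rad/√sample), giving the source a
finite coherence time and a realistic linewidth (~0.07 Hz).  Every pixel
mixes one scene-shared source with a pixel-private one:
`w·shared + (1−w)·private`, amplitude 0.08 °C in both classes.  The class
contrast is carried entirely by the coupling weight (tumor w = 0.9, healthy
w = 0.1, per-pixel SD 0.15, clipped to [0, 1]): tumor pixels oscillate
coherently with the tumor reference, healthy pixels mostly privately.

Two noise floors complete the model: white sensor noise (SD 0.1 °C,
consistent with a cooled bolometer's <30 mK NETD plus residual scene
variation) and a per-pixel Ornstein–Uhlenbeck vasomotor fluctuation
(stationary SD 0.3 °C, correlation time 20 s) identical in both classes.
The OU term matters: living cortex fluctuates strongly below ~0.1 Hz
(endothelial/neurogenic/myogenic activity), and without it the slow
frequency bands of the coherence spectrum become artificially
class-separating, which real tissue is not.

What the generator does **not** emulate: spatial correlation of the
physiology, brain shift and motion, vascular trees crossing the boundary,
radiometric effects (emissivity, atmosphere), and the partial-volume mix at
the lesion margin.  Passing tests therefore demonstrate that the pipeline
recovers the designed statistical structure, not that it would reach the
same operating point on clinical recordings.

## Co-registration

The visible→thermal transform is a 2-D affine fit to ≥3 operator-chosen
control-point pairs by least squares (RANSAC would be wrong here: the
points are curated, not putative matches).  Coordinates are 0-based
(row, col) with pixel centres at integers; file formats carry 1-based
(x, y) (imaging-tool convention) converted only at the I/O boundary.
Rasterization uses the even-odd rule on pixel centres, with
boundary-touching centres counted inside — a deterministic rule that a
brute-force point-in-polygon oracle pins down in the tests.

## Time-domain features

Per pixel: exponential recovery fit `y = a(1−e^{bt}) + c` by bounded
(b < 0) Levenberg–Marquardt with analytic Jacobian, initialized at
c₀ = first REC sample, a₀ = last−first, b₀ = −3/T with a three-point
multi-start on b₀.  Goodness of fit is the correlation form
R = √max(R², 0); the fit is kept only when R > 0.8 (strict), otherwise the
coefficients are recorded as missing (never zero-filled; imputation is the
classifier's explicit job).  A flat trace makes `b` unidentifiable and is
rejected.

Δ is mean(last 10 s) − mean(first 10 s) of the whole session (positive =
net warming).  T_INI is the mean over the 30 s before the injection.
Per-phase moments use the sample SD (ddof 1), Pearson (non-excess)
kurtosis and skewness — the conventions of the common numerical toolboxes —
and the linearly interpolated 90th percentile.  Sample entropy uses m = 2,
r = 0.2·SD, Chebyshev distance with closed tolerance (≤ r), self-matches
excluded, identical pair normalization in numerator and denominator (so it
cancels); a constant trace returns 0, and an unmatched m+1 template set
returns +inf.  The counting kernel is compiled with numba, with a pure
numpy fallback; the test suite checks it exactly against an exhaustive
O(N²) oracle.

## Frequency-domain features

Wavelet coherence against the mean trace of a random 20 % subset of tumor
pixels ("a randomized portion"; the fraction is a package default).
Transform: analytic Morlet, centre frequency parameter ω₀ = 6, evaluated at
the 60 band-centre scales; bands are logarithmically spaced over
[0.015, 2] Hz (wavelet resolution is multiplicative; linear spacing is a
config option).  Traces are demeaned before the transform — the absolute
temperature level is time-domain information, and a nonzero mean turns the
zero-padded trace ends into large spurious low-frequency structure.

Coherence is |S(W_x W_y*)|² / (S|W_x|² · S|W_y|²) with S a boxcar over time
of length 6× the scale plus a 3-point boxcar across scales.  The time
window spans several coefficient decorrelation lengths, putting the
independent-noise floor near 0.3; with no smoothing the ratio is
identically 1.  Magnitude-squared coherence is the default ("amplitude"
is available via `squared=False`).  Values are clipped to [0, 1]; zero
denominators (constant traces) yield NaN flags.

BL and REC band averages come from a single transform of the full trace,
windowed afterwards, to avoid doubling edge effects.  Samples within the
cone of influence (√2·scale from either end) are excluded from the
averages; bands whose window is entirely edge-contaminated fall back to
the plain window mean and are flagged unreliable rather than dropped.
Reference-subset pixels stay in the feature table, flagged `in_reference`,
so the consumer can decide about the circularity.

## Statistics

Per patient and per feature, a two-sample t-test of class 0 vs class 1 —
Welch's by default (no variance-homogeneity assumption across tissue
types; the pooled form is a flag).  Bonferroni correction uses the number
of features in the table as the family, mirroring per-figure correction;
no cross-patient correction.  The maximally discriminative band is the
argmax of the cross-patient mean t (class1−class0) over the 60 recovery
bands, ties broken toward the lower band.

## Classification

Per patient, four RBF-SVM families: TD_BL, TD_BL+REC, FD_BL, FD_BL+REC.
Pixels split 20/20/60 into train/test/validation; the larger class is
randomly down-sampled within train and within test.  The pipeline is
impute(train median) → z-score(train statistics) → SVC(C = 1,
gamma = "scale"); standardization is required by the RBF kernel over
features with heterogeneous units, and both preprocessing steps are cloned
into every CV fold, so no fold sees another fold's statistics.  10-fold CV
runs over the balanced train+test pool — the only reading of a "split plus
10-fold CV" protocol that leaves the 60 % validation set untouched — and
the headline accuracy/sensitivity/specificity are the validation-set
(unbalanced) values; CV accuracy is reported alongside.

## Problem sizes and numerical choices

The bundled cohort runs 5 simulated patients at 64 × 64 px (desk-scale;
full 640 × 480 generation is supported), 950 frames each.  Determinism:
every random element (generator, reference subset, split, balancing, CV
shuffling) derives from explicit integer seeds, and two identical cohort
runs produce byte-identical reports.  Known limitations: per-pixel
independence of the synthetic physiology makes the random-split protocol
more favourable than spatially correlated clinical data would be;
coherence at the lowest bands is edge-dominated on a 3-minute recording
and carried only as flagged values; the SVM hyperparameters are not tuned
(a small in-train grid search is available but off by default).
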