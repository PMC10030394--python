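"""Wavelet-coherence features against a randomized tumor reference signal.

For every pixel, the wavelet coherence between its trace and the mean trace
of a random subset of tumor pixels is computed with an analytic Morlet
continuous wavelet transform (center frequency parameter 6) and summarized
as the time-average per frequency band over the baseline and recovery
windows — 60 bands spanning [0.015, 2] Hz.

Coherence is the standard smoothed-spectra form

    C = |S(Wx * conj(Wy))|^2 / (S(|Wx|^2) * S(|Wy|^2))

with S a boxcar over time of length 6x the scale plus a 3-point
boxcar across scales; without smoothing the ratio is identically 1.  Samples
inside the cone of influence (edge-contaminated region, ~1.37/f seconds from
either end) are excluded from the time averages; bands whose window lies
entirely inside the cone are still reported but flagged unreliable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from ..bands import BandLayout, make_band_layout
from ..video import ThermalVideo

__all__ = [
    "MORLET_WAVELET", "make_reference", "wavelet_coherence", "band_average",
    "WaveletCoherenceFeaturizer", "extract_fd_table",
]

# complex Morlet exp(2i*pi*C*t) * exp(-t^2 / B) with C = 6/(2*pi): the
# analytic Morlet with omega0 = 6 that is standard in coherence work
MORLET_WAVELET = "cmor2.0-0.9549296585513721"

def _coi_seconds(freq: float) -> float:
    """Cone-of-influence half-width at ``freq``, seconds.

    The edge-contaminated region extends sqrt(2) * scale from either trace
    end (the e-folding time of the Morlet envelope); the physical scale at
    Fourier frequency f is 1 / (f * fourier_factor) with
    fourier_factor = 4*pi / (omega0 + sqrt(2 + omega0^2)) ~ 1.033 for
    omega0 = 6.
    """
    omega0 = 6.0
    fourier_factor = 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))
    scale = 1.0 / (freq * fourier_factor)
    return float(np.sqrt(2.0) * scale)


def _scales_for(centers: np.ndarray, fs: float) -> np.ndarray:
    fc = pywt.central_frequency(MORLET_WAVELET)
    return fc * fs / np.asarray(centers, dtype=float)


def cwt_morlet(X: np.ndarray, fs: float, centers: np.ndarray) -> np.ndarray:
    """Analytic-Morlet CWT sampled at the band center frequencies.

    ``X`` may be (n,) or (n_traces, n); output prepends a scale axis of
    length ``len(centers)``.
    """
    scales = _scales_for(centers, fs)
    coefs, _ = pywt.cwt(np.asarray(X, dtype=np.float64), scales,
                        MORLET_WAVELET, sampling_period=1.0 / fs,
                        method="fft", axis=-1)
    return coefs


def _smooth_real(P: np.ndarray, scales: np.ndarray, factor: float) -> np.ndarray:
    out = np.empty_like(P)
    for i, a in enumerate(scales):
        size = max(3, int(round(factor * a)) | 1)
        out[i] = uniform_filter1d(P[i], size=size, axis=-1, mode="reflect")
    return uniform_filter1d(out, size=3, axis=0, mode="nearest")


def _smooth(P: np.ndarray, scales: np.ndarray, factor: float) -> np.ndarray:
    if np.iscomplexobj(P):
        return (_smooth_real(P.real, scales, factor)
                + 1j * _smooth_real(P.imag, scales, factor))
    return _smooth_real(P, scales, factor)


def _coherence_from_transforms(Wx: np.ndarray, Wy: np.ndarray,
                               scales: np.ndarray, factor: float,
                               squared: bool = True) -> np.ndarray:
    """Coherence map(s) from precomputed transforms; NaN where power is zero."""
    sxy = _smooth(Wx * np.conj(Wy), scales, factor)
    sxx = _smooth((Wx * np.conj(Wx)).real, scales, factor)
    syy = _smooth((Wy * np.conj(Wy)).real, scales, factor)
    den = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = (sxy.real ** 2 + sxy.imag ** 2) / den
    coh = np.where(den > 1e-300, coh, np.nan)
    coh = np.clip(coh, 0.0, 1.0)
    if not squared:
        coh = np.sqrt(coh)
    return coh


def wavelet_coherence(x, y, fs: float, bands: BandLayout | None = None,
                      smooth_time_factor: float = 6.0,
                      squared: bool = True) -> tuple[np.ndarray, BandLayout]:
    """Time-frequency coherence magnitude between two equal-length traces.

    Returns a (n_bands, n_samples) map in [0, 1] (NaN where a trace has zero
    power, e.g. for constant input) and the band layout used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D traces")
    if bands is None:
        bands = make_band_layout()
    if bands.f_high[-1] > fs / 2.0:
        raise ValueError(f"band range exceeds the Nyquist frequency {fs / 2.0} Hz")
    scales = _scales_for(bands.centers, fs)
    # demean before transforming: the absolute temperature level is
    # time-domain information, and a nonzero mean turns the trace ends into
    # large spurious steps for the (zero-padded) transform
    Wx = cwt_morlet(x - x.mean(), fs, bands.centers)
    Wy = cwt_morlet(y - y.mean(), fs, bands.centers)
    return _coherence_from_transforms(Wx, Wy, scales, smooth_time_factor,
                                      squared), bands


def band_average(coh_map: np.ndarray, timestamps, window: tuple[float, float],
                 bands: BandLayout) -> tuple[np.ndarray, np.ndarray]:
    """Per-band time average of a coherence map inside a phase window.

    Samples inside the cone of influence at each band's center frequency are
    excluded; a band whose window is fully edge-contaminated falls back to
    the plain window mean and is flagged unreliable.

    Returns ``(means, reliable)``: two length-n_bands arrays.
    """
    t = np.asarray(timestamps, dtype=np.float64)
    coh_map = np.asarray(coh_map, dtype=np.float64)
    if coh_map.shape[-1] != t.size or coh_map.shape[-2] != bands.n_bands:
        raise ValueError("coherence map must end in (n_bands, n_samples)")
    t0, t1 = window
    in_win = (t >= t0) & (t < t1)
    if not in_win.any():
        raise ValueError("phase window contains no samples")
    means = np.empty(coh_map.shape[:-2] + (bands.n_bands,))
    reliable = np.ones(bands.n_bands, dtype=bool)
    with np.errstate(invalid="ignore"):
        for i, f in enumerate(bands.centers):
            coi = _coi_seconds(f)
            sel = in_win & (t - t[0] >= coi) & (t[-1] - t >= coi)
            if not sel.any():
                sel = in_win
                reliable[i] = False
            means[..., i] = np.nanmean(coh_map[..., i, sel], axis=-1)
    return means, reliable


def make_reference(video: ThermalVideo, tumor_mask: np.ndarray,
                   fraction: float = 0.2,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean trace over a random without-replacement subset of tumor pixels.

    Returns ``(trace, flat_indices)`` with ``ceil(fraction * n_tumor)``
    pixels chosen under ``seed``.
    """
    mask = np.asarray(tumor_mask, dtype=bool)
    if mask.shape != video.frame_shape:
        raise ValueError("mask shape does not match the video frames")
    flat = np.flatnonzero(mask.ravel())
    if flat.size == 0:
        raise ValueError("tumor mask is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * flat.size))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(flat, size=k, replace=False))
    traces = video.traces()
    return traces[chosen].mean(axis=0), chosen


class WaveletCoherenceFeaturizer(TransformerMixin, BaseEstimator):
    """Transform pixel traces into band-averaged wavelet-coherence features.

    ``fit(X, y)`` picks the randomized tumor reference subset from the rows
    with ``y == 1`` and stores its mean trace; ``transform(X)`` computes, for
    every row, the coherence with that reference and averages it per band
    over the baseline (and, for scope "bl+rec", recovery) window.  BL and REC
    averages come from a single transform of the full trace, windowed
    afterwards, to avoid doubling edge effects.
    """

    def __init__(self, timestamps=None, phases=None, scope: str = "bl+rec",
                 fraction: float = 0.2, seed: int = 0, n_bands: int = 60,
                 f_min: float = 0.015, f_max: float = 2.0,
                 spacing: str = "log", smooth_time_factor: float = 6.0,
                 squared: bool = True, chunk_size: int = 96):
        self.timestamps = timestamps
        self.phases = phases
        self.scope = scope
        self.fraction = fraction
        self.seed = seed
        self.n_bands = n_bands
        self.f_min = f_min
        self.f_max = f_max
        self.spacing = spacing
        self.smooth_time_factor = smooth_time_factor
        self.squared = squared
        self.chunk_size = chunk_size

    def fit(self, X, y):
        if self.timestamps is None or self.phases is None:
            raise ValueError("timestamps and phases are required")
        if self.scope not in ("bl", "bl+rec"):
            raise ValueError("scope must be 'bl' or 'bl+rec'")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        tumor_rows = np.flatnonzero(y == 1)
        if tumor_rows.size == 0:
            raise ValueError("no tumor rows (y == 1) to build the reference from")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        k = int(np.ceil(self.fraction * tumor_rows.size))
        rng = np.random.default_rng(self.seed)
        self.reference_rows_ = np.sort(rng.choice(tumor_rows, size=k,
                                                  replace=False))
        self.reference_trace_ = X[self.reference_rows_].mean(axis=0)
        self.bands_ = make_band_layout(self.n_bands, self.f_min, self.f_max,
                                       self.spacing)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=np.float64)
        t = np.asarray(self.timestamps, dtype=np.float64)
        fs = 1.0 / float(np.mean(np.diff(t)))
        bands = self.bands_
        if bands.f_high[-1] > fs / 2.0:
            raise ValueError(f"band range exceeds the Nyquist frequency {fs / 2.0} Hz")
        scales = _scales_for(bands.centers, fs)
        windows = [("bl", self.phases.bl)]
        if self.scope == "bl+rec":
            windows.append(("rec", self.phases.rec))

        ref = self.reference_trace_
        Wy = cwt_morlet(ref - ref.mean(), fs, bands.centers)
        syy = _smooth((Wy * np.conj(Wy)).real, scales, self.smooth_time_factor)

        n = X.shape[0]
        out = {tag: np.empty((n, bands.n_bands)) for tag, _ in windows}
        self.reliable_ = {}
        for start in range(0, n, self.chunk_size):
            sl = slice(start, min(start + self.chunk_size, n))
            chunk = X[sl]
            Wx = cwt_morlet(chunk - chunk.mean(axis=-1, keepdims=True),
                            fs, bands.centers)          # (B, chunk, T)
            sxy = _smooth(Wx * np.conj(Wy)[:, None, :], scales,
                          self.smooth_time_factor)
            sxx = _smooth((Wx * np.conj(Wx)).real, scales,
                          self.smooth_time_factor)
            den = sxx * syy[:, None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                coh = (sxy.real ** 2 + sxy.imag ** 2) / den
            coh = np.where(den > 1e-300, coh, np.nan)
            coh = np.clip(coh, 0.0, 1.0)
            if not self.squared:
                coh = np.sqrt(coh)
            coh = np.moveaxis(coh, 0, 1)                # (chunk, B, T)
            for tag, win in windows:
                means, reliable = band_average(coh, t, win, bands)
                out[tag][sl] = means
                self.reliable_[tag] = reliable
        cols = {}
        for tag, _ in windows:
            for i in range(bands.n_bands):
                cols[f"wcoh_{tag}_{i:02d}"] = out[tag][:, i]
        return pd.DataFrame(cols)

    def get_feature_names_out(self, input_features=None):
        tags = ["bl"] + (["rec"] if self.scope == "bl+rec" else [])
        return np.asarray([f"wcoh_{tag}_{i:02d}" for tag in tags
                           for i in range(self.n_bands)], dtype=object)


def extract_fd_table(video: ThermalVideo, mask: np.ndarray,
                     scope: str = "bl+rec", fraction: float = 0.2,
                     seed: int = 0, **featurizer_kwargs) -> pd.DataFrame:
    """Per-pixel FD feature table: 60 (BL) or 120 (BL+REC) coherence values.

    Pixels belonging to the randomized reference subset are kept in the table
    and flagged in the ``in_reference`` column.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != video.frame_shape:
        raise ValueError("mask shape does not match the video frames")
    traces = video.traces()
    labels = mask.ravel().astype(int)
    fz = WaveletCoherenceFeaturizer(video.timestamps, video.phases,
                                    scope=scope, fraction=fraction, seed=seed,
                                    **featurizer_kwargs)
    feats = fz.fit(traces, labels).transform(traces)
    n_rows, n_cols = video.frame_shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    in_ref = np.zeros(labels.size, dtype=bool)
    in_ref[fz.reference_rows_] = True
    head = pd.DataFrame({"pixel_row": rr.ravel(), "pixel_col": cc.ravel(),
                         "label": labels, "in_reference": in_ref})
    return pd.concat([head, feats], axis=1)
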