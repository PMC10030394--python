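"""Per-pixel time-domain features of cold-stress thermal traces.

For each pixel the recovery phase is modelled as an exponential re-warming
``y = a * (1 - exp(b*t)) + c`` (a: asymptotic recovery amplitude, b < 0: the
negative inverse time constant, c: post-injection temperature); the fit is
kept only when its goodness R exceeds 0.8.  Alongside the fit, the features
are the whole-session temperature variation Δ, the pre-injection temperature
T_INI, and per-phase (baseline / recovery) standard deviation, kurtosis,
skewness, 90th percentile and sample entropy (m=2, r=0.2·SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

from ..video import ThermalVideo

__all__ = [
    "TdFit", "fit_recovery", "temperature_variation", "initial_temperature",
    "moment_features", "sample_entropy", "TimeDomainFeaturizer",
    "extract_td_table", "TD_BL_FEATURES", "TD_REC_FEATURES",
]

TD_BL_FEATURES = ["t_ini", "std_bl", "k_bl", "sk_bl", "p90_bl", "sampen_bl"]
TD_REC_FEATURES = ["a", "b", "c", "delta", "std_rec", "k_rec", "sk_rec",
                   "p90_rec", "sampen_rec"]


# -- sample entropy ---------------------------------------------------------

def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.size
    nt = n - m
    d = np.abs(x[:, None] - x[None, :])
    dm = d[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dm, d[k:k + nt, k:k + nt], out=dm)
    match_m = dm <= r
    match_m1 = match_m & (d[m:m + nt, m:m + nt] <= r)
    iu = np.triu_indices(nt, k=1)
    return int(match_m1[iu].sum()), int(match_m[iu].sum())


try:  # numba kernel; identical semantics to the numpy path
    from numba import njit

    @njit(cache=True)
    def _sampen_counts_numba(x, m, r):  # pragma: no cover - exercised via wrapper
        n = x.shape[0]
        nt = n - m
        a = 0
        b = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    dd = abs(x[i + k] - x[j + k])
                    if dd > d:
                        d = dd
                if d <= r:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

    _sampen_counts = _sampen_counts_numba
except ImportError:  # pragma: no cover
    _sampen_counts = _sampen_counts_numpy


def sample_entropy(trace, m: int = 2, r_factor: float = 0.2,
                   r: float | None = None) -> float:
    """Sample entropy: -ln of the conditional probability that length-m
    template matches (Chebyshev distance <= r, self-matches excluded) also
    match at length m+1.

    ``r`` defaults to ``r_factor * SD(trace)``.  A constant trace returns 0
    (every template matches); if no length-(m+1) pair matches, +inf.
    """
    x = np.ascontiguousarray(trace, dtype=np.float64)
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} samples for m={m}")
    if r is None:
        sd = float(np.std(x))
        if sd == 0.0:
            return 0.0
        r = r_factor * sd
    a, b = _sampen_counts(x, m, float(r))
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


# -- exponential recovery fit -----------------------------------------------

@dataclass
class TdFit:
    a: float
    b: float
    c: float
    r: float
    accepted: bool
    message: str = ""


def _exp_model(t, a, b, c):
    return a * (1.0 - np.exp(b * t)) + c


def _exp_jac(t, a, b, c):
    ebt = np.exp(b * t)
    return np.column_stack([1.0 - ebt, -a * t * ebt, np.ones_like(t)])


def fit_recovery(signal, t, r_threshold: float = 0.8) -> TdFit:
    """Nonlinear least-squares exponential re-warming fit on a REC trace.

    ``t`` must start at 0 and increase.  R is the correlation form of the
    goodness of fit, ``sqrt(max(R², 0))`` with R² the coefficient of
    determination; fits with R <= ``r_threshold`` are rejected (marked
    ``accepted=False``), as are degenerate or non-converging traces.
    """
    y = np.asarray(signal, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if y.size < 10:
        raise ValueError("need at least 10 recovery samples")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t must start at 0 and be strictly increasing")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return TdFit(np.nan, np.nan, np.nan, np.nan, False,
                     "flat trace: b unidentifiable")
    span = t[-1] - t[0]
    c0 = float(y[0])
    a0 = float(y[-1] - y[0])
    best = None
    for b0 in (-3.0 / span, -0.3 / span, -30.0 / span):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _exp_model, t, y, p0=(a0, b0, c0), jac=_exp_jac,
                    bounds=([-np.inf, -np.inf, -np.inf], [np.inf, -1e-12, np.inf]),
                    maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _exp_model(t, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return TdFit(np.nan, np.nan, np.nan, np.nan, False, "fit did not converge")
    popt, sse = best
    r = float(np.sqrt(max(1.0 - sse / sst, 0.0)))
    accepted = r > r_threshold
    return TdFit(float(popt[0]), float(popt[1]), float(popt[2]), r, accepted,
                 "" if accepted else f"goodness of fit R={r:.3f} <= {r_threshold}")


# -- scalar trace features --------------------------------------------------

def temperature_variation(signal, timestamps) -> float:
    """Δ: mean over the last 10 s minus mean over the first 10 s.

    Windows are ``t < t0 + 10`` and ``t >= t_end - 10``; positive values mean
    net warming over the session.  Requires >= 20 s of data.
    """
    y = np.asarray(signal, dtype=np.float64)
    t = np.asarray(timestamps, dtype=np.float64)
    if t[-1] - t[0] < 20.0:
        raise ValueError("trace must span at least 20 s")
    first = y[t < t[0] + 10.0]
    last = y[t >= t[-1] - 10.0]
    return float(last.mean() - first.mean())


def initial_temperature(signal, timestamps, t_injection: float) -> float:
    """T_INI: mean temperature over the 30 s preceding the cold stress."""
    y = np.asarray(signal, dtype=np.float64)
    t = np.asarray(timestamps, dtype=np.float64)
    if t_injection - t[0] < 30.0:
        raise ValueError("need at least 30 s of data before the injection")
    sel = (t >= t_injection - 30.0) & (t < t_injection)
    return float(y[sel].mean())


def moment_features(window) -> dict:
    """Sample SD, Pearson kurtosis (normal -> 3), skewness and interpolated
    90th percentile of a phase window.  Zero-variance windows return std=0
    with skewness/kurtosis NaN (flagged undefined)."""
    y = np.asarray(window, dtype=np.float64)
    if y.size < 4:
        raise ValueError("need at least 4 samples")
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        return {"std": 0.0, "kurtosis": np.nan, "skewness": np.nan,
                "p90": float(y[0]), "degenerate": True}
    return {"std": sd,
            "kurtosis": float(stats.kurtosis(y, fisher=False, bias=True)),
            "skewness": float(stats.skew(y, bias=True)),
            "p90": float(np.percentile(y, 90)),
            "degenerate": False}


# -- table extraction -------------------------------------------------------

class TimeDomainFeaturizer(TransformerMixin, BaseEstimator):
    """Transform a (n_pixels, n_frames) trace matrix into TD feature vectors.

    Parameters
    ----------
    timestamps : array
        Per-frame times, s.
    phases : Phases
        Protocol annotation (baseline / injection / recovery).
    scope : {"bl", "bl+rec"}
        "bl" yields only baseline-window features (plus T_INI);
        "bl+rec" adds the recovery fit (a, b, c), Δ and the REC-window
        features.  Rejected fits leave a/b/c as NaN.
    """

    def __init__(self, timestamps=None, phases=None, scope: str = "bl+rec",
                 m: int = 2, r_factor: float = 0.2, r_threshold: float = 0.8):
        self.timestamps = timestamps
        self.phases = phases
        self.scope = scope
        self.m = m
        self.r_factor = r_factor
        self.r_threshold = r_threshold

    def fit(self, X, y=None):
        if self.timestamps is None or self.phases is None:
            raise ValueError("timestamps and phases are required")
        if self.scope not in ("bl", "bl+rec"):
            raise ValueError("scope must be 'bl' or 'bl+rec'")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit(X)
        X = np.asarray(X, dtype=np.float64)
        t = np.asarray(self.timestamps, dtype=np.float64)
        ph = self.phases
        bl = (t >= ph.bl[0]) & (t < ph.bl[1])
        cols = {}
        cols["t_ini"] = X[:, (t >= ph.injection - 30.0) & (t < ph.injection)].mean(axis=1)
        self._phase_moments(X[:, bl], "bl", cols)
        if self.scope == "bl+rec":
            rec = (t >= ph.rec[0]) & (t < ph.rec[1])
            if not rec.any():
                raise ValueError("recovery phase missing for scope 'bl+rec'")
            t_rec = t[rec] - t[rec][0]
            fits = [fit_recovery(row, t_rec, self.r_threshold) for row in X[:, rec]]
            cols["a"] = [f.a if f.accepted else np.nan for f in fits]
            cols["b"] = [f.b if f.accepted else np.nan for f in fits]
            cols["c"] = [f.c if f.accepted else np.nan for f in fits]
            cols["fit_r"] = [f.r for f in fits]
            cols["delta"] = [temperature_variation(row, t) for row in X]
            self._phase_moments(X[:, rec], "rec", cols)
        return pd.DataFrame(cols)

    def _phase_moments(self, W: np.ndarray, tag: str, cols: dict) -> None:
        sd = np.std(W, axis=1, ddof=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kur = stats.kurtosis(W, axis=1, fisher=False, bias=True)
            skw = stats.skew(W, axis=1, bias=True)
        kur = np.where(sd == 0, np.nan, kur)
        skw = np.where(sd == 0, np.nan, skw)
        cols[f"std_{tag}"] = sd
        cols[f"k_{tag}"] = kur
        cols[f"sk_{tag}"] = skw
        cols[f"p90_{tag}"] = np.percentile(W, 90, axis=1)
        cols[f"sampen_{tag}"] = np.array(
            [sample_entropy(row, self.m, self.r_factor) for row in W])

    def get_feature_names_out(self, input_features=None):
        names = TD_BL_FEATURES.copy()
        if self.scope == "bl+rec":
            names += ["a", "b", "c", "fit_r"] + \
                [f for f in TD_REC_FEATURES if f not in ("a", "b", "c")]
        return np.asarray(names, dtype=object)


def extract_td_table(video: ThermalVideo, mask: np.ndarray,
                     scope: str = "bl+rec") -> pd.DataFrame:
    """Per-pixel TD feature table with pixel coordinates and class labels.

    Rows are labelled 1 inside the tumor mask, 0 outside.  Pixels whose
    recovery fit was rejected carry NaN in a/b/c.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != video.frame_shape:
        raise ValueError("mask shape does not match the video frames")
    if scope not in ("bl", "bl+rec"):
        raise ValueError("scope must be 'bl' or 'bl+rec'")
    feats = TimeDomainFeaturizer(video.timestamps, video.phases,
                                 scope=scope).transform(video.traces())
    n_rows, n_cols = video.frame_shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    head = pd.DataFrame({"pixel_row": rr.ravel(), "pixel_col": cc.ravel(),
                         "label": mask.ravel().astype(int)})
    return pd.concat([head, feats], axis=1)
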