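"""Feature-inspection statistics: per-patient two-class t-tests per feature
with Bonferroni correction, and the cross-patient maximally discriminative
coherence band."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bands import BandLayout

__all__ = ["test_features", "max_discriminative_band", "band_t_vector",
           "NON_FEATURE_COLUMNS"]

NON_FEATURE_COLUMNS = ("pixel_row", "pixel_col", "label", "in_reference",
                       "fit_r")


def test_features(table: pd.DataFrame, orientation: str = "class0-class1",
                  equal_var: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample t-test of class 0 (healthy) vs class 1 (tumor) per feature.

    Welch's test by default (``equal_var=True`` for the pooled-variance
    form).  Missing values are dropped per feature.  Bonferroni correction
    uses the number of feature columns in the table as the family size.
    ``orientation`` sets the sign: "class0-class1" or "class1-class0".

    Returns a DataFrame with columns feature_id, t_value, p_raw,
    p_bonferroni, significant, n0, n1.
    """
    if orientation not in ("class0-class1", "class1-class0"):
        raise ValueError("orientation must be 'class0-class1' or 'class1-class0'")
    labels = table["label"].to_numpy()
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes must be present")
    feature_cols = [c for c in table.columns if c not in NON_FEATURE_COLUMNS]
    n_tests = len(feature_cols)
    sign = 1.0 if orientation == "class0-class1" else -1.0
    rows = []
    for col in feature_cols:
        x = table[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        x0 = x[ok & (labels == 0)]
        x1 = x[ok & (labels == 1)]
        if x0.size < 2 or x1.size < 2 or (np.var(x0) == 0 and np.var(x1) == 0):
            t_val, p_raw = np.nan, np.nan
        else:
            t_val, p_raw = sps.ttest_ind(x0, x1, equal_var=equal_var)
            t_val *= sign
        p_bonf = min(1.0, p_raw * n_tests) if np.isfinite(p_raw) else np.nan
        rows.append({"feature_id": col, "t_value": t_val, "p_raw": p_raw,
                     "p_bonferroni": p_bonf,
                     "significant": bool(np.isfinite(p_bonf) and p_bonf < alpha),
                     "n0": int(x0.size), "n1": int(x1.size)})
    return pd.DataFrame(rows)


def band_t_vector(results: pd.DataFrame, prefix: str = "wcoh_rec_",
                  n_bands: int = 60) -> np.ndarray:
    """Extract the length-n_bands t-value vector for one coherence window."""
    vals = np.full(n_bands, np.nan)
    for _, row in results.iterrows():
        fid = row["feature_id"]
        if fid.startswith(prefix):
            vals[int(fid[len(prefix):])] = row["t_value"]
    if np.isnan(vals).any():
        raise ValueError(f"results lack some '{prefix}*' features")
    return vals


def max_discriminative_band(t_vectors: list[np.ndarray],
                            bands: BandLayout) -> tuple[int, float, float]:
    """Band with the largest cross-patient mean t-value.

    ``t_vectors`` holds one length-n_bands array per patient (class1-class0
    orientation).  Ties break toward the lower band index.  Returns
    ``(band_index, f_low, f_high)``.
    """
    arr = np.asarray(t_vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != bands.n_bands:
        raise ValueError("every t-vector must match the band layout")
    mean_t = arr.mean(axis=0)
    idx = int(np.argmax(mean_t))   # np.argmax returns the first (lowest) max
    return idx, float(bands.f_low[idx]), float(bands.f_high[idx])
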