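"""Frequency-band layout for the wavelet-coherence features.

The coherence spectrum is summarized over 60 contiguous bands spanning
[0.015, 2] Hz.  Bands are logarithmically spaced by default because wavelet
scale resolution is multiplicative; linear spacing is available for
sensitivity checks.  The cardiac band is the sub-range [0.4, 2] Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["BandLayout", "make_band_layout", "CARDIAC_BAND"]

CARDIAC_BAND = (0.4, 2.0)


@dataclass
class BandLayout:
    f_low: np.ndarray
    f_high: np.ndarray
    centers: np.ndarray

    @property
    def n_bands(self) -> int:
        return len(self.centers)

    def band_of(self, freq: float) -> int:
        """Index of the band containing ``freq`` (highest band is closed)."""
        idx = np.searchsorted(self.f_high, freq, side="left")
        if freq < self.f_low[0] or idx >= self.n_bands:
            if np.isclose(freq, self.f_high[-1]):
                return self.n_bands - 1
            raise ValueError(f"{freq} Hz outside the band layout")
        return int(idx)

    def to_records(self) -> list[dict]:
        return [{"band_id": i, "f_low": float(self.f_low[i]),
                 "f_center": float(self.centers[i]),
                 "f_high": float(self.f_high[i])}
                for i in range(self.n_bands)]

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)


def make_band_layout(n_bands: int = 60, f_min: float = 0.015,
                     f_max: float = 2.0, spacing: str = "log") -> BandLayout:
    if spacing == "log":
        edges = np.geomspace(f_min, f_max, n_bands + 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
    elif spacing == "linear":
        edges = np.linspace(f_min, f_max, n_bands + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
    else:
        raise ValueError("spacing must be 'log' or 'linear'")
    return BandLayout(f_low=edges[:-1], f_high=edges[1:], centers=centers)
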