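"""Thermal video container: a temperature movie with timebase and phase marks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phases", "ThermalVideo"]


@dataclass
class Phases:
    """Protocol phases on the recording's time axis (seconds).

    ``bl`` and ``rec`` are half-open intervals ``[t0, t1)``; ``injection`` is
    the instant of the cold-saline perturbation.  Baseline must end at or
    before the injection, recovery must begin at or after it.
    """

    bl: tuple[float, float]
    injection: float
    rec: tuple[float, float]

    def validate(self) -> None:
        if not (self.bl[0] < self.bl[1] <= self.injection <= self.rec[0] < self.rec[1]):
            raise ValueError("phases must be ordered BL <= injection <= REC")

    def to_dict(self) -> dict:
        return {"bl": list(self.bl), "injection": float(self.injection),
                "rec": list(self.rec)}

    @classmethod
    def from_dict(cls, d: dict) -> "Phases":
        return cls(bl=tuple(d["bl"]), injection=float(d["injection"]),
                   rec=tuple(d["rec"]))


@dataclass
class ThermalVideo:
    """Temperature movie: frames (n_frames, n_rows, n_cols) in °C."""

    frames: np.ndarray
    timestamps: np.ndarray
    phases: Phases
    meta: dict = field(default_factory=dict)

    def validate(self, uniform_tol: float = 1e-9) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, n_rows, n_cols) array")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("timestamps length must match frame count")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if dt.size and np.ptp(dt) > uniform_tol:
            raise ValueError("timestamps must be uniformly spaced")
        if not np.all(np.isfinite(self.frames)):
            bad = np.flatnonzero(~np.isfinite(self.frames).all(axis=(1, 2)))
            raise ValueError(f"non-finite temperatures in frames {bad.tolist()}")
        self.phases.validate()

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.timestamps)))

    def traces(self) -> np.ndarray:
        """Per-pixel traces as a (n_pixels, n_frames) float64 matrix.

        Pixels are flattened in C order, so trace ``i`` belongs to pixel
        ``(i // n_cols, i % n_cols)``.
        """
        t, r, c = self.frames.shape
        return self.frames.reshape(t, r * c).T.astype(np.float64)

    def phase_index(self, phase: str) -> np.ndarray:
        """Boolean frame mask for ``"bl"`` or ``"rec"`` (half-open windows)."""
        if phase == "bl":
            t0, t1 = self.phases.bl
        elif phase == "rec":
            t0, t1 = self.phases.rec
        else:
            raise ValueError(f"unknown phase {phase!r}")
        return (self.timestamps >= t0) & (self.timestamps < t1)
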