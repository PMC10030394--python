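"""Scenario configuration for the synthetic cold-stress thermal video generator.

A scenario describes the acquisition protocol (frame rate, phase durations),
the tumor geometry, and the per-class generative parameters of the two pixel
populations (healthy cortex vs. tumor).  Defaults follow the intraoperative
protocol the pipeline targets: 5 Hz thermal video, one minute of baseline,
a cold-saline perturbation, and two minutes of recovery, with the tumor
running 0.5-2 °C cooler than the surrounding parenchyma and re-warming more
slowly after the cold stress.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ClassParams",
    "ScenarioConfig",
    "default_tumor_polygon",
    "load_scenario",
    "save_scenario",
]


@dataclass
class ClassParams:
    """Generative parameters of one pixel class.

    Parameters
    ----------
    t_base : float
        Mean baseline temperature of the class, °C.
    t_base_sd : float
        Spatial standard deviation of the per-pixel baseline temperature, °C.
        Pixels draw their baseline level once; it does not vary over time.
    drop : float
        Cold-stress temperature drop applied at the injection, °C (positive).
    a : float
        Mean recovery amplitude, °C: the asymptotic re-warming above the
        post-injection level.
    b : float
        Mean recovery rate, 1/s; negative (the inverse of the recovery time
        constant, with the recovery modelled as ``a * (1 - exp(b*t)) + c``).
    a_rel_sd, b_rel_sd : float
        Relative per-pixel log-normal spread of ``a`` and ``|b|``; models
        within-class heterogeneity of the recovery dynamics.
    f_c : float
        Cardiac (perfusion) oscillation frequency, Hz.
    cardiac_amp : float
        Amplitude of the cardiac oscillation, °C.
    coherence_weight : float
        Mixing weight ``w`` in [0, 1] between the scene-shared cardiac source
        and a pixel-private one: the pixel's oscillation is
        ``w * shared + (1 - w) * private``.  High ``w`` makes the class
        coherent with the tumor reference signal.
    coherence_weight_sd : float
        Per-pixel Gaussian spread of the mixing weight (clipped to [0, 1]);
        models tissue heterogeneity within a class.
    """

    t_base: float
    t_base_sd: float
    drop: float
    a: float
    b: float
    a_rel_sd: float = 0.1
    b_rel_sd: float = 0.1
    f_c: float = 0.71
    cardiac_amp: float = 0.08
    coherence_weight: float = 0.1
    coherence_weight_sd: float = 0.15


def default_tumor_polygon(center: tuple[float, float] = (32.0, 32.0),
                          radius: float = 12.0, n_vertices: int = 12) -> list[tuple[float, float]]:
    """Regular polygon approximating a round lesion, in (row, col) pixel coords."""
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return [(center[0] + radius * math.sin(a), center[1] + radius * math.cos(a))
            for a in ang]


def _default_class_params() -> dict:
    # Healthy cortex: warmer, fast re-warming (tau ~ 8 s), weakly coupled to
    # the tumor reference.  Tumor: 1 °C cooler at baseline, slow re-warming
    # (tau ~ 50 s) that does not fully return to baseline, strongly coupled
    # cardiac oscillation.  Cardiac amplitude is the same in both classes:
    # the frequency-domain contrast is carried by the coupling weight alone.
    return {
        "healthy": ClassParams(t_base=33.5, t_base_sd=1.0, drop=4.0,
                               a=4.0, b=-0.12, coherence_weight=0.1),
        "tumor": ClassParams(t_base=32.5, t_base_sd=1.0, drop=4.0,
                             a=3.5, b=-0.02, coherence_weight=0.9),
    }


@dataclass
class ScenarioConfig:
    """Full description of a synthetic recording.

    ``t_bl`` and ``t_rec`` are the baseline and recovery durations in seconds;
    ``t_gap`` is the injection transient between them, excluded from every
    feature window.  ``noise_sd`` is the per-frame sensor noise SD in °C.
    ``slow_amp`` / ``slow_tau`` set the stationary SD (°C) and correlation
    time (s) of a per-pixel vasomotor fluctuation (Ornstein-Uhlenbeck), the
    sub-0.1 Hz physiological variability present in both tissue classes.
    """

    n_rows: int = 64
    n_cols: int = 64
    fs: float = 5.0
    t_bl: float = 60.0
    t_gap: float = 10.0
    t_rec: float = 120.0
    tumor_polygon: list = field(default_factory=default_tumor_polygon)
    class_params: dict = field(default_factory=_default_class_params)
    noise_sd: float = 0.1
    slow_amp: float = 0.3
    slow_tau: float = 20.0
    phase_drift_sd: float = 0.3   # rad / sqrt(sample), cardiac phase random walk
    baseline_smooth_sigma: float = 0.0  # px; 0 keeps pixels spatially i.i.d.
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.t_bl <= 0 or self.t_rec <= 0 or self.t_gap < 0:
            raise ValueError("phase durations must be positive (gap >= 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.slow_amp < 0 or self.slow_tau <= 0:
            raise ValueError("slow_amp must be >= 0 and slow_tau > 0")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("frame must be at least 2x2 pixels")
        poly = np.asarray(self.tumor_polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise ValueError("tumor_polygon needs >= 3 (row, col) vertices")
        if _polygon_area(poly) <= 0:
            raise ValueError("tumor_polygon is degenerate (zero area)")
        if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
                or poly[:, 0].max() > self.n_rows - 1
                or poly[:, 1].max() > self.n_cols - 1):
            raise ValueError("tumor_polygon must lie inside the frame")
        for name, cp in self.class_params.items():
            if not 0.0 <= cp.coherence_weight <= 1.0:
                raise ValueError(f"{name}: coherence_weight must be in [0, 1]")
            if cp.f_c >= self.fs / 2.0:
                raise ValueError(
                    f"{name}: cardiac frequency {cp.f_c} Hz violates the "
                    f"Nyquist limit fs/2 = {self.fs / 2.0} Hz")
            if cp.b >= 0:
                raise ValueError(f"{name}: recovery rate b must be negative")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tumor_polygon"] = [list(map(float, v)) for v in self.tumor_polygon]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        cp = d.get("class_params")
        if cp is not None:
            d["class_params"] = {k: ClassParams(**v) if isinstance(v, dict) else v
                                 for k, v in cp.items()}
        poly = d.get("tumor_polygon")
        if poly is not None:
            d["tumor_polygon"] = [tuple(map(float, v)) for v in poly]
        return cls(**d)


def _polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) vertices."""
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(y, np.roll(x, -1)) - np.dot(x, np.roll(y, -1)))


def save_scenario(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))
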