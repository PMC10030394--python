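"""Synthetic cold-stress thermal video generator.

Emulates an intraoperative recording of exposed cortex: a baseline phase at
the tissue's resting temperature, an instantaneous cold-saline perturbation
followed by a short excluded transient, and a recovery phase in which each
pixel re-warms exponentially.  Tumor and healthy pixels differ in baseline
temperature, recovery dynamics, and in how strongly their cardiac-band
oscillation is coupled to a scene-shared source — the structure the
downstream time-domain and wavelet-coherence features are designed to pick
up.

Per-pixel trace model (t measured from recovery onset)::

    T(t) = baseline                                   during BL
    T(t) = linear drop baseline -> c                  during the injection gap
    T(t) = c + a * (1 - exp(b * t))                   during REC
    + cardiac_amp * (w * shared(t) + (1 - w) * private(t)) + sensor noise

where ``shared`` and ``private`` are unit sinusoids at the cardiac frequency
with slowly drifting random phase, ``w`` is the class coherence weight and
``c = baseline - drop``.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ScenarioConfig
from .registration import AffineMap, rasterize_polygon
from .video import Phases, ThermalVideo

__all__ = ["generate_video", "make_control_points"]


def _narrowband_source(rng: np.random.Generator, t: np.ndarray, f_c: float,
                       drift_sd: float, n_sources: int = 1) -> np.ndarray:
    """Unit-amplitude sinusoids at f_c with random-walk phase drift.

    Returns an (n_sources, n_frames) array.  The phase random walk (SD
    ``drift_sd`` rad per sample) gives the source a finite coherence time, so
    two independent sources at the same frequency decorrelate.
    """
    steps = rng.normal(0.0, drift_sd, size=(n_sources, t.size))
    steps[:, 0] = rng.uniform(0.0, 2.0 * np.pi, size=n_sources)
    phi = np.cumsum(steps, axis=1)
    return np.sin(2.0 * np.pi * f_c * t[None, :] + phi)


def generate_video(cfg: ScenarioConfig) -> tuple[ThermalVideo, np.ndarray]:
    """Generate a synthetic thermal video and its ground-truth tumor mask.

    Returns
    -------
    video : ThermalVideo
        Frames are float32 °C, ``round(fs * (t_bl + t_gap + t_rec))`` of them.
    mask : ndarray of bool
        True inside the tumor polygon (pixel-center rasterization).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_frames = int(round(cfg.fs * (cfg.t_bl + cfg.t_gap + cfg.t_rec)))
    t = np.arange(n_frames, dtype=np.float64) / cfg.fs
    t_inj = cfg.t_bl
    t_rec0 = cfg.t_bl + cfg.t_gap
    phases = Phases(bl=(0.0, cfg.t_bl), injection=t_inj,
                    rec=(t_rec0, t_rec0 + cfg.t_rec))

    shape = (cfg.n_rows, cfg.n_cols)
    mask = rasterize_polygon(cfg.tumor_polygon, shape)
    if not mask.any():
        raise ValueError("tumor polygon covers no pixel centers")
    n_pix = cfg.n_rows * cfg.n_cols
    flat_mask = mask.ravel()

    hp = cfg.class_params["healthy"]
    tp = cfg.class_params["tumor"]

    # per-pixel static parameters, drawn healthy-first for reproducibility
    base = np.empty(n_pix)
    a_pix = np.empty(n_pix)
    b_pix = np.empty(n_pix)
    drop = np.empty(n_pix)
    amp = np.empty(n_pix)
    w = np.empty(n_pix)
    f_c = np.empty(n_pix)
    for sel, cp in ((~flat_mask, hp), (flat_mask, tp)):
        k = int(sel.sum())
        base[sel] = cp.t_base + cp.t_base_sd * rng.standard_normal(k)
        a_pix[sel] = cp.a * np.exp(cp.a_rel_sd * rng.standard_normal(k))
        b_pix[sel] = cp.b * np.exp(cp.b_rel_sd * rng.standard_normal(k))
        drop[sel] = cp.drop
        amp[sel] = cp.cardiac_amp
        w[sel] = np.clip(cp.coherence_weight
                         + cp.coherence_weight_sd * rng.standard_normal(k),
                         0.0, 1.0)
        f_c[sel] = cp.f_c

    if cfg.baseline_smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter
        base = gaussian_filter(base.reshape(shape),
                               cfg.baseline_smooth_sigma).ravel()

    c_pix = base - drop

    # deterministic thermal trajectory, (n_pix, n_frames)
    traj = np.empty((n_pix, n_frames))
    bl_sel = t < t_inj
    gap_sel = (t >= t_inj) & (t < t_rec0)
    rec_sel = t >= t_rec0
    traj[:, bl_sel] = base[:, None]
    if gap_sel.any():
        frac = (t[gap_sel] - t_inj) / cfg.t_gap
        traj[:, gap_sel] = base[:, None] + (c_pix - base)[:, None] * frac[None, :]
    t_rec = t[rec_sel] - t_rec0
    traj[:, rec_sel] = (c_pix[:, None]
                        + a_pix[:, None] * (1.0 - np.exp(b_pix[:, None] * t_rec[None, :])))

    # cardiac oscillation: shared source at the tumor cardiac frequency plus
    # one private source per pixel at its class frequency
    shared = _narrowband_source(rng, t, tp.f_c, cfg.phase_drift_sd)[0]
    private = np.empty((n_pix, n_frames))
    for freq in np.unique(f_c):
        sel = f_c == freq
        private[sel] = _narrowband_source(rng, t, float(freq),
                                          cfg.phase_drift_sd, int(sel.sum()))
    cardiac = amp[:, None] * (w[:, None] * shared[None, :]
                              + (1.0 - w[:, None]) * private)
    traj += cardiac

    # slow vasomotor fluctuation: per-pixel stationary Ornstein-Uhlenbeck
    # noise with SD slow_amp and correlation time slow_tau, identical in the
    # two classes — the sub-0.1 Hz physiological variability of living cortex
    if cfg.slow_amp > 0:
        rho = math.exp(-1.0 / (cfg.fs * cfg.slow_tau))
        innov = cfg.slow_amp * math.sqrt(1.0 - rho * rho)
        z = rng.standard_normal((n_pix, n_frames))
        z[:, 0] = z[:, 0] * cfg.slow_amp / max(innov, 1e-300)  # stationary start
        from scipy.signal import lfilter
        traj += lfilter([innov], [1.0, -rho], z, axis=1)

    if cfg.noise_sd > 0:
        traj += rng.normal(0.0, cfg.noise_sd, size=traj.shape)

    frames = traj.T.reshape(n_frames, *shape).astype(np.float32)
    video = ThermalVideo(frames=frames, timestamps=t, phases=phases,
                         meta={"generator": "thermoseg.simulate",
                               "config": cfg.to_dict()})
    video.validate()
    return video, mask


def make_control_points(cfg: ScenarioConfig, true_affine: AffineMap,
                        n_points: int, jitter_sd: float,
                        seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Paired control points for exercising the co-registration stage.

    Draws ``n_points`` non-collinear points uniformly inside the visible
    frame and maps them through ``true_affine``, adding Gaussian jitter of SD
    ``jitter_sd`` px to the mapped points (landmark-selection error).

    Returns ``(src_points, dst_points)`` as (n, 2) arrays in (row, col).
    """
    if n_points < 3:
        raise ValueError("at least 3 control points are required")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    margin = 1.0
    for _ in range(100):
        src = np.column_stack([
            rng.uniform(margin, cfg.n_rows - 1 - margin, n_points),
            rng.uniform(margin, cfg.n_cols - 1 - margin, n_points),
        ])
        centered = src - src.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] > 1e-6 * max(s[0], 1.0):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not draw non-collinear control points")
    dst = true_affine.apply(src)
    if jitter_sd > 0:
        dst = dst + rng.normal(0.0, jitter_sd, size=dst.shape)
    return src, dst


def n_expected_frames(cfg: ScenarioConfig) -> int:
    """Frame count implied by the protocol timing."""
    return int(round(cfg.fs * (cfg.t_bl + cfg.t_gap + cfg.t_rec)))
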