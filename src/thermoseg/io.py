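"""File formats: thermal video (multi-page TIFF + YAML sidecar, or NPZ),
masks (PNG), polygons and control points (CSV), feature tables (CSV/Parquet).

Disk conventions: TIFF frames are 32-bit float °C, one page per frame; mask
PNGs are 8-bit with 0 = healthy, 255 = tumor; point CSVs carry 1-based (x, y)
columns (imaging-tool convention) which are converted to the package's
0-based (row, col) at this boundary and nowhere else.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .video import Phases, ThermalVideo

__all__ = [
    "write_video", "read_video", "write_video_npz", "read_video_npz",
    "write_mask", "read_mask", "write_polygon_csv", "read_polygon_csv",
    "write_control_points", "read_control_points",
    "write_table", "read_table",
]

_TIFF_NAME = "video.tif"
_SIDECAR_NAME = "video.yaml"


# -- video ------------------------------------------------------------------

def write_video(video: ThermalVideo, path) -> None:
    """Write a video as ``path/video.tif`` plus ``path/video.yaml``."""
    video.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = np.ascontiguousarray(video.frames, dtype=np.float32)
    tifffile.imwrite(path / _TIFF_NAME, frames, photometric="minisblack")
    sidecar = {
        "n_frames": int(video.n_frames),
        "timestamps": [float(t) for t in video.timestamps],
        "phases": video.phases.to_dict(),
        "meta": video.meta,
    }
    with open(path / _SIDECAR_NAME, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_video(path) -> ThermalVideo:
    path = Path(path)
    tif = path / _TIFF_NAME
    sidecar = path / _SIDECAR_NAME
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    if not tif.exists():
        raise FileNotFoundError(f"missing video file {tif}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if "phases" not in meta or meta["phases"] is None:
        raise ValueError("sidecar lacks the phase annotation")
    frames = tifffile.imread(tif)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != int(meta["n_frames"]):
        raise ValueError(
            f"TIFF holds {frames.shape[0]} pages but sidecar declares "
            f"{meta['n_frames']} frames")
    if not np.all(np.isfinite(frames)):
        bad = np.flatnonzero(~np.isfinite(frames).all(axis=(1, 2)))
        raise ValueError(f"non-finite temperatures in frames {bad.tolist()}")
    video = ThermalVideo(frames=frames,
                         timestamps=np.asarray(meta["timestamps"], dtype=np.float64),
                         phases=Phases.from_dict(meta["phases"]),
                         meta=meta.get("meta", {}))
    video.validate()
    return video


def write_video_npz(video: ThermalVideo, path) -> None:
    """Single-file compressed container."""
    video.validate()
    np.savez_compressed(
        path, frames=video.frames, timestamps=video.timestamps,
        phases=np.asarray(yaml.safe_dump(video.phases.to_dict())),
        meta=np.asarray(yaml.safe_dump(video.meta)))


def read_video_npz(path) -> ThermalVideo:
    with np.load(path) as z:
        video = ThermalVideo(
            frames=z["frames"], timestamps=z["timestamps"],
            phases=Phases.from_dict(yaml.safe_load(str(z["phases"]))),
            meta=yaml.safe_load(str(z["meta"])) or {})
    video.validate()
    return video


# -- masks and polygons -----------------------------------------------------

def write_mask(mask: np.ndarray, path) -> None:
    img = Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255)), mode="L")
    img.save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_polygon_csv(polygon: np.ndarray, path) -> None:
    """Vertex list as CSV with 1-based (x, y) = (col+1, row+1) columns."""
    poly = np.asarray(polygon, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({"vertex_id": np.arange(len(poly)),
                       "x": poly[:, 1] + 1.0, "y": poly[:, 0] + 1.0})
    df.to_csv(path, index=False)


def read_polygon_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return np.column_stack([df["y"].to_numpy(float) - 1.0,
                            df["x"].to_numpy(float) - 1.0])


# -- control points ---------------------------------------------------------

def write_control_points(src, dst, path,
                         source_frame: str = "visible",
                         target_frame: str = "thermal") -> None:
    """Paired landmarks as CSV: frame_label, x, y, pair_id (1-based x, y)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    rows = []
    for label, pts in ((source_frame, src), (target_frame, dst)):
        for i, (r, c) in enumerate(pts):
            rows.append({"frame_label": label, "x": c + 1.0, "y": r + 1.0,
                         "pair_id": i})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_control_points(path, source_frame: str = "visible",
                        target_frame: str = "thermal"):
    df = pd.read_csv(path)
    out = []
    for label in (source_frame, target_frame):
        sub = df[df["frame_label"] == label].sort_values("pair_id")
        if sub.empty:
            raise ValueError(f"no control points labelled {label!r}")
        out.append(np.column_stack([sub["y"].to_numpy(float) - 1.0,
                                    sub["x"].to_numpy(float) - 1.0]))
    if len(out[0]) != len(out[1]):
        raise ValueError("unpaired control points")
    return out[0], out[1]


# -- feature tables ---------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> None:
    """Feature table to CSV or Parquet by extension.  NaN marks missing."""
    path = os.fspath(path)
    if path.endswith(".parquet"):
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = os.fspath(path)
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)
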