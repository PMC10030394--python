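"""Visible-to-thermal co-registration.

The tumor boundary is drawn by the neurosurgeon on a visible-light image;
paired control points between the visible and thermal images determine a 2-D
affine transform by least squares, and the mapped polygon is rasterized onto
the thermal pixel grid.

Coordinate convention: 0-based (row, col) with pixel centers at integer
coordinates.  Rasterization uses the even-odd rule on pixel centers;
boundary-touching centers count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AffineMap",
    "TumorBoundary",
    "estimate_affine",
    "rasterize_polygon",
    "transfer_boundary",
    "AffinePointRegistration",
]

_EPS_BOUNDARY = 1e-9


@dataclass
class AffineMap:
    """2-D affine transform ``p -> matrix @ p + offset`` on (row, col) points."""

    matrix: np.ndarray
    offset: np.ndarray
    source_frame: str = "visible"
    target_frame: str = "thermal"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.matrix)
        return AffineMap(inv, -inv @ self.offset,
                         source_frame=self.target_frame,
                         target_frame=self.source_frame)

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Return the map ``self  after  other`` (first apply ``other``)."""
        return AffineMap(self.matrix @ other.matrix,
                         self.matrix @ other.offset + self.offset,
                         source_frame=other.source_frame,
                         target_frame=self.target_frame)


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("control points are collinear; the affine transform "
                         "is underdetermined")


def estimate_affine(src_points, dst_points,
                    source_frame: str = "visible",
                    target_frame: str = "thermal") -> AffineMap:
    """Least-squares affine transform mapping ``src_points`` onto ``dst_points``.

    Minimizes ``sum ||A p + t - q||^2`` over the point pairs; with exactly
    three non-collinear pairs the fit is exact.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.ndim != 2 or src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) point arrays")
    if src.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required to fit an "
                         "affine transform")
    _check_not_collinear(src)
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2, :].T
    offset = coef[2, :]
    return AffineMap(matrix, offset, source_frame, target_frame)


# -- polygon handling -------------------------------------------------------

def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _check_simple(poly: np.ndarray) -> None:
    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closure
            if _segments_intersect(*edges[i], *edges[j]):
                raise ValueError("polygon is self-intersecting")


@dataclass
class TumorBoundary:
    """Closed tumor outline in a named coordinate frame, plus its raster."""

    polygon: np.ndarray
    frame: str = "visible"
    rasterized_mask: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        _check_simple(self.polygon)


def rasterize_polygon(polygon, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon.

    Even-odd (crossing number) rule; centers exactly on an edge are inside.
    ``polygon`` is an (n, 2) array of (row, col) vertices; pixel centers sit
    at integer (row, col).
    """
    poly = np.asarray(polygon, dtype=float).reshape(-1, 2)
    n_rows, n_cols = grid_shape
    rr, cc = np.meshgrid(np.arange(n_rows, dtype=float),
                         np.arange(n_cols, dtype=float), indexing="ij")
    py, px = rr.ravel(), cc.ravel()   # y = row, x = col
    inside = np.zeros(py.shape, dtype=bool)
    on_edge = np.zeros(py.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        y1, x1 = poly[i]
        y2, x2 = poly[(i + 1) % n]
        # even-odd crossing of the horizontal ray towards +x
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < xint)
        # explicit on-segment test so boundary-touching centers stay inside
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            on_edge |= (np.abs(px - x1) < _EPS_BOUNDARY) & (np.abs(py - y1) < _EPS_BOUNDARY)
            continue
        cross = (px - x1) * dy - (py - y1) * dx
        tpar = ((px - x1) * dx + (py - y1) * dy) / seg_len2
        on_edge |= (np.abs(cross) <= _EPS_BOUNDARY * np.sqrt(seg_len2)) & \
                   (tpar >= -_EPS_BOUNDARY) & (tpar <= 1 + _EPS_BOUNDARY)
    return (inside | on_edge).reshape(n_rows, n_cols)


def transfer_boundary(boundary: TumorBoundary, amap: AffineMap,
                      grid_shape: tuple[int, int]) -> TumorBoundary:
    """Map a boundary into the thermal frame and rasterize it on the grid."""
    if boundary.frame != amap.source_frame:
        raise ValueError(f"boundary frame {boundary.frame!r} does not match "
                         f"transform source {amap.source_frame!r}")
    mapped = amap.apply(boundary.polygon)
    n_rows, n_cols = grid_shape
    if (mapped[:, 0].max() < -0.5 or mapped[:, 0].min() > n_rows - 0.5
            or mapped[:, 1].max() < -0.5 or mapped[:, 1].min() > n_cols - 0.5):
        raise ValueError("mapped polygon lies entirely outside the thermal grid")
    mask = rasterize_polygon(mapped, grid_shape)
    if not mask.any():
        raise ValueError("mapped polygon covers no pixel centers on the grid")
    return TumorBoundary(mapped, frame=amap.target_frame, rasterized_mask=mask)


class AffinePointRegistration(TransformerMixin, BaseEstimator):
    """Landmark-based affine registration as a scikit-learn estimator.

    ``fit(src, dst)`` estimates the least-squares affine transform between
    paired control points; ``transform(points)`` maps points from the source
    into the target frame.
    """

    def __init__(self, source_frame: str = "visible", target_frame: str = "thermal"):
        self.source_frame = source_frame
        self.target_frame = target_frame

    def fit(self, X, y):
        src = np.asarray(X, dtype=float)
        dst = np.asarray(y, dtype=float)
        self.affine_ = estimate_affine(src, dst, self.source_frame, self.target_frame)
        resid = self.affine_.apply(src) - dst
        self.residuals_ = resid
        self.residual_rms_ = float(np.sqrt(np.mean(resid ** 2)))
        return self

    def transform(self, X):
        return self.affine_.apply(np.asarray(X, dtype=float))
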