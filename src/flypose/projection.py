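"""Pinhole projection, silhouette polygons and rasterization.

A camera is a 3x4 projection matrix ``M`` mapping homogeneous world points
(mm) to homogeneous pixel coordinates: ``(i', j', t) = M @ (x, y, z, 1)``
and ``(i, j) = (i'/t, j'/t)``.  Pixel convention: ``i`` is the column and
``j`` the row, 0-based, with the origin at the centre of the top-left
pixel.

The model silhouette in a view is built part-wise: the projected body
(plus rod, if any) and each wing are reduced to their 2D convex hulls
separately, and the silhouette is the planar union of the three hulls —
which is in general non-convex.  Occlusion needs no hidden-surface
treatment at silhouette level: the union already is the silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .fly_model import FlyGeometry, PoseVector17, pose_to_world_mesh


@dataclass
class CameraModel:
    """One calibrated camera: 3x4 projection matrix + image size."""

    M: np.ndarray
    image_width: int
    image_height: int
    label: str = ""

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (3, 4):
            raise ValueError(f"camera matrix must be 3x4, got {self.M.shape}")
        if np.linalg.matrix_rank(self.M) != 3:
            raise ValueError(f"camera matrix for '{self.label}' is rank-deficient")


@dataclass
class SilhouettePolygon:
    """Model silhouette in one view: union polygon + per-part hulls."""

    geometry: shapely.Geometry                 # union (Polygon or MultiPolygon)
    part_hulls: Dict[str, np.ndarray]          # part -> (h, 2) CCW hull vertices

    @property
    def area(self) -> float:
        return float(self.geometry.area)


def project_points(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Project 3D mm points to 2D pixel coordinates, order preserved.

    Raises ValueError (reporting the first offending index) if any point
    maps to projective infinity (third homogeneous coordinate t = 0).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = pts @ camera.M[:, :3].T + camera.M[:, 3]
    t = h[:, 2]
    bad = np.flatnonzero(np.abs(t) < 1e-12)
    if bad.size:
        raise ValueError(
            f"point {bad[0]} projects to infinity (t=0) in camera "
            f"'{camera.label}'")
    return h[:, :2] / t[:, None]


def convex_hull_2d(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull vertices of a 2D point set.

    Degenerate (fewer than 3 points, or all collinear) input is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("convex hull needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear) point set: {e}") from e
    return pts[hull.vertices]  # scipy returns CCW order in 2D


def hulls_from_mesh(mesh: Dict[str, np.ndarray],
                    camera: CameraModel) -> Dict[str, np.ndarray]:
    """Per-part convex hulls of a posed mesh projected into one camera.

    Rod vertices, when present, are merged into the body part.
    """
    body = mesh["body"]
    if "rod" in mesh:
        body = np.vstack([body, mesh["rod"]])
    return {name: convex_hull_2d(project_points(verts, camera))
            for name, verts in (("body", body), ("wing_l", mesh["wing_l"]),
                                ("wing_r", mesh["wing_r"]))}


def silhouette_hulls(pose: PoseVector17, geometry: FlyGeometry,
                     camera: CameraModel) -> Dict[str, np.ndarray]:
    """Per-part convex hulls of the posed model in one view (hot path)."""
    return hulls_from_mesh(pose_to_world_mesh(pose, geometry), camera)


def silhouette(pose: PoseVector17, geometry: FlyGeometry,
               camera: CameraModel) -> SilhouettePolygon:
    """Model silhouette polygon in one camera view.

    Convex hulls of the projected body (rod merged in) and of each wing
    are taken separately, then united; the union may be non-convex.
    """
    hulls = silhouette_hulls(pose, geometry, camera)
    union = unary_union([Polygon(h) for h in hulls.values()])
    return SilhouettePolygon(geometry=union, part_hulls=hulls)


def rasterize(polygon, camera: CameraModel) -> np.ndarray:
    """Binary mask: pixel set iff its centre lies inside the polygon.

    ``polygon`` may be a :class:`SilhouettePolygon`, a shapely geometry, or
    an (n, 2) vertex array.  The polygon is clipped to the image bounds.
    """
    if isinstance(polygon, SilhouettePolygon):
        geom = polygon.geometry
    elif isinstance(polygon, shapely.Geometry):
        geom = polygon
    else:
        geom = Polygon(np.asarray(polygon, dtype=float))
    H, W = camera.image_height, camera.image_width
    mask = np.zeros((H, W), dtype=bool)
    minx, miny, maxx, maxy = geom.bounds
    i0 = max(int(np.ceil(minx - 0.5)), 0)
    i1 = min(int(np.floor(maxx + 0.5)), W - 1)
    j0 = max(int(np.ceil(miny - 0.5)), 0)
    j1 = min(int(np.floor(maxy + 0.5)), H - 1)
    if i1 < i0 or j1 < j0:
        return mask
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1))
    inside = shapely.contains_xy(geom, ii.ravel(), jj.ravel())
    mask[j0:j1 + 1, i0:i1 + 1] = inside.reshape(jj.shape)
    return mask


def rasterize_convex(hull: np.ndarray, shape, origin=(0, 0)) -> np.ndarray:
    """Fast rasterizer for a single convex CCW polygon (half-plane test).

    Same pixel-centre convention as :func:`rasterize`; used on the hot
    path of the loss, where the parts are convex by construction.  Pixel
    (row j, col i) of the output grid sits at world pixel coordinates
    ``(i + origin[0], j + origin[1])``.
    """
    mask = np.zeros(shape, dtype=bool)
    out = _convex_patch(hull, shape, origin, smooth=False)
    if out is not None:
        patch, j0, i0 = out
        mask[j0:j0 + patch.shape[0], i0:i0 + patch.shape[1]] = patch
    return mask


def _convex_patch(hull: np.ndarray, shape, origin, smooth: bool):
    """Rasterize a convex CCW polygon over its bbox within a grid.

    Returns ``(patch, j0, i0)``: a float (coverage) or bool (pixel-centre)
    patch and its top-left grid indices, or ``None`` if the polygon does
    not intersect the grid.  Grid pixel (j, i) sits at world pixel
    coordinates ``(i + origin[0], j + origin[1])``.
    """
    H, W = shape
    pad = 1.0 if smooth else 0.5
    xs, ys = hull[:, 0] - origin[0], hull[:, 1] - origin[1]
    i0 = max(int(np.ceil(xs.min() - pad)), 0)
    i1 = min(int(np.floor(xs.max() + pad)), W - 1)
    j0 = max(int(np.ceil(ys.min() - pad)), 0)
    j1 = min(int(np.floor(ys.max() + pad)), H - 1)
    if i1 < i0 or j1 < j0:
        return None
    xs = xs.astype(np.float32)
    ys = ys.astype(np.float32)
    ii = np.arange(i0, i1 + 1, dtype=np.float32)
    jj = np.arange(j0, j1 + 1, dtype=np.float32)
    ex = np.concatenate([xs[1:], xs[:1]]) - xs
    ey = np.concatenate([ys[1:], ys[:1]]) - ys
    if smooth:
        ln = np.hypot(ex, ey)
        ln[ln == 0] = 1.0
        ex, ey = ex / ln, ey / ln
    d = (ex[:, None, None] * (jj[None, :, None] - ys[:, None, None])
         - ey[:, None, None] * (ii[None, None, :] - xs[:, None, None]))
    if smooth:
        patch = np.clip(d.min(axis=0) + np.float32(0.5), 0.0, 1.0)
    else:
        patch = (d >= 0.0).all(axis=0)
    return patch, j0, i0


def coverage_convex(hull: np.ndarray, shape,
                    origin=(0, 0)) -> np.ndarray:
    """Anti-aliased raster of a convex CCW polygon: per-pixel coverage.

    Coverage is approximated from the signed distance to the nearest
    edge line, ``clip(d + 1/2, 0, 1)`` — exact for a straight boundary
    crossing the pixel, smooth in the polygon's pose everywhere.  Pixel
    (row j, col i) of the output grid sits at world pixel coordinates
    ``(i + origin[0], j + origin[1])``.
    """
    cov = np.zeros(shape)
    out = _convex_patch(hull, shape, origin, smooth=True)
    if out is not None:
        patch, j0, i0 = out
        cov[j0:j0 + patch.shape[0], i0:i0 + patch.shape[1]] = patch
    return cov


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a simple polygon (positive for CCW order)."""
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def clip_polygon_to_rect(poly: np.ndarray, xmin: float, xmax: float,
                         ymin: float, ymax: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex CCW polygon to a rectangle."""
    def clip_half(pts, inside, intersect):
        out = []
        n = len(pts)
        for k in range(n):
            cur, nxt = pts[k], pts[(k + 1) % n]
            cin, nin = inside(cur), inside(nxt)
            if cin:
                out.append(cur)
                if not nin:
                    out.append(intersect(cur, nxt))
            elif nin:
                out.append(intersect(cur, nxt))
        return out

    def x_cross(a, b, x0):
        t = (x0 - a[0]) / (b[0] - a[0])
        return (x0, a[1] + t * (b[1] - a[1]))

    def y_cross(a, b, y0):
        t = (y0 - a[1]) / (b[1] - a[1])
        return (a[0] + t * (b[0] - a[0]), y0)

    pts = [tuple(p) for p in np.asarray(poly, dtype=float)]
    for inside, intersect in (
            (lambda p: p[0] >= xmin, lambda a, b: x_cross(a, b, xmin)),
            (lambda p: p[0] <= xmax, lambda a, b: x_cross(a, b, xmax)),
            (lambda p: p[1] >= ymin, lambda a, b: y_cross(a, b, ymin)),
            (lambda p: p[1] <= ymax, lambda a, b: y_cross(a, b, ymax))):
        pts = clip_half(pts, inside, intersect)
        if not pts:
            return np.empty((0, 2))
    return np.array(pts)


def rasterize_parts(part_hulls: Dict[str, np.ndarray], camera: CameraModel,
                    parts: Optional[List[str]] = None) -> np.ndarray:
    """OR of the per-part convex rasters — the rasterized silhouette union."""
    shape = (camera.image_height, camera.image_width)
    mask = np.zeros(shape, dtype=bool)
    for name, hull in part_hulls.items():
        if parts is not None and name not in parts:
            continue
        mask |= rasterize_convex(hull, shape)
    return mask
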