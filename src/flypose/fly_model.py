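"""Parametric 3D fly model: 17-DOF pose, deformable geometry, posing.

The fly is described by 17 kinematic parameters per frame:

* ``x, y, z`` — centre-of-mass position in the lab frame (mm);
* ``yaw, pitch, roll`` — body Euler angles (deg), intrinsic z-y-x order;
* ``phi_l, phi_r`` — wing stroke angles in the stroke plane (deg);
* ``theta_l, theta_r`` — wing elevation angles out of the stroke plane (deg);
* ``psi_l, psi_r`` — wing pitch angles about the span axis (deg);
* ``dx, dy, dz`` — symmetric wing-hinge translation in the body frame (mm);
* ``alpha_l, alpha_r`` — wing twist per unit span (deg/mm).

The wing hinge is not anatomically fixed, so the two hinges are allowed to
translate *symmetrically* about the sagittal plane (one shared (dx, dy, dz),
applied with opposite lateral sign to the two sides).  Wing-surface
deformation is modelled as a kinematic linear twist: zero at the wing tip,
maximal at the base, applied only to the trailing (chordwise "bottom") half
of the wing.

Euler-angle conventions used throughout (the rotation code below is the
single source of truth):

* body: intrinsic yaw about lab z, then pitch about the new y, then roll
  about the new x, i.e. ``R = Rz(yaw) @ Ry(pitch) @ Rx(roll)``;
* stroke plane: fixed in the body frame, inclined ``stroke_plane_angle``
  (default 45 deg) about the body y axis relative to the body long axis;
* wing (left): stroke ``phi`` about the stroke-plane normal, elevation
  ``theta`` about the in-plane axis perpendicular to the span, pitch ``psi``
  about the span axis, i.e. ``R = Rz(phi) @ Rx(theta) @ Ry(psi)`` in the
  stroke-plane frame with the span along +y.  The right wing is the exact
  sagittal mirror of the left-wing construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

POSE_FIELDS = (
    "x", "y", "z",
    "yaw", "pitch", "roll",
    "phi_l", "phi_r",
    "theta_l", "theta_r",
    "psi_l", "psi_r",
    "dx", "dy", "dz",
    "alpha_l", "alpha_r",
)

POSE_UNITS = {
    "x": "mm", "y": "mm", "z": "mm",
    "yaw": "deg", "pitch": "deg", "roll": "deg",
    "phi_l": "deg", "phi_r": "deg",
    "theta_l": "deg", "theta_r": "deg",
    "psi_l": "deg", "psi_r": "deg",
    "dx": "mm", "dy": "mm", "dz": "mm",
    "alpha_l": "deg/mm", "alpha_r": "deg/mm",
}

#: indices of the 9 angular DOFs (body + wing Euler angles) in POSE_FIELDS
ANGLE_FIELDS = ("yaw", "pitch", "roll",
                "phi_l", "phi_r", "theta_l", "theta_r", "psi_l", "psi_r")


@dataclass
class PoseVector17:
    """Full kinematic state of the fly in one frame.

    Fields are in the fixed order of :data:`POSE_FIELDS`; see the module
    docstring for units and conventions.
    """

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    phi_l: float = 0.0
    phi_r: float = 0.0
    theta_l: float = 0.0
    theta_r: float = 0.0
    psi_l: float = 0.0
    psi_r: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    alpha_l: float = 0.0
    alpha_r: float = 0.0

    def to_array(self) -> np.ndarray:
        """Return the pose as a length-17 float array in canonical order."""
        return np.array([getattr(self, f) for f in POSE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PoseVector17":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (17,):
            raise ValueError(f"pose vector must have 17 entries, got {arr.shape}")
        return cls(**{f: float(v) for f, v in zip(POSE_FIELDS, arr)})

    def replace(self, **kw) -> "PoseVector17":
        return replace(self, **kw)


def mirror_pose(pose: PoseVector17) -> PoseVector17:
    """Sagittal mirror of a pose: swap left/right wings, flip lateral signs.

    The posed mesh of the mirrored pose is the reflection, about the lab
    x-z plane, of the posed mesh of the input (with body left/right labels
    swapped).  The map is an involution.
    """
    return PoseVector17(
        x=pose.x, y=-pose.y, z=pose.z,
        yaw=-pose.yaw, pitch=pose.pitch, roll=-pose.roll,
        phi_l=pose.phi_r, phi_r=pose.phi_l,
        theta_l=pose.theta_r, theta_r=pose.theta_l,
        psi_l=pose.psi_r, psi_r=pose.psi_l,
        dx=pose.dx, dy=pose.dy, dz=pose.dz,
        alpha_l=pose.alpha_r, alpha_r=pose.alpha_l,
    )


@dataclass
class FlyGeometry:
    """Rest-pose geometry of the model fly, in mm.

    ``body_vertices``/``body_faces`` describe the rigid body mesh in the
    body frame (x forward, y left, z up, origin at the centre of mass).
    ``wing_outline`` is the planar outline of one wing in its own frame:
    base at the origin, span along +y up to ``span_length``, chord along x
    with the leading edge at x > 0.  ``rod_vertices`` optionally describes
    a magnet rod glued to the thorax (rigidly follows the body).
    """

    body_vertices: np.ndarray          # (N, 3)
    body_faces: np.ndarray             # (M, 3) int
    wing_outline: np.ndarray           # (K, 2): columns (chord x, span y)
    span_length: float
    rest_hinge_left: np.ndarray        # (3,)
    rest_hinge_right: np.ndarray       # (3,)
    scale: float = 1.0
    stroke_plane_angle: float = 45.0   # deg, inclination about body y axis
    rod_vertices: Optional[np.ndarray] = None

    def __post_init__(self):
        self.body_vertices = np.asarray(self.body_vertices, dtype=float)
        self.body_faces = np.asarray(self.body_faces, dtype=int)
        self.wing_outline = np.asarray(self.wing_outline, dtype=float)
        self.rest_hinge_left = np.asarray(self.rest_hinge_left, dtype=float)
        self.rest_hinge_right = np.asarray(self.rest_hinge_right, dtype=float)
        if self.rod_vertices is not None:
            self.rod_vertices = np.asarray(self.rod_vertices, dtype=float)
        if self.span_length <= 0:
            raise ValueError("span_length must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rest_hinge_left * [1, -1, 1],
                           self.rest_hinge_right, atol=1e-9):
            raise ValueError("rest hinges must be mirror-symmetric about y=0")


def _ellipsoid_points(center, radii, n_lat=6, n_lon=10):
    """Lat-long point grid + triangulation of one ellipsoid."""
    lat = np.linspace(-np.pi / 2, np.pi / 2, n_lat + 2)[1:-1]
    lon = np.linspace(0, 2 * np.pi, n_lon, endpoint=False)
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")
    pts = np.stack([
        np.cos(LAT) * np.cos(LON) * radii[0],
        np.cos(LAT) * np.sin(LON) * radii[1],
        np.sin(LAT) * radii[2],
    ], axis=-1).reshape(-1, 3) + np.asarray(center)
    poles = np.array([
        [center[0], center[1], center[2] - radii[2]],
        [center[0], center[1], center[2] + radii[2]],
    ])
    verts = np.vstack([pts, poles])
    faces = []
    idx = lambda i, j: i * n_lon + (j % n_lon)
    for i in range(n_lat - 1):
        for j in range(n_lon):
            faces.append([idx(i, j), idx(i, j + 1), idx(i + 1, j)])
            faces.append([idx(i + 1, j), idx(i, j + 1), idx(i + 1, j + 1)])
    south, north = len(verts) - 2, len(verts) - 1
    for j in range(n_lon):
        faces.append([south, idx(0, j + 1), idx(0, j)])
        faces.append([north, idx(n_lat - 1, j), idx(n_lat - 1, j + 1)])
    return verts, np.array(faces, dtype=int)


def _default_wing_outline(span: float, n_edge: int = 14) -> np.ndarray:
    """Drosophila-like wing outline: rounded tip, bulged trailing edge.

    Closed simple polyline, counter-clockwise, base at the origin, span
    along +y, leading edge at x > 0.  Chord widths are fractions of span
    chosen to give the familiar ~0.36 chord/span aspect of a fruit-fly
    wing; this is a documented parametric stand-in, not a digitised wing.
    """
    s = np.linspace(0.02, 0.995, n_edge)
    x_le = 0.10 * span * np.sin(np.pi * s ** 0.9)          # leading edge
    x_te = -0.26 * span * np.sin(np.pi * s ** 0.62)        # trailing edge
    lead = np.column_stack([x_le, s * span])
    trail = np.column_stack([x_te, s * span])[::-1]
    tip = np.array([[0.0, span]])
    base = np.array([[0.0, 0.0]])
    return np.vstack([base, lead, tip, trail])


def default_geometry(scale: float = 1.0,
                     with_rod: bool = False,
                     stroke_plane_angle: float = 45.0) -> FlyGeometry:
    """Built-in fly geometry at a given global size multiplier.

    The body is a three-ellipsoid stand-in (abdomen, thorax, head) of total
    length ~2.5 mm at scale 1; the single-wing span is 2.5 mm.  These are
    package defaults for a female *D. melanogaster*-sized fly.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    # the body axis is curved (drooping abdomen, raised head), as in a
    # real fly: the curvature breaks the roll-symmetry of the silhouette
    # that a straight tube of ellipsoids would have
    segs = [
        # center (mm), radii (mm): abdomen, thorax, head
        ((-0.62, 0.0, -0.22), (0.68, 0.34, 0.40)),
        ((0.28, 0.0, 0.10), (0.42, 0.33, 0.36)),
        ((0.93, 0.0, 0.28), (0.30, 0.25, 0.27)),
    ]
    verts, faces = [], []
    off = 0
    for c, r in segs:
        v, f = _ellipsoid_points(c, r)
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    body_v = np.vstack(verts) * scale
    body_f = np.vstack(faces)
    span = 2.5 * scale
    rod = None
    if with_rod:
        t = np.linspace(0, 1, 8)[:, None]
        a = np.array([0.25, 0.0, 0.40]) * scale
        b = np.array([-0.3, 0.0, 1.6]) * scale
        axis = a + t * (b - a)
        r = 0.05 * scale
        ring = np.array([[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0]])
        rod = (axis[:, None, :] + ring[None, :, :]).reshape(-1, 3)
    return FlyGeometry(
        body_vertices=body_v,
        body_faces=body_f,
        wing_outline=_default_wing_outline(span),
        span_length=span,
        rest_hinge_left=np.array([0.25, 0.22, 0.28]) * scale,
        rest_hinge_right=np.array([0.25, -0.22, 0.28]) * scale,
        scale=scale,
        stroke_plane_angle=stroke_plane_angle,
        rod_vertices=rod,
    )


# ---------------------------------------------------------------------------
# rotations


def rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def body_rotation(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Body frame -> lab frame rotation, intrinsic z-y-x (yaw-pitch-roll)."""
    return rot_z(yaw) @ rot_y(pitch) @ rot_x(roll)


def wing_rotation(phi: float, theta: float, psi: float) -> np.ndarray:
    """Left-wing frame -> stroke-plane frame rotation.

    Stroke about the stroke-plane normal (z), elevation about the in-plane
    x axis, pitch about the span (y) axis; intrinsic order phi-theta-psi.
    """
    return rot_z(phi) @ rot_x(theta) @ rot_y(psi)


_MIRROR = np.diag([1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# deformation and posing


def apply_twist(wing_outline: np.ndarray, alpha: float,
                span_length: float) -> np.ndarray:
    """Twist a planar wing outline linearly from tip (none) to base (max).

    Each vertex on the trailing side of the span axis (chord coordinate
    x < 0) at spanwise position ``s`` is rotated about the span axis by
    ``alpha * (span_length - s)`` degrees; the leading side and the tip are
    left in place.  Returns 3D vertices (twist moves trailing points out of
    the wing plane).
    """
    out = np.zeros((len(wing_outline), 3))
    x = wing_outline[:, 0]
    s = wing_outline[:, 1]
    out[:, 0] = x
    out[:, 1] = s
    trailing = x < 0
    ang = np.deg2rad(alpha * (span_length - s[trailing]))
    # rotation about +y axis: (x, z=0) -> (x cos a, -x sin a) ... using the
    # right-handed convention of rot_y: x' = x cos a, z' = -x sin a
    out[trailing, 0] = x[trailing] * np.cos(ang)
    out[trailing, 2] = -x[trailing] * np.sin(ang)
    return out


def check_pose_bounds(pose: PoseVector17, lower: np.ndarray,
                      upper: np.ndarray) -> None:
    """Raise ValueError naming the first out-of-bounds pose field."""
    arr = pose.to_array()
    for i, name in enumerate(POSE_FIELDS):
        if not (lower[i] - 1e-9 <= arr[i] <= upper[i] + 1e-9):
            raise ValueError(
                f"pose field '{name}' = {arr[i]:.4g} outside "
                f"[{lower[i]:.4g}, {upper[i]:.4g}]")


def pose_to_world_mesh(pose: PoseVector17,
                       geometry: FlyGeometry) -> Dict[str, np.ndarray]:
    """Pose the model and return lab-frame vertex sets.

    Returns a dict with keys ``body``, ``wing_l``, ``wing_r`` and, when the
    geometry carries a rod, ``rod`` (the rod rigidly follows the body).
    """
    Rb = body_rotation(pose.yaw, pose.pitch, pose.roll)
    pos = np.array([pose.x, pose.y, pose.z])
    Rs = rot_y(-geometry.stroke_plane_angle)
    delta = np.array([pose.dx, pose.dy, pose.dz])

    out: Dict[str, np.ndarray] = {}
    out["body"] = geometry.body_vertices @ Rb.T + pos
    if geometry.rod_vertices is not None:
        out["rod"] = geometry.rod_vertices @ Rb.T + pos

    # left wing
    wl = apply_twist(geometry.wing_outline, pose.alpha_l, geometry.span_length)
    Rwl = Rs @ wing_rotation(pose.phi_l, pose.theta_l, pose.psi_l)
    hinge_l = geometry.rest_hinge_left + delta
    out["wing_l"] = (wl @ Rwl.T + hinge_l) @ Rb.T + pos

    # right wing: sagittal mirror of the left-wing construction
    wr = apply_twist(geometry.wing_outline, pose.alpha_r, geometry.span_length)
    Rwr = Rs @ wing_rotation(pose.phi_r, pose.theta_r, pose.psi_r)
    hinge_r = geometry.rest_hinge_right + delta * [1, -1, 1]
    out["wing_r"] = (wr @ Rwr.T) @ _MIRROR + hinge_r
    out["wing_r"] = out["wing_r"] @ Rb.T + pos
    return out
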