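"""Sequential pose tracking: bounded derivative-free fitting per frame,
wing-pitch degeneracy detection, and multi-random-start correction.

Each frame is fitted by minimizing the weighted multi-view silhouette-XOR
loss, starting from the previous frame's result.  All parameters are
affinely scaled to the unit cube before optimization so that the loss is
equally sensitive to a unit step in every coordinate, and the optimizer is
a monotone compass (coordinate pattern) search: it polls +/- steps along
each free coordinate, accepts only strict improvements, and halves the
step when a full sweep fails — so the returned loss never exceeds the
loss of the initial condition and the whole procedure is deterministic.

Physiological bounds constrain every angle; in addition the body roll
angle is constrained to a +/-2 deg window around each frame's initial
condition, and (as a frame-to-frame continuity constraint at high frame
rates) the position and the remaining body angles are constrained to
configurable windows around the initial condition as well.

Certain body/wing configurations make the wing pitch angle psi nearly
unobservable from silhouettes: two psi values ~30 deg apart project to
almost identical outlines, and the optimizer can fall into the wrong
minimum.  Such events are detected as discontinuities in psi or in the
loss, and corrected by a multi-random-start (MRS) procedure: the flagged
frame is re-fitted from spread-out random points (k-means++ seeding over
the scaled parameter cube), the best result is kept, and the preceding
"suspected" frames are re-fitted backwards from their corrected
neighbour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .fly_model import (POSE_FIELDS, POSE_UNITS, FlyGeometry, PoseVector17,
                        check_pose_bounds, pose_to_world_mesh)
from .loss import LossValue, ViewWeights, view_weights
from ._fastgeom import abs_diff_sum, add_convex_patch, convex_hull_ccw
from .projection import CameraModel, clip_polygon_to_rect, polygon_area
from .segmentation import Frame, SegMask, estimate_background, segment_frame

_IDX = {name: i for i, name in enumerate(POSE_FIELDS)}
_DEFORM_FIELDS = ("dx", "dy", "dz", "alpha_l", "alpha_r")


@dataclass
class ParamBounds:
    """Box bounds for the 17 pose parameters plus per-frame windows.

    ``lower``/``upper`` are the global (physiological) bounds.  Per frame,
    the effective bounds additionally confine roll to ``roll_window`` deg,
    yaw and pitch to ``body_angle_window`` deg, and x, y, z to
    ``pos_window`` mm around that frame's initial condition.  ``frozen``
    marks coordinates excluded from optimization (e.g. the five
    deformation DOFs when fitting the rigid 12-DOF model).
    """

    lower: np.ndarray
    upper: np.ndarray
    roll_window: float = 2.0
    body_angle_window: float = 10.0
    pos_window: float = 0.5
    frozen: np.ndarray = field(
        default_factory=lambda: np.zeros(17, dtype=bool))

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        if self.lower.shape != (17,) or self.upper.shape != (17,):
            raise ValueError("bounds must have 17 entries")
        if not (self.lower < self.upper).all():
            raise ValueError("every lower bound must be below its upper bound")

    @classmethod
    def default(cls, rigid: bool = False, **kw) -> "ParamBounds":
        """Physiological default bounds; ``rigid=True`` freezes the five
        deformation DOFs (hinge translation and twist) at their initial
        values, i.e. fits the basic 12-DOF model."""
        lo = np.array([-30, -30, -30,          # x y z (mm)
                       -360, -90, -120,        # yaw pitch roll (deg)
                       -90, -90, -60, -60,     # phi_l phi_r theta_l theta_r
                       -120, -120,             # psi_l psi_r
                       -0.3, -0.3, -0.3,       # dx dy dz (mm)
                       -20, -20], dtype=float)  # alpha_l alpha_r (deg/mm)
        hi = np.array([30, 30, 30,
                       360, 90, 120,
                       160, 160, 60, 60,
                       120, 120,
                       0.3, 0.3, 0.3,
                       20, 20], dtype=float)
        frozen = np.zeros(17, dtype=bool)
        if rigid:
            for f in _DEFORM_FIELDS:
                frozen[_IDX[f]] = True
        return cls(lower=lo, upper=hi, frozen=frozen, **kw)

    def frame_bounds(self, initial: PoseVector17) -> Tuple[np.ndarray, np.ndarray]:
        """Effective (lower, upper) for one frame, windows centred on the
        frame's initial condition and intersected with the global box."""
        init = initial.to_array()
        lo, hi = self.lower.copy(), self.upper.copy()
        windows = {"x": self.pos_window, "y": self.pos_window,
                   "z": self.pos_window,
                   "yaw": self.body_angle_window,
                   "pitch": self.body_angle_window,
                   "roll": self.roll_window}
        for name, w in windows.items():
            i = _IDX[name]
            lo[i] = max(lo[i], init[i] - w)
            hi[i] = min(hi[i], init[i] + w)
        return lo, hi


def scale_params(pose: PoseVector17, lower: np.ndarray,
                 upper: np.ndarray) -> np.ndarray:
    """Affine map of a pose into the unit cube defined by the bounds."""
    check_pose_bounds(pose, lower, upper)
    arr = pose.to_array()
    return np.clip((arr - lower) / (upper - lower), 0.0, 1.0)


def unscale_params(vec: np.ndarray, lower: np.ndarray,
                   upper: np.ndarray) -> PoseVector17:
    """Inverse of :func:`scale_params`."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (17,):
        raise ValueError("scaled vector must have 17 entries")
    return PoseVector17.from_array(lower + vec * (upper - lower))


@dataclass
class FitOptions:
    """Per-frame optimizer settings (scaled, unit-cube units).

    The fit runs a short coarse compass search on the anti-aliased loss,
    then bounded Nelder-Mead stages with a progressively sharper
    anti-aliasing band (a wide band smooths the raster staircase but
    biases thin wing slivers by a fraction of a pixel; sharpening shrinks
    that bias), and finally a fine compass polish on the exact binary
    loss that also enforces the monotone-improvement contract against
    the initial condition.  ``retry_loss`` is the binary-loss level
    above which the sequential tracker considers the frame suspect and
    re-fits from a constant-velocity extrapolated initial condition
    (active only when error detection is enabled).
    """

    initial_step: float = 0.02     # coarse compass step
    coarse_evals: int = 150
    coarse_min_step: float = 5e-3
    nm_stages: Tuple[Tuple[float, int], ...] = ((1.0, 400), (4.0, 220))
    xatol: float = 1e-5            # Nelder-Mead termination
    fatol: float = 1e-10
    polish_evals: int = 300        # binary-loss compass polish
    polish_angle_step: float = 0.6     # deg, initial physical poll step
    polish_pos_step: float = 0.012     # mm
    polish_shrink: float = 8.0         # total step shrink across the polish
    retry_loss: float = 1.2e-2
    # frames whose binary loss stays above escalate_loss after the
    # standard stages get extra Nelder-Mead rounds on a finer AA ladder
    # (off by default: the standard ladder plus roll anchoring reaches
    # the accuracy floor, and deeper digging mostly re-finds the same
    # near-degenerate minima at twice the cost)
    escalate_loss: float = 8e-3
    escalate_stages: Tuple[Tuple[float, int], ...] = ()
    # body roll is the least observable DOF from silhouettes: small roll
    # offsets are almost fully compensable by wing-angle adjustments, so
    # an unconstrained fit lets roll random-walk at the fit-noise level.
    # After the fit, a candidate with roll re-anchored to the initial
    # condition (and the rest re-polished) is preferred unless moving
    # roll lowered the loss by more than this margin (hysteresis).
    roll_anchor_margin: float = 6e-3
    anchor_stages: Tuple[Tuple[float, int], ...] = ((4.0, 200),)
    anchor_polish: int = 140
    # final centre-of-mass refinement: a short Nelder-Mead over x, y, z
    # alone on a sharp AA band (the position subspace is well-behaved,
    # and the joint stages leave sub-pixel position on the table)
    pos_refine_evals: int = 120
    pos_refine_sharp: float = 8.0

    def polish_scales(self, lower: np.ndarray,
                      upper: np.ndarray) -> np.ndarray:
        """Per-DOF polish steps, physical units mapped to scaled space."""
        phys = np.empty(17)
        for i, name in enumerate(POSE_FIELDS):
            unit = POSE_UNITS[name]
            phys[i] = (self.polish_pos_step if unit == "mm"
                       else self.polish_angle_step)
        return phys / (upper - lower)


@dataclass
class MRSConfig:
    """Anomaly detection + multi-random-start correction settings."""

    n_candidates: int = 10_000
    n_starts: int = 15
    backtrack_depth: int = 5
    psi_jump_threshold: float = 15.0     # deg per frame
    loss_jump_threshold: float = 0.5     # relative increase
    loss_floor: float = 0.012            # ignore loss jumps below this level
    loss_window: int = 5                 # frames of loss history compared
    rng_seed: int = 0
    enabled: bool = True
    restart_initial_step: float = 0.1
    restart_max_evals: int = 500

    def __post_init__(self):
        if self.n_starts > self.n_candidates:
            raise ValueError("n_starts must not exceed n_candidates")
        if self.psi_jump_threshold <= 0 or self.loss_jump_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class FrameRecord:
    """Per-frame tracking result."""

    index: int
    pose: PoseVector17
    loss: LossValue
    init_pose: PoseVector17
    anomaly: bool = False
    anomaly_reason: str = ""
    corrected: bool = False
    correction_failed: bool = False
    failed: bool = False
    n_evals: int = 0


class TrackRecord:
    """Ordered per-frame records of one tracked sequence."""

    def __init__(self, records: Optional[List[FrameRecord]] = None):
        self.records: List[FrameRecord] = records or []

    def append(self, rec: FrameRecord) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> FrameRecord:
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    def poses(self) -> List[PoseVector17]:
        return [r.pose for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per frame: pose fields, per-view and total loss, flags."""
        if not self.records:
            cols = (["frame"] + list(POSE_FIELDS)
                    + ["loss_total", "anomaly", "corrected", "failed",
                       "n_evals"])
            return pd.DataFrame(columns=cols)
        rows = []
        for r in self.records:
            row = {"frame": r.index}
            row.update({f: getattr(r.pose, f) for f in POSE_FIELDS})
            for cam, L in sorted(r.loss.per_view.items()):
                row[f"loss_{cam}"] = L
            row["loss_total"] = r.loss.total
            row["anomaly"] = int(r.anomaly)
            row["corrected"] = int(r.corrected)
            row["failed"] = int(r.failed)
            row["n_evals"] = r.n_evals
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# objective with per-frame caching


class MultiViewObjective:
    """Weighted multi-view loss over the scaled unit cube, one frame.

    Each call poses the model once, projects it into every camera, and
    accumulates the weighted normalized XOR against the cached masks.
    Computation is cropped to a region of interest around each view's
    mask (with a generous margin for model excursions); model area
    falling outside the ROI is still counted, via the exact hull areas,
    so the loss value is unaffected by the crop.

    Two evaluation modes share the geometry pipeline: ``loss_value``
    (exact pixel-centre binary XOR, the reported quantity) and
    ``smooth`` (the same XOR evaluated on an anti-aliased
    coverage raster, continuous in the pose — what the optimizer
    descends; the binary loss is a staircase whose flat treads stall
    derivative-free local search).
    """

    ROI_MARGIN = 32  # px beyond the mask bounding box

    def __init__(self, masks: Dict[str, SegMask], geometry: FlyGeometry,
                 cameras: Sequence[CameraModel], weights: ViewWeights,
                 lower: np.ndarray, upper: np.ndarray):
        self.masks = masks
        self.geometry = geometry
        self.cameras = cameras
        self.weights = weights
        self.lower = lower
        self.upper = upper
        self._mask_areas = {}
        self._roi = {}          # label -> (origin_i, origin_j, cropped mask)
        for cam in cameras:
            m = masks[cam.label].mask
            area = int(m.sum())
            if area == 0:
                raise ValueError(f"empty mask in view '{cam.label}'")
            self._mask_areas[cam.label] = area
            js, is_ = np.nonzero(m)
            i0 = max(is_.min() - self.ROI_MARGIN, 0)
            i1 = min(is_.max() + self.ROI_MARGIN, cam.image_width - 1)
            j0 = max(js.min() - self.ROI_MARGIN, 0)
            j1 = min(js.max() + self.ROI_MARGIN, cam.image_height - 1)
            crop = np.ascontiguousarray(m[j0:j1 + 1, i0:i1 + 1])
            self._roi[cam.label] = (i0, j0, crop,
                                    crop.astype(np.float32))

    def pose_of(self, u: np.ndarray) -> PoseVector17:
        return unscale_params(u, self.lower, self.upper)

    @staticmethod
    def _hull_area(hull: np.ndarray) -> float:
        x, y = hull[:, 0], hull[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def _part_hulls(self, mesh, cam) -> List[np.ndarray]:
        """Projected per-part convex hulls via the JIT monotone chain.

        A part whose projection is degenerate (collinear: apparent area
        zero) is skipped rather than rejected — a perfectly edge-on
        wing contributes no silhouette area.
        """
        body = mesh["body"]
        if "rod" in mesh:
            body = np.vstack([body, mesh["rod"]])
        hulls = []
        M = cam.M
        for verts in (body, mesh["wing_l"], mesh["wing_r"]):
            h = verts @ M[:, :3].T + M[:, 3]
            pts = h[:, :2] / h[:, 2:3]
            hull = convex_hull_ccw(pts)
            if len(hull) >= 3:
                hulls.append(hull)
        return hulls

    def _view_loss(self, hulls, cam, smooth: bool,
                   sharp: float = 1.0) -> float:
        i0, j0, m, mf = self._roi[cam.label]
        shape = m.shape
        model = np.zeros(shape, dtype=np.float32)
        outside = 0.0
        xmax, ymax = i0 + shape[1] - 0.5, j0 + shape[0] - 0.5
        for h in hulls:
            fully_in = ((h[:, 0] > i0 - 0.5) & (h[:, 0] < xmax) &
                        (h[:, 1] > j0 - 0.5) & (h[:, 1] < ymax)).all()
            if not fully_in:
                # model area beyond the ROI counts against the fit, or
                # hiding a wing off-screen would lower the loss
                clipped = clip_polygon_to_rect(h, i0 - 0.5, xmax,
                                               j0 - 0.5, ymax)
                outside += self._hull_area(h) - abs(polygon_area(clipped))
            add_convex_patch(model, h[:, 0], h[:, 1], i0, j0,
                             smooth, sharp)
        xor = abs_diff_sum(mf, model)
        return (xor + outside) / self._mask_areas[cam.label]

    def loss_value(self, u: np.ndarray) -> LossValue:
        """Exact binary XOR loss with per-view components."""
        mesh = pose_to_world_mesh(self.pose_of(u), self.geometry)
        per_view = {}
        total = 0.0
        for cam in self.cameras:
            L = self._view_loss(self._part_hulls(mesh, cam), cam,
                                smooth=False)
            per_view[cam.label] = L
            total += self.weights[cam.label] * L
        return LossValue(total=total, per_view=per_view)

    def smooth(self, u: np.ndarray, sharp: float = 1.0) -> float:
        """Anti-aliased XOR loss: the optimizer's objective.

        ``sharp`` narrows the anti-aliasing transition band to 1/sharp
        pixels, trading smoothness for a smaller sub-pixel bias.
        """
        mesh = pose_to_world_mesh(self.pose_of(u), self.geometry)
        total = 0.0
        for cam in self.cameras:
            total += self.weights[cam.label] * self._view_loss(
                self._part_hulls(mesh, cam), cam, smooth=True, sharp=sharp)
        return total

    def __call__(self, u: np.ndarray) -> float:
        return self.loss_value(u).total


def _compass_search(f: Callable[[np.ndarray], float], x0: np.ndarray,
                    free: np.ndarray, step0: float, min_step: float,
                    max_evals: int,
                    scale_vec: Optional[np.ndarray] = None,
                    ) -> Tuple[np.ndarray, float, int]:
    """Monotone bounded compass search on the unit cube.

    Polls +/-step along each free coordinate, greedily marches along an
    improving direction, halves the step after an unsuccessful sweep.
    ``scale_vec`` optionally rescales the step per coordinate (used to
    give every DOF a physically comparable poll step even when the
    scaled ranges differ wildly, e.g. a +/-2 deg roll window against a
    240 deg wing-pitch range).  Deterministic; the returned value never
    exceeds ``f(x0)``.
    """
    x = np.clip(x0, 0.0, 1.0).copy()
    fx = f(x)
    evals = 1
    step = step0
    dims = np.flatnonzero(free)
    scales = np.ones(len(x0)) if scale_vec is None else scale_vec
    while step >= min_step and evals < max_evals:
        improved = False
        for i in dims:
            if evals >= max_evals:
                break
            # poll both signs and take the better (a fixed greedy sign
            # order would bias flat directions systematically)
            best_ft, best_sgn = fx, 0.0
            for sgn in (1.0, -1.0):
                xi = float(np.clip(x[i] + sgn * step * scales[i], 0.0, 1.0))
                if xi == x[i]:
                    continue
                xt = x.copy()
                xt[i] = xi
                ft = f(xt)
                evals += 1
                if ft < best_ft - 1e-12:
                    best_ft, best_sgn = ft, sgn
                if evals >= max_evals:
                    break
            if best_sgn != 0.0:
                x = x.copy()
                x[i] = float(np.clip(x[i] + best_sgn * step * scales[i],
                                     0.0, 1.0))
                fx = best_ft
                improved = True
                while evals < max_evals:  # march while it helps
                    xi = float(np.clip(x[i] + best_sgn * step * scales[i],
                                       0.0, 1.0))
                    if xi == x[i]:
                        break
                    xt = x.copy()
                    xt[i] = xi
                    ft = f(xt)
                    evals += 1
                    if ft < fx - 1e-12:
                        x, fx = xt, ft
                    else:
                        break
        if not improved:
            step *= 0.5
    return x, fx, evals


def fit_frame(initial: PoseVector17, masks: Dict[str, SegMask],
              geometry: FlyGeometry, cameras: Sequence[CameraModel],
              weights: ViewWeights, bounds: ParamBounds,
              options: Optional[FitOptions] = None,
              frame_lo: Optional[np.ndarray] = None,
              frame_hi: Optional[np.ndarray] = None,
              ) -> Tuple[PoseVector17, LossValue, int]:
    """Fit one frame's pose by bounded compass search from ``initial``.

    The effective bounds are the frame windows around ``initial`` unless
    explicit ``frame_lo``/``frame_hi`` are given (the MRS correction
    passes the flagged frame's original windows so restarts obey the same
    constraints).  Returns (pose, loss, evaluation count); on optimizer
    failure the initial pose is returned with its own loss.
    """
    options = options or FitOptions()
    if frame_lo is None or frame_hi is None:
        frame_lo, frame_hi = bounds.frame_bounds(initial)
    obj = MultiViewObjective(masks, geometry, cameras, weights,
                             frame_lo, frame_hi)
    init_arr = np.clip(initial.to_array(), frame_lo, frame_hi)
    u0 = (init_arr - frame_lo) / (frame_hi - frame_lo)
    free = ~bounds.frozen
    try:
        # stage 1: coarse compass on the anti-aliased loss
        u, _, evals = _compass_search(obj.smooth, u0, free,
                                      options.initial_step,
                                      options.coarse_min_step,
                                      options.coarse_evals)
        # stage 2: Nelder-Mead with a progressively sharper AA band
        idx = np.flatnonzero(free)

        def nm_rounds(u, stages, evals):
            for sharp, budget in stages:
                def reduced(v, s=sharp):
                    w = u.copy()
                    w[idx] = v
                    return obj.smooth(np.clip(w, 0.0, 1.0), sharp=s)

                res = optimize.minimize(
                    reduced, u[idx], method="Nelder-Mead",
                    bounds=[(0.0, 1.0)] * len(idx),
                    options=dict(maxfev=budget, xatol=options.xatol,
                                 fatol=options.fatol, adaptive=True))
                u = u.copy()
                u[idx] = res.x
                evals += res.nfev
            return u, evals

        u, evals = nm_rounds(u, options.nm_stages, evals)
        # stage 3: fine compass polish on the exact binary loss with
        # physically comparable per-DOF steps
        scales = options.polish_scales(frame_lo, frame_hi)
        u_fin, f_fin, ev3 = _compass_search(
            obj, u, free, 1.0, 1.0 / options.polish_shrink,
            options.polish_evals, scale_vec=scales)
        evals += ev3
        # escalation: frames still fitting poorly get a finer AA ladder
        if f_fin > options.escalate_loss and options.escalate_stages:
            u2, evals = nm_rounds(u_fin, options.escalate_stages, evals)
            u2, f2, ev4 = _compass_search(
                obj, u2, free, 1.0, 1.0 / options.polish_shrink,
                options.polish_evals, scale_vec=scales)
            evals += ev4
            if f2 < f_fin:
                u_fin, f_fin = u2, f2
        # roll anchoring: keep roll at the initial condition unless the
        # fit's roll move bought a clear loss improvement
        ri = _IDX["roll"]
        roll_moved_deg = abs(u_fin[ri] - u0[ri]) * (frame_hi[ri] - frame_lo[ri])
        if (options.roll_anchor_margin > 0 and not bounds.frozen[ri]
                and roll_moved_deg > 0.15):
            frozen_roll = free.copy()
            frozen_roll[ri] = False
            ua = u_fin.copy()
            ua[ri] = u0[ri]
            saved_idx = idx
            idx = np.flatnonzero(frozen_roll)
            ua, evals = nm_rounds(ua, options.anchor_stages, evals)
            idx = saved_idx
            ua, fa, ev5 = _compass_search(
                obj, ua, frozen_roll, 1.0, 1.0 / options.polish_shrink,
                options.anchor_polish, scale_vec=scales)
            evals += ev5
            if fa < f_fin + options.roll_anchor_margin:
                u_fin, f_fin = ua, fa
        # position-only refinement on a sharp AA band
        if options.pos_refine_evals > 0:
            pos_free = np.zeros(17, dtype=bool)
            pos_free[:3] = free[:3]
            if pos_free.any():
                saved_idx = idx
                idx = np.flatnonzero(pos_free)
                up, evals = nm_rounds(
                    u_fin, ((options.pos_refine_sharp,
                             options.pos_refine_evals),), evals)
                idx = saved_idx
                fp = obj(up)
                evals += 1
                if fp <= f_fin:
                    u_fin, f_fin = up, fp
        # monotone-improvement guarantee against the initial condition
        if f_fin > obj(u0):
            u_fin = u0
        return obj.pose_of(u_fin), obj.loss_value(u_fin), evals
    except Exception as e:  # pragma: no cover - defensive
        warnings.warn(f"optimizer failure, keeping initial pose: {e}")
        return (obj.pose_of(u0), obj.loss_value(u0), 0)


# ---------------------------------------------------------------------------
# anomaly detection and MRS correction


def detect_anomaly(history: TrackRecord, current: Tuple[PoseVector17, LossValue],
                   config: MRSConfig) -> Tuple[bool, str]:
    """Flag a frame whose wing pitch or loss is discontinuous with the
    recent history.

    A jump in psi of either wing beyond ``psi_jump_threshold`` deg
    against the previous frame, or a loss exceeding the median of the
    last ``loss_window`` frames by more than ``loss_jump_threshold``
    (relative, evaluated only above ``loss_floor`` so noise around a
    near-zero loss does not trigger), marks the frame as suspected of
    the psi degeneracy.  The median reference also catches gradual
    creep into a wrong branch, which a frame-to-frame ratio misses.
    """
    if len(history) == 0:
        return False, ""
    prev = history[len(history) - 1]
    pose, lv = current
    for side in ("l", "r"):
        dpsi = abs(getattr(pose, f"psi_{side}")
                   - getattr(prev.pose, f"psi_{side}"))
        if dpsi > config.psi_jump_threshold:
            return True, f"psi_{side} jump of {dpsi:.1f} deg"
    recent = [history[k].loss.total
              for k in range(max(0, len(history) - config.loss_window),
                             len(history))
              if np.isfinite(history[k].loss.total)]
    if recent and lv.total > config.loss_floor:
        ref = float(np.median(recent))
        rel = (lv.total - ref) / max(ref, config.loss_floor)
        if rel > config.loss_jump_threshold:
            return True, f"loss jump of {100 * rel:.0f}% over recent median"
    return False, ""


def kmeanspp_starts(config: MRSConfig,
                    rng: Optional[np.random.Generator] = None,
                    dim: int = 17) -> np.ndarray:
    """Spread-out restart points in the unit cube via k-means++ seeding.

    ``n_candidates`` points are sampled uniformly; the first start is
    picked uniformly among them, and each subsequent start is drawn with
    probability proportional to its distance from the nearest already
    chosen start.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    cand = rng.random((config.n_candidates, dim))
    first = int(rng.integers(config.n_candidates))
    chosen = [cand[first]]
    d = np.linalg.norm(cand - chosen[0], axis=1)
    for _ in range(config.n_starts - 1):
        p = d / d.sum()
        nxt = int(rng.choice(config.n_candidates, p=p))
        chosen.append(cand[nxt])
        d = np.minimum(d, np.linalg.norm(cand - cand[nxt], axis=1))
    return np.array(chosen)


@dataclass
class TrackContext:
    """Everything needed to (re-)fit any frame of a sequence."""

    geometry: FlyGeometry
    cameras: Sequence[CameraModel]
    weights: ViewWeights
    bounds: ParamBounds
    fit_options: FitOptions
    masks: List[Dict[str, SegMask]]     # per frame, keyed by camera label


def correct_frames(records: TrackRecord, flagged: int, ctx: TrackContext,
                   config: MRSConfig) -> TrackRecord:
    """MRS correction of a flagged frame plus backtracking re-fit.

    The flagged frame is re-fitted from ``n_starts`` k-means++-seeded
    random points inside its original per-frame bounds (frozen
    coordinates keep their initial values); the lowest-loss result is
    kept only if it improves on the original fit.  Then up to
    ``backtrack_depth`` preceding frames are re-fitted backwards, each
    initialized from its corrected neighbour, again keeping a re-fit only
    if it lowers that frame's loss.  Records are modified in place.
    """
    rec = records[flagged]
    lo, hi = ctx.bounds.frame_bounds(rec.init_pose)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, flagged]))
    starts = kmeanspp_starts(config, rng=rng)
    init_arr = np.clip(rec.init_pose.to_array(), lo, hi)
    # restarts start far from the optimum: larger coarse steps, leaner
    # refinement stages sized by the restart budget
    nm1 = max(100, int(0.6 * config.restart_max_evals))
    nm2 = max(60, int(0.3 * config.restart_max_evals))
    restart_opts = replace(ctx.fit_options,
                           initial_step=config.restart_initial_step,
                           coarse_evals=150,
                           nm_stages=((1.0, nm1), (4.0, nm2)),
                           polish_evals=80,
                           escalate_stages=(),
                           anchor_stages=((4.0, 120),),
                           anchor_polish=80,
                           pos_refine_evals=0)
    best_pose, best_loss = rec.pose, rec.loss
    improved = False
    # deterministic wing-pitch branch candidates first: the degeneracy
    # gap is ~30 deg, so hopping psi of either wing by one gap from the
    # current fit lands in the competing branch directly
    gap = 30.0
    branch_offsets = [(gap, 0.0), (-gap, 0.0), (0.0, gap), (0.0, -gap),
                      (gap, gap), (-gap, -gap)]
    start_arrs = []
    for dl, dr in branch_offsets:
        arr = rec.pose.to_array().copy()
        arr[_IDX["psi_l"]] += dl
        arr[_IDX["psi_r"]] += dr
        # the roll of the suspect fit is itself unreliable: restart the
        # branch candidates from the frame's initial-condition roll
        arr[_IDX["roll"]] = init_arr[_IDX["roll"]]
        # branch candidates start near a converged fit: regular settings
        start_arrs.append((np.clip(arr, lo, hi), ctx.fit_options))
    for u in starts:
        arr = lo + u * (hi - lo)
        arr[ctx.bounds.frozen] = init_arr[ctx.bounds.frozen]
        start_arrs.append((arr, restart_opts))
    candidates = [(rec.pose, rec.loss)]
    resolved = min(0.6 * rec.loss.total, 5e-3)
    for arr, opts in start_arrs:
        start = PoseVector17.from_array(arr)
        pose, lv, _ = fit_frame(start, ctx.masks[flagged], ctx.geometry,
                                ctx.cameras, ctx.weights, ctx.bounds,
                                options=opts,
                                frame_lo=lo, frame_hi=hi)
        candidates.append((pose, lv))
        if lv.total <= resolved:
            break   # a start clearly resolved the frame; stop restarting
    for pose, lv in candidates[1:]:
        if lv.total < best_loss.total - 1e-12:
            best_pose, best_loss, improved = pose, lv, True
    if improved:
        # polish the winning restart at the regular fit settings
        pose, lv, ne = fit_frame(best_pose, ctx.masks[flagged], ctx.geometry,
                                 ctx.cameras, ctx.weights, ctx.bounds,
                                 options=ctx.fit_options,
                                 frame_lo=lo, frame_hi=hi)
        if lv.total <= best_loss.total:
            best_pose, best_loss = pose, lv
        rec.pose, rec.loss, rec.corrected = best_pose, best_loss, True
    else:
        rec.correction_failed = True
        warnings.warn(f"MRS correction did not improve frame {flagged}")
    # backtracking re-fit of preceding suspected frames: a predecessor
    # is suspected when its wing pitch disagrees with its corrected
    # neighbour by more than half the degeneracy gap, or its loss is
    # elevated; the walk stops at the first unsuspected frame
    neighbour = records[flagged].pose
    lower_frame = max(flagged - config.backtrack_depth, 0)
    for t in range(flagged - 1, lower_frame - 1, -1):
        prev_rec = records[t]
        dpsi = max(abs(prev_rec.pose.psi_l - neighbour.psi_l),
                   abs(prev_rec.pose.psi_r - neighbour.psi_r))
        if (dpsi <= config.psi_jump_threshold
                and prev_rec.loss.total <= config.loss_floor):
            break
        pose, lv, _ = fit_frame(neighbour, ctx.masks[t], ctx.geometry,
                                ctx.cameras, ctx.weights, ctx.bounds,
                                options=ctx.fit_options)
        if lv.total < prev_rec.loss.total - 1e-12:
            prev_rec.pose, prev_rec.loss = pose, lv
            prev_rec.corrected = True
        neighbour = prev_rec.pose
    return records


# ---------------------------------------------------------------------------
# full sequence


def track_sequence(frames_per_camera: Dict[str, List[Frame]],
                   cameras: Sequence[CameraModel],
                   geometry: FlyGeometry,
                   initial_pose: PoseVector17,
                   bounds: Optional[ParamBounds] = None,
                   config: Optional[MRSConfig] = None,
                   fit_options: Optional[FitOptions] = None,
                   backgrounds: Optional[Dict[str, Frame]] = None,
                   masks: Optional[List[Dict[str, SegMask]]] = None,
                   init_offsets: Optional[Dict[int, np.ndarray]] = None,
                   min_component_px: int = 8,
                   ) -> TrackRecord:
    """Track a whole multi-view sequence.

    The background is estimated once per camera (first/last frame
    maximum) unless explicit ``backgrounds`` or precomputed ``masks`` are
    given; view weights are computed once from the initial pose and then
    frozen.  Frames are processed in order: segment, fit (initialized
    from the previous result), detect anomalies and, when flagged,
    correct via MRS with backtracking.  ``init_offsets`` optionally adds
    a perturbation (length-17 array) to selected frames' initial
    conditions — used to provoke the psi degeneracy in validation.  No
    smoothing or filtering is applied to the outputs.
    """
    bounds = bounds or ParamBounds.default()
    config = config or MRSConfig()
    fit_options = fit_options or FitOptions()
    init_offsets = init_offsets or {}

    labels = [cam.label for cam in cameras]
    n_frames = len(next(iter(frames_per_camera.values())))
    if masks is None:
        masks = []
        bgs = {}
        for lab in labels:
            seq = frames_per_camera[lab]
            if backgrounds is not None:
                bgs[lab] = backgrounds[lab]
            else:
                bgs[lab] = estimate_background(seq[0], seq[-1])
        for t in range(n_frames):
            masks.append({lab: segment_frame(frames_per_camera[lab][t],
                                             bgs[lab],
                                             min_component_px=min_component_px)
                          for lab in labels})
    weights = view_weights(initial_pose, geometry, cameras)
    ctx = TrackContext(geometry=geometry, cameras=cameras, weights=weights,
                       bounds=bounds, fit_options=fit_options, masks=masks)
    records = TrackRecord()
    prev = initial_pose
    for t in range(len(masks)):
        init = prev
        if t in init_offsets:
            arr = np.clip(init.to_array() + np.asarray(init_offsets[t]),
                          bounds.lower, bounds.upper)
            init = PoseVector17.from_array(arr)
        if any(masks[t][lab].empty for lab in labels):
            lv = LossValue(total=float("nan"), per_view={})
            records.append(FrameRecord(index=t, pose=init, loss=lv,
                                       init_pose=init, failed=True))
            continue
        pose, lv, ne = fit_frame(init, masks[t], geometry, cameras,
                                 weights, bounds, options=fit_options)
        if (config.enabled and t >= 2 and not records[t - 1].failed
                and not records[t - 2].failed
                and lv.total > fit_options.retry_loss):
            # suspect fit: re-fit from a constant-velocity extrapolation
            # of the two previous results and keep the better of the two
            ex = np.clip(2 * records[t - 1].pose.to_array()
                         - records[t - 2].pose.to_array(),
                         bounds.lower, bounds.upper)
            extrap = PoseVector17.from_array(ex)
            pose2, lv2, ne2 = fit_frame(extrap, masks[t], geometry, cameras,
                                        weights, bounds, options=fit_options)
            ne += ne2
            if lv2.total < lv.total:
                pose, lv, init = pose2, lv2, extrap
        flag, reason = detect_anomaly(records, (pose, lv), config)
        records.append(FrameRecord(index=t, pose=pose, loss=lv,
                                   init_pose=init, anomaly=flag,
                                   anomaly_reason=reason, n_evals=ne))
        if flag and config.enabled:
            correct_frames(records, t, ctx, config)
        prev = records[t].pose
    return records
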