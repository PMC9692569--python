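"""Silhouette-XOR loss: single view, view weights, multi-view objective.

The disagreement between the model at pose ``p`` and one segmented frame
is the non-overlapping (XOR) area between the rasterized model silhouette
and the binary fly mask, normalized by the mask area::

    L(p) = Area(mask XOR model(p)) / Area(mask)

Normalization compensates for the different apparent fly sizes across
views.  The multi-view objective is a weighted mean of the single-view
losses; views that see more of the wings (a larger fraction of wing area
unoccluded by the body at the initial pose) receive a larger weight, and
the weights are computed once from the initial condition and then frozen
for the whole sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .fly_model import FlyGeometry, PoseVector17
from .projection import CameraModel, rasterize_parts, silhouette_hulls
from .segmentation import SegMask


@dataclass
class ViewWeights:
    """Per-camera non-negative weights, normalized to sum to one."""

    weights: Dict[str, float]

    def __post_init__(self):
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("view weights must be non-negative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("view weights must not all be zero")
        self.weights = {k: float(v / total) for k, v in self.weights.items()}

    def __getitem__(self, label: str) -> float:
        return self.weights[label]


@dataclass
class LossValue:
    """Weighted multi-view loss with its per-view components."""

    total: float
    per_view: Dict[str, float]

    def __float__(self) -> float:
        return self.total


def xor_loss_from_rasters(mask: np.ndarray, model: np.ndarray) -> float:
    """Normalized XOR between two binary rasters: |mask ^ model| / |mask|."""
    mask_area = int(mask.sum())
    if mask_area == 0:
        raise ValueError("empty mask: normalized XOR loss is undefined")
    model_area = int(model.sum())
    inter = int(np.logical_and(mask, model).sum())
    return (mask_area + model_area - 2 * inter) / mask_area


def single_view_loss(mask: SegMask, pose: PoseVector17,
                     geometry: FlyGeometry, camera: CameraModel) -> float:
    """Normalized silhouette-XOR loss of one pose against one view's mask."""
    model = rasterize_parts(silhouette_hulls(pose, geometry, camera), camera)
    return xor_loss_from_rasters(mask.mask, model)


def view_weights(initial_pose: PoseVector17, geometry: FlyGeometry,
                 cameras: Sequence[CameraModel]) -> ViewWeights:
    """Per-view weights from the wing-occlusion geometry at the initial pose.

    For each camera the model is rendered part-wise at the initial pose;
    the raw weight is the fraction of wing pixels (both wings combined)
    that fall outside the body raster.  Weights are normalized to sum to
    one.  If the wings are fully occluded in every view, uniform weights
    are returned with a warning.
    """
    raw = {}
    for cam in cameras:
        hulls = silhouette_hulls(initial_pose, geometry, cam)
        body = rasterize_parts(hulls, cam, parts=["body"])
        wings = rasterize_parts(hulls, cam, parts=["wing_l", "wing_r"])
        wing_px = int(wings.sum())
        if wing_px == 0:
            raw[cam.label] = 0.0
        else:
            unoccluded = int(np.logical_and(wings, ~body).sum())
            raw[cam.label] = unoccluded / wing_px
    if sum(raw.values()) <= 0:
        warnings.warn("wings fully occluded in every view; "
                      "falling back to uniform view weights")
        raw = {cam.label: 1.0 for cam in cameras}
    return ViewWeights(raw)


def multi_view_loss(pose: PoseVector17, masks: Dict[str, SegMask],
                    geometry: FlyGeometry, cameras: Sequence[CameraModel],
                    weights: ViewWeights) -> LossValue:
    """Weighted mean of the single-view losses over all cameras."""
    per_view = {}
    total = 0.0
    for cam in cameras:
        L = single_view_loss(masks[cam.label], pose, geometry, cam)
        per_view[cam.label] = L
        total += weights[cam.label] * L
    return LossValue(total=total, per_view=per_view)
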