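"""Back-lit frame segmentation: background model, contrast boost, Otsu.

Back-lighting makes the fly darker than the background, so the background
is estimated as the pixel-wise maximum of the first and last frames (valid
when the fly occupies different positions in the two).  A frame is
segmented by subtracting it from the background, boosting contrast with
the power transform ``p -> 1 - (1 - p)**6`` (which brightens the
translucent wings and makes the intensity histogram bimodal), and
thresholding with Otsu's method on a 256-bin histogram.  Tiny connected
components are dropped as noise specks; genuine fly fragments (a nearly
edge-on wing can detach from the body blob in the raster) are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects


@dataclass
class Frame:
    """One grayscale frame, values in [0, 1]."""

    image: np.ndarray
    index: int = 0
    camera_label: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("frame must be a 2D grayscale image")
        if self.image.min() < -1e-9 or self.image.max() > 1 + 1e-9:
            raise ValueError("frame values must lie in [0, 1]")


@dataclass
class SegMask:
    """Binary fly mask for one frame."""

    mask: np.ndarray
    camera_label: str = ""
    index: int = 0
    empty: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


def estimate_background(first: Frame, last: Frame) -> Frame:
    """Pixel-wise maximum of the first and last frames.

    Assumes (caller-verified) that the fly does not overlap itself between
    the two frames, so the dark fly is removed from every pixel.
    """
    if first.image.shape != last.image.shape:
        raise ValueError("background frames must have the same size")
    if first.camera_label != last.camera_label:
        raise ValueError("background frames must come from the same camera")
    return Frame(np.maximum(first.image, last.image),
                 index=-1, camera_label=first.camera_label)


def enhance_contrast(diff: np.ndarray) -> np.ndarray:
    """Power transform ``p -> 1 - (1 - p)**6`` on values in [0, 1].

    Strictly increasing on (0, 1) with fixed points 0 and 1; pushes the
    faint wing pixels of a background-subtracted image toward 1.
    """
    return 1.0 - (1.0 - np.asarray(diff, dtype=float)) ** 6


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu threshold of an image in [0, 1], on a 256-bin histogram."""
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("Otsu threshold is undefined for a constant image")
    return float(threshold_otsu(img, nbins=256))


def segment_frame(frame: Frame, background: Frame,
                  min_component_px: int = 8) -> SegMask:
    """Binary fly mask of one frame given the background model.

    Pipeline: clipped difference (background - frame), power transform,
    Otsu threshold (mask = transformed >= threshold), then drop connected
    components smaller than ``min_component_px`` (salt noise; real fly
    parts — even a nearly edge-on wing, which can rasterize as a thin
    sliver detached from the body blob — stay above this size).  An
    (almost) empty foreground is flagged on the returned mask rather
    than raised.
    """
    if frame.image.shape != background.image.shape:
        raise ValueError("frame and background sizes differ")
    diff = np.clip(background.image - frame.image, 0.0, 1.0)
    enhanced = enhance_contrast(diff)
    if np.ptp(enhanced) == 0:
        return SegMask(np.zeros_like(diff, dtype=bool),
                       camera_label=frame.camera_label, index=frame.index,
                       empty=True)
    thr = otsu_threshold(enhanced)
    mask = enhanced >= thr
    if min_component_px > 1 and mask.any():
        # removes components of size <= max_size, i.e. < min_component_px
        mask = remove_small_objects(mask, max_size=min_component_px - 1,
                                    connectivity=2)
    empty = not mask.any()
    if empty:
        warnings.warn(f"empty foreground in frame {frame.index} "
                      f"({frame.camera_label})")
    return SegMask(mask, camera_label=frame.camera_label, index=frame.index,
                   empty=empty)
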