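"""Saliency-driven object localization and its evaluation protocol.

The localization stage turns a saliency map into a fixed-size square crop
centered on the salient object: threshold the map (default 0.3), refine
the thresholded mask with three rounds of GrabCut, take the tight box of
the largest connected foreground component, extend it to a square and
crop/resize to 256 x 256.  A predicted box counts as a correct
localization when (1) its area differs from the ground-truth box area by
less than 20% of the latter and (2) at least 80% of its pixels lie inside
the ground-truth box.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .grabcut import DegenerateInitError, grabcut_refine
from .saliency import SaliencyConfig, SaliencyMap, compute_saliency

__all__ = [
    "BoundingBox",
    "LocalizationConfig",
    "LocalizationResult",
    "threshold_saliency",
    "largest_component_box",
    "extend_to_square",
    "crop_and_resize",
    "localize",
    "is_correct_localization",
    "localization_accuracy",
    "accuracy_curve",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based, half-open pixel coordinates.

    The box spans columns ``x0 <= x < x1`` and rows ``y0 <= y < y1``.
    """

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x1, other.x1) - max(self.x0, other.x0)
        ih = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(iw, 0) * max(ih, 0)


@dataclass(frozen=True)
class LocalizationConfig:
    threshold: float = 0.3
    grabcut_iters: int = 3
    crop_size: int = 256
    seed: int = 0
    saliency: SaliencyConfig = SaliencyConfig()

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.grabcut_iters < 1:
            raise ValueError("grabcut_iters must be >= 1")


@dataclass(frozen=True)
class LocalizationResult:
    mask: np.ndarray
    tight_box: BoundingBox
    square_box: BoundingBox
    crop: np.ndarray
    fallback_used: bool


def threshold_saliency(smap: SaliencyMap, th: float) -> np.ndarray:
    """Binary mask of pixels with saliency >= th."""
    if not (0.0 < th < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return smap.pixel_raster >= th


def largest_component_box(mask: np.ndarray) -> BoundingBox:
    """Tight box of the largest 8-connected foreground component.

    Ties between equally large components are broken in favor of the one
    whose bounding-box top-left corner comes first in row-major order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no components")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    best = sizes.max()
    slices = ndimage.find_objects(labels)
    candidates = [
        (sl[0].start, sl[1].start, i) for i, sl in enumerate(slices) if sizes[i] == best
    ]
    candidates.sort()
    sl = slices[candidates[0][2]]
    return BoundingBox(x0=sl[1].start, y0=sl[0].start, x1=sl[1].stop, y1=sl[0].stop)


def _extend_axis(lo: int, hi: int, side: int, limit: int) -> tuple[int, int]:
    """Grow [lo, hi) symmetrically to length ``side``, shifted inside [0, limit)."""
    grow = side - (hi - lo)
    lo -= grow // 2
    hi += grow - grow // 2
    if lo < 0:
        hi -= lo
        lo = 0
    if hi > limit:
        lo -= hi - limit
        hi = limit
    lo = max(lo, 0)
    return lo, hi


def extend_to_square(box: BoundingBox, width: int, height: int) -> BoundingBox:
    """Extend a box to a square of side max(w, h), kept inside the image.

    The short axis grows symmetrically about the box center; if the
    square would cross an image edge it is shifted inward, and if the
    side exceeds the image's short dimension the square is clamped to
    that dimension (then containing the centrally-cropped box).
    """
    side = max(box.width, box.height)
    side = min(side, width, height)
    x0, x1 = _extend_axis(box.x0, box.x1, side, width)
    y0, y1 = _extend_axis(box.y0, box.y1, side, height)
    return BoundingBox(x0=x0, y0=y0, x1=x1, y1=y1)


def crop_and_resize(image: np.ndarray, square: BoundingBox, size: int = 256) -> np.ndarray:
    """Bilinear resize of the cropped square region to ``size x size``."""
    crop = image[square.y0 : square.y1, square.x0 : square.x1]
    if crop.shape[0] == size and crop.shape[1] == size:
        return crop.copy()
    out = resize(crop.astype(np.float64), (size, size), order=1, anti_aliasing=False)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def localize(image: np.ndarray, config: LocalizationConfig | None = None) -> LocalizationResult:
    """Full localization pipeline for one image.

    Falls back gracefully: if GrabCut cannot be initialized (all-zero or
    all-one thresholded map) the thresholded mask's largest component is
    used directly, and if that too is empty the whole-image square is
    returned with ``fallback_used`` set.
    """
    config = config or LocalizationConfig()
    image = np.asarray(image)
    h, w = image.shape[:2]
    smap = compute_saliency(image, config.saliency)
    init_mask = threshold_saliency(smap, config.threshold)
    fallback = False
    try:
        mask = grabcut_refine(image, init_mask, iters=config.grabcut_iters, seed=config.seed)
        if not mask.any():
            mask = init_mask
            fallback = True
    except DegenerateInitError:
        mask = init_mask
        fallback = True
    if mask.any():
        tight = largest_component_box(mask)
    else:
        tight = BoundingBox(0, 0, w, h)
        fallback = True
    square = extend_to_square(tight, width=w, height=h)
    crop = crop_and_resize(image, square, config.crop_size)
    return LocalizationResult(
        mask=mask, tight_box=tight, square_box=square, crop=crop, fallback_used=fallback
    )


def is_correct_localization(pred: BoundingBox, gt: BoundingBox) -> bool:
    """Two-restriction correctness criterion on a predicted box.

    (1) |A_pred - A_gt| < 0.2 * A_gt, and
    (2) at least 80% of predicted-box pixels lie inside the ground-truth
        box.  Note the predicate is deliberately asymmetric in (2).
    """
    area_ok = abs(pred.area - gt.area) < 0.2 * gt.area
    overlap_ok = pred.intersection_area(gt) / pred.area >= 0.8
    return bool(area_ok and overlap_ok)


def localization_accuracy(scenes, config: LocalizationConfig | None = None) -> float:
    """Fraction of scenes whose predicted tight box is a correct localization.

    ``scenes`` is a sequence of objects with ``image`` and ``gt_box``
    attributes (e.g. :class:`pestvision.fixtures.SyntheticScene`).
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("scene list must be non-empty")
    config = config or LocalizationConfig()
    hits = 0
    for scene in scenes:
        result = localize(scene.image, config)
        hits += is_correct_localization(result.tight_box, scene.gt_box)
    return hits / len(scenes)


def accuracy_curve(scenes, thresholds, config: LocalizationConfig | None = None) -> list[tuple[float, float]]:
    """Localization accuracy as a function of the saliency threshold."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    config = config or LocalizationConfig()
    return [
        (float(th), localization_accuracy(scenes, replace(config, threshold=float(th))))
        for th in thresholds
    ]
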