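"""Seeded synthetic imagery for exercising the localization and
classification stages without external data.

Localization fixtures emulate the situation the saliency detector is
built for: a single high-contrast "insect-like" object (a filled ellipse
with a few protruding leg/antenna-like appendages) sitting on a muted,
value-noise textured background with optional blurred clutter blobs.
The generator records the exact object mask and tight ground-truth box,
so end-to-end localization accuracy can be scored.

Classification fixtures are small multi-class datasets where each class
is a distinct (shape family, hue band) combination rendered with random
pose/scale jitter — separable, but not trivially so, by a small CNN.

Everything is driven by :class:`numpy.random.Generator` seeds; identical
arguments give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb

from .localization import BoundingBox

__all__ = [
    "SyntheticScene",
    "LabeledDataset",
    "make_localization_fixture",
    "make_localization_suite",
    "make_classification_dataset",
    "write_scene",
    "write_annotations",
]

DIFFICULTY_PRESETS = {
    # contrast range, clutter range, bokeh blur sigma range, clutter strength
    "easy": {"contrast": (0.75, 1.0), "clutter": (0.0, 0.2), "bokeh": (1.0, 2.0), "strength": 0.18},
    "hard": {"contrast": (0.45, 0.8), "clutter": (0.7, 1.0), "bokeh": (5.0, 9.0), "strength": 0.55},
}


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray          # H x W x 3 uint8
    gt_box: BoundingBox
    object_mask: np.ndarray    # boolean raster of true object pixels
    params: dict


@dataclass(frozen=True)
class LabeledDataset:
    images: np.ndarray   # N x H x W x 3 uint8
    labels: np.ndarray   # N ints in 0..n_classes-1
    split: np.ndarray    # N strings, "train" or "val"
    n_classes: int

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == tag
        return self.images[sel], self.labels[sel]


def _value_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Smooth zero-mean unit-ish noise field."""
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    s = n.std()
    return n / s if s > 0 else n


_RGB_CORNERS = np.array(
    [[r, g, b] for r in (0.0, 1.0) for g in (0.0, 1.0) for b in (0.0, 1.0)]
)


def _object_color(base: np.ndarray, contrast: float) -> np.ndarray:
    """A color at (approximately) `contrast` normalized-RGB distance from base."""
    d = np.linalg.norm(_RGB_CORNERS - base, axis=1)
    corner = _RGB_CORNERS[int(np.argmax(d))]
    u = (corner - base) / np.linalg.norm(corner - base)
    return np.clip(base + contrast * u, 0.0, 1.0)


def _stamp_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Mark a thick line segment in a boolean raster (in place)."""
    h, w = mask.shape
    length = float(np.linalg.norm(p1 - p0))
    n_steps = max(int(length * 2), 1)
    rr = int(np.ceil(radius))
    for t in np.linspace(0.0, 1.0, n_steps + 1):
        cy, cx = p0 + t * (p1 - p0)
        y0, y1 = max(int(cy) - rr, 0), min(int(cy) + rr + 2, h)
        x0, x1 = max(int(cx) - rr, 0), min(int(cx) + rr + 2, w)
        if y0 >= y1 or x0 >= x1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2


def make_localization_fixture(
    height: int,
    width: int,
    contrast: float,
    clutter: float,
    seed: int,
    *,
    bokeh_sigma: float = 2.0,
    clutter_strength: float = 0.25,
) -> SyntheticScene:
    """One synthetic scene: insect-like object on a muted textured background.

    Parameters
    ----------
    height, width:
        Image size in pixels, both >= 64.
    contrast:
        Target object/background mean-color separation, as Euclidean
        distance in normalized RGB (image max is sqrt(3)).
    clutter:
        Amount of distractor blobs in [0, 1].
    seed:
        Scene seed; identical arguments give byte-identical scenes.
    bokeh_sigma:
        Gaussian blur width applied to the clutter blobs (large values
        emulate background bokeh).
    clutter_strength:
        Color amplitude of the clutter blobs relative to the background.
    """
    if height < 64 or width < 64:
        raise ValueError("image dimensions must be >= 64")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    rng = np.random.default_rng(seed)
    mind = min(height, width)

    # --- background: dark muted green-brown + value-noise texture
    base = np.array([0.33, 0.38, 0.27]) + rng.uniform(-0.03, 0.03, 3)
    img = np.empty((height, width, 3))
    tex = _value_noise(rng, (height, width), sigma=5.0)
    for c in range(3):
        img[..., c] = base[c] + 0.030 * tex + 0.012 * _value_noise(rng, (height, width), sigma=3.0)

    # --- clutter: blurred distractor blobs
    n_blobs = int(round(clutter * 8))
    if n_blobs > 0:
        layer = np.zeros((height, width, 3))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            r = rng.uniform(0.04, 0.11) * mind
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            amp = rng.uniform(0.4, 1.0) * clutter_strength
            ys, xs = np.mgrid[0:height, 0:width]
            blob = ((ys - cy) ** 2 + (xs - cx) ** 2 <= r**2).astype(float)
            layer += blob[..., None] * direction[None, None, :] * amp
        layer = ndimage.gaussian_filter(layer, sigma=(bokeh_sigma, bokeh_sigma, 0))
        img += layer

    # --- object: tilted ellipse plus 2-6 appendages
    obj_color = _object_color(base, contrast)
    a = rng.uniform(0.10, 0.15) * mind
    aspect = np.exp(rng.uniform(np.log(0.35), np.log(2.8)))
    rx = a * np.sqrt(aspect)
    ry = a / np.sqrt(aspect)
    theta = rng.uniform(-0.3, 0.3)
    cy = rng.uniform(0.35, 0.65) * height
    cx = rng.uniform(0.35, 0.65) * width
    ys, xs = np.mgrid[0:height, 0:width]
    xr = (xs - cx) * np.cos(theta) + (ys - cy) * np.sin(theta)
    yr = -(xs - cx) * np.sin(theta) + (ys - cy) * np.cos(theta)
    mask = (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0

    n_app = int(rng.integers(2, 7))
    rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    for _ in range(n_app):
        t = rng.uniform(0, 2 * np.pi)
        boundary_local = np.array([ry * np.sin(t), rx * np.cos(t)])  # (y, x) in ellipse frame
        outward = boundary_local / np.linalg.norm(boundary_local)
        length = rng.uniform(0.25, 0.5) * a
        p0_local = boundary_local
        p1_local = boundary_local + outward * length
        p0 = np.array([cy, cx]) + rot @ p0_local
        p1 = np.array([cy, cx]) + rot @ p1_local
        _stamp_segment(mask, p0, p1, radius=1.3)

    jitter = rng.normal(0.0, 0.01, size=(int(mask.sum()), 3))
    img[mask] = obj_color[None, :] + jitter
    img = np.clip(img, 0.0, 1.0)
    image = np.round(img * 255.0).astype(np.uint8)

    ys_o, xs_o = np.nonzero(mask)
    gt_box = BoundingBox(
        x0=int(xs_o.min()), y0=int(ys_o.min()), x1=int(xs_o.max()) + 1, y1=int(ys_o.max()) + 1
    )
    frac = gt_box.area / (height * width)
    assert 0.01 <= frac <= 0.5, f"gt box covers {frac:.1%} of the image"
    params = {
        "object_color": obj_color.tolist(),
        "contrast": float(contrast),
        "scale_fraction": float(a / mind),
        "clutter": float(clutter),
        "blur_radius": float(bokeh_sigma),
        "seed": int(seed),
    }
    return SyntheticScene(image=image, gt_box=gt_box, object_mask=mask, params=params)


def make_localization_suite(
    n: int,
    seed: int,
    difficulty: str = "easy",
    height: int = 160,
    width: int = 160,
) -> list[SyntheticScene]:
    """A suite of ``n`` scenes with per-scene child seeds ``seed + index``.

    ``difficulty="easy"`` gives high-contrast objects on lightly cluttered
    backgrounds; ``"hard"`` lowers the contrast and adds strongly blurred
    high-amplitude clutter (background bokeh), the regime in which
    saliency thresholding is known to break down.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if difficulty not in DIFFICULTY_PRESETS:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    preset = DIFFICULTY_PRESETS[difficulty]
    scenes = []
    for i in range(n):
        child = seed + i
        draw = np.random.default_rng((child, 0x5EED))
        contrast = draw.uniform(*preset["contrast"])
        clutter = draw.uniform(*preset["clutter"])
        bokeh = draw.uniform(*preset["bokeh"])
        scenes.append(
            make_localization_fixture(
                height,
                width,
                contrast=contrast,
                clutter=clutter,
                seed=child,
                bokeh_sigma=bokeh,
                clutter_strength=preset["strength"],
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# classification fixtures

def _shape_mask(kind: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Rotated, jittered mask of one of six shape families."""
    s = rng.uniform(0.26, 0.38) * size
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    theta = rng.uniform(0, 2 * np.pi)
    ys, xs = np.mgrid[0:size, 0:size]
    xr = (xs - cx) * np.cos(theta) + (ys - cy) * np.sin(theta)
    yr = -(xs - cx) * np.sin(theta) + (ys - cy) * np.cos(theta)
    if kind == 0:  # ellipse
        return (xr / s) ** 2 + (yr / (0.55 * s)) ** 2 <= 1.0
    if kind == 1:  # rectangle
        return (np.abs(xr) <= s) & (np.abs(yr) <= 0.5 * s)
    if kind == 2:  # triangle (half-planes)
        return (yr >= -0.5 * s) & (yr <= 2.0 * (xr + s)) & (yr <= -2.0 * (xr - s))
    if kind == 3:  # cross
        return ((np.abs(xr) <= s) & (np.abs(yr) <= 0.33 * s)) | (
            (np.abs(yr) <= s) & (np.abs(xr) <= 0.33 * s)
        )
    if kind == 4:  # ring
        rr = np.sqrt(xr**2 + yr**2)
        return (rr <= s) & (rr >= 0.55 * s)
    # crescent: disk minus offset disk
    rr = np.sqrt(xr**2 + yr**2)
    rr2 = np.sqrt((xr - 0.5 * s) ** 2 + yr**2)
    return (rr <= s) & (rr2 >= 0.75 * s)


_HUE_BANDS = (0.00, 0.33, 0.62, 0.12)  # red, green, blue, yellow
_N_SHAPES = 6


def make_classification_dataset(
    n_classes: int,
    n_per_class: int,
    image_size: int = 64,
    seed: int = 0,
    val_fraction: float = 0.25,
) -> LabeledDataset:
    """Labeled multi-class shape dataset with a train/val split.

    Class ``i`` is the (shape family ``i mod 6``, hue band ``i mod 4``)
    combination — distinct for every ``i < 12`` — rendered with random
    pose/scale jitter over a gray textured background.
    """
    if not (2 <= n_classes <= 12):
        raise ValueError("n_classes must lie in 2..12")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    images, labels, split = [], [], []
    n_val = max(int(round(val_fraction * n_per_class)), 1)
    for cls in range(n_classes):
        shape_kind = cls % _N_SHAPES
        hue = _HUE_BANDS[cls % len(_HUE_BANDS)]
        for j in range(n_per_class):
            bg = 0.5 + 0.05 * _value_noise(rng, (image_size, image_size), sigma=3.0)
            img = np.repeat(bg[..., None], 3, axis=2) + rng.uniform(-0.02, 0.02, 3)
            mask = _shape_mask(shape_kind, image_size, rng)
            hsv = np.array(
                [
                    (hue + rng.uniform(-0.03, 0.03)) % 1.0,
                    rng.uniform(0.65, 0.85),
                    rng.uniform(0.65, 0.85),
                ]
            )
            color = hsv2rgb(hsv.reshape(1, 1, 3)).reshape(3)
            img[mask] = color + rng.normal(0.0, 0.015, (int(mask.sum()), 3))
            images.append(np.round(np.clip(img, 0, 1) * 255).astype(np.uint8))
            labels.append(cls)
            split.append("val" if j < n_val else "train")
    return LabeledDataset(
        images=np.stack(images),
        labels=np.array(labels, dtype=np.int64),
        split=np.array(split),
        n_classes=n_classes,
    )


# ---------------------------------------------------------------------------
# serialization

def write_scene(scene: SyntheticScene, image_path, annotation_path=None) -> None:
    """Write a scene as PNG plus (optionally) a JSON box annotation."""
    import imageio.v3 as iio

    iio.imwrite(image_path, scene.image)
    if annotation_path is not None:
        b = scene.gt_box
        record = {
            "filename": str(image_path),
            "x0": b.x0,
            "y0": b.y0,
            "x1": b.x1,
            "y1": b.y1,
            "params": scene.params,
        }
        with open(annotation_path, "w") as fh:
            json.dump(record, fh, indent=2)


def write_annotations(scenes_with_names, csv_path) -> None:
    """CSV annotation table: ``filename,x0,y0,x1,y1`` (0-based, half-open)."""
    with open(csv_path, "w") as fh:
        fh.write("filename,x0,y0,x1,y1\n")
        for name, box in scenes_with_names:
            fh.write(f"{name},{box.x0},{box.y0},{box.x1},{box.y1}\n")
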