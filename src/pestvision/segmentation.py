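"""Graph-based over-segmentation and per-region statistics.

The saliency stage needs a coarse partition of the image into
color-coherent regions.  We use efficient graph-based segmentation
(Felzenszwalb–Huttenlocher): pixels are nodes of a grid graph weighted by
color difference and components are merged greedily when the connecting
edge weight does not exceed the minimum internal difference plus ``k/|C|``.
The merge itself is delegated to :func:`skimage.segmentation.felzenszwalb`;
this module enforces the contract on top of it (consecutive labels, full
partition, minimum region size) and computes the region statistics
(pixel counts and normalized centroids) consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import felzenszwalb

__all__ = [
    "RegionMap",
    "RegionStats",
    "segment_graph",
    "compute_region_stats",
    "save_region_map",
    "load_region_map",
]

#: default merge scale, expressed on the 0-255 intensity scale
DEFAULT_K = 300.0
DEFAULT_SMOOTH_SIGMA = 0.8
DEFAULT_MIN_SIZE = 100


@dataclass(frozen=True)
class RegionMap:
    """Integer region labeling of an image.

    ``labels`` is an ``H x W`` raster with values ``0 .. n_regions-1``;
    every pixel carries exactly one label and every label occurs.
    """

    labels: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        present = np.unique(self.labels)
        if present.size != self.n_regions or present[0] != 0 or present[-1] != self.n_regions - 1:
            raise ValueError("labels must be consecutive integers 0..n_regions-1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class RegionStats:
    """Size and position of one region.

    ``pixel_count`` is the number of member pixels; ``centroid`` is the
    mean of member pixel centers, x normalized by image width and y by
    image height into [0, 1].
    """

    pixel_count: int
    centroid: tuple[float, float]  # (x, y), normalized


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB raster, got shape {image.shape}")
    return image


def segment_graph(
    image: np.ndarray,
    k: float = DEFAULT_K,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    min_size: int = DEFAULT_MIN_SIZE,
) -> RegionMap:
    """Partition an RGB image into connected regions.

    Parameters
    ----------
    image:
        ``H x W x 3`` 8-bit RGB raster.
    k:
        Merge scale on the 0-255 intensity scale; larger values favor
        larger regions.
    smooth_sigma:
        Gaussian pre-smoothing width in pixels.
    min_size:
        Minimum region size; smaller components are absorbed into the
        neighbor joined by the cheapest edge.
    """
    image = _as_rgb(image)
    if k <= 0:
        raise ValueError("k must be positive")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    # skimage computes edge weights on a [0, 1] float image; rescale the
    # 0-255 merge constant accordingly.
    labels = felzenszwalb(image, scale=k / 255.0, sigma=smooth_sigma, min_size=min_size)
    labels = np.ascontiguousarray(labels)
    # relabel to consecutive ids (felzenszwalb output is already dense in
    # practice, but the contract must not depend on that)
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(image.shape[:2]).astype(np.int32)
    return RegionMap(labels=labels, n_regions=int(labels.max()) + 1)


def compute_region_stats(region_map: RegionMap, height: int | None = None, width: int | None = None) -> list[RegionStats]:
    """Per-region pixel counts and normalized centroids.

    Pixel centers sit at integer coordinates; the centroid of region *r*
    is the mean of its pixel centers with x divided by ``width`` and y by
    ``height``, so both components land in [0, 1).
    """
    labels = region_map.labels
    h, w = labels.shape
    height = h if height is None else height
    width = w if width is None else width
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=region_map.n_regions)
    ys, xs = np.indices((h, w))
    sum_x = np.bincount(flat, weights=xs.ravel(), minlength=region_map.n_regions)
    sum_y = np.bincount(flat, weights=ys.ravel(), minlength=region_map.n_regions)
    stats = []
    for r in range(region_map.n_regions):
        c = int(counts[r])
        stats.append(
            RegionStats(
                pixel_count=c,
                centroid=(float(sum_x[r] / c / width), float(sum_y[r] / c / height)),
            )
        )
    return stats


def save_region_map(region_map: RegionMap, png_path, stats_path=None) -> None:
    """Write labels as 16-bit single-channel PNG, stats as a JSON sidecar."""
    import json

    import imageio.v3 as iio

    if region_map.n_regions > 2**16:
        raise ValueError("more regions than a 16-bit raster can hold")
    iio.imwrite(png_path, region_map.labels.astype(np.uint16))
    if stats_path is not None:
        stats = compute_region_stats(region_map)
        with open(stats_path, "w") as fh:
            json.dump(
                [{"pixel_count": s.pixel_count, "centroid": list(s.centroid)} for s in stats],
                fh,
                indent=2,
            )


def load_region_map(png_path) -> RegionMap:
    import imageio.v3 as iio

    labels = iio.imread(png_path).astype(np.int32)
    return RegionMap(labels=labels, n_regions=int(labels.max()) + 1)
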