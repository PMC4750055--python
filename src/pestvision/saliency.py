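"""Global-contrast region-based saliency.

A region is salient when its color content contrasts with the rest of the
image.  After graph-based segmentation, colors are quantized to a coarse
palette (10 bins per RGB channel by default, 10^3 colors), a color
histogram is built per region, and each region's saliency is its
size- and distance-weighted contrast against all other regions:

    S(r_k) = sum_{i != k}  exp(-D_s(r_k, r_i) / sigma_s^2) * w(r_i) * D_r(r_k, r_i)

where ``w(r_i)`` is the pixel count of region i, ``D_s`` the Euclidean
distance between normalized region centroids and ``D_r`` the
histogram-weighted color distance

    D_r(r_1, r_2) = sum_i sum_j p(c_{1,i}) p(c_{2,j}) D(c_{1,i}, c_{2,j}),

so dominant colors weigh most.  A large ``sigma_s`` (default 0.45) keeps
the spatial weighting mild, letting far regions contribute.  The map is
min-max normalized to [0, 1] and broadcast back to pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import rgb2lab

from .segmentation import (
    DEFAULT_K,
    DEFAULT_MIN_SIZE,
    DEFAULT_SMOOTH_SIGMA,
    RegionMap,
    RegionStats,
    compute_region_stats,
    segment_graph,
)

__all__ = [
    "SaliencyConfig",
    "ColorQuantization",
    "RegionColorHistogram",
    "SaliencyMap",
    "quantize_colors",
    "build_region_histograms",
    "color_distance",
    "palette_distance_matrix",
    "region_color_distance",
    "region_saliency",
    "normalize_and_render",
    "compute_saliency",
]

COLOR_METRICS = ("lab", "rgb")


@dataclass(frozen=True)
class SaliencyConfig:
    """Knobs of the contrast computation.

    ``sigma_s`` controls the strength of the spatial weighting (larger =
    weaker decay with distance); ``color_metric`` selects the space in
    which palette colors are compared ("lab" or "rgb", both scaled so the
    maximal palette pair has distance 1).
    """

    bins_per_channel: int = 10
    sigma_s: float = 0.45
    color_metric: str = "lab"
    # segmentation stage parameters, bundled here so one config drives
    # the end-to-end map
    seg_k: float = DEFAULT_K
    seg_sigma: float = DEFAULT_SMOOTH_SIGMA
    seg_min_size: int = DEFAULT_MIN_SIZE

    def __post_init__(self) -> None:
        if self.bins_per_channel < 2:
            raise ValueError("bins_per_channel must be >= 2")
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if self.color_metric not in COLOR_METRICS:
            raise ValueError(f"unknown color metric {self.color_metric!r}; choose from {COLOR_METRICS}")


@dataclass(frozen=True)
class ColorQuantization:
    """Quantized color index per pixel plus the bin-center palette.

    ``index_raster`` holds flat indices ``bR*bins^2 + bG*bins + bB``;
    ``palette`` maps every possible index to its bin-center RGB color in
    [0, 255] floats.
    """

    index_raster: np.ndarray
    palette: np.ndarray
    bins_per_channel: int


@dataclass(frozen=True)
class RegionColorHistogram:
    """Normalized frequency of the quantized colors occurring in a region."""

    region: int
    colors: np.ndarray  # palette indices occurring in the region
    probs: np.ndarray   # matching probabilities, summing to 1


@dataclass(frozen=True)
class SaliencyMap:
    region_values: np.ndarray
    pixel_raster: np.ndarray
    region_map: RegionMap = field(repr=False)


def quantize_colors(image: np.ndarray, bins_per_channel: int = 10) -> ColorQuantization:
    """Quantize each RGB channel to ``bins_per_channel`` values.

    Channel value v in 0..255 falls into bin ``floor(v * bins / 256)``;
    the palette entry for a bin is its center ``(b + 0.5) * 256 / bins``.
    With 10 bins the set of producible colors has 10^3 = 1000 members.
    """
    if bins_per_channel < 2:
        raise ValueError("bins_per_channel must be >= 2")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit H x W x 3 RGB raster")
    b = bins_per_channel
    bins = (image.astype(np.int64) * b) // 256
    index = bins[..., 0] * b * b + bins[..., 1] * b + bins[..., 2]
    centers = (np.arange(b) + 0.5) * 256.0 / b
    palette = np.stack(np.meshgrid(centers, centers, centers, indexing="ij"), axis=-1).reshape(-1, 3)
    return ColorQuantization(index_raster=index, palette=palette, bins_per_channel=b)


def build_region_histograms(quant: ColorQuantization, region_map: RegionMap) -> list[RegionColorHistogram]:
    """Per-region normalized histograms over the quantized palette."""
    if quant.index_raster.shape != region_map.labels.shape:
        raise ValueError("quantization raster and region map sizes differ")
    n_colors = quant.palette.shape[0]
    combined = region_map.labels.astype(np.int64).ravel() * n_colors + quant.index_raster.ravel()
    counts = np.bincount(combined, minlength=region_map.n_regions * n_colors)
    counts = counts.reshape(region_map.n_regions, n_colors)
    out = []
    for r in range(region_map.n_regions):
        row = counts[r]
        occur = np.nonzero(row)[0]
        probs = row[occur] / row.sum()
        out.append(RegionColorHistogram(region=r, colors=occur, probs=probs))
    return out


def palette_distance_matrix(palette: np.ndarray, metric: str = "lab") -> np.ndarray:
    """Pairwise color distances over the whole palette, scaled to max 1.

    The scale factor is found by brute force over all palette pairs, so
    the maximal pair has distance exactly 1 regardless of metric.
    """
    if metric == "lab":
        pts = rgb2lab(palette.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
    elif metric == "rgb":
        pts = palette / 255.0
    else:
        raise ValueError(f"unknown color metric {metric!r}; choose from {COLOR_METRICS}")
    d = cdist(pts, pts)
    return d / d.max()


def color_distance(c_i: int, c_j: int, palette: np.ndarray, metric: str = "lab") -> float:
    """Distance between two palette colors (symmetric, 0 iff identical)."""
    return float(palette_distance_matrix(palette, metric)[c_i, c_j])


def region_color_distance(
    h1: RegionColorHistogram,
    h2: RegionColorHistogram,
    dmat: np.ndarray,
) -> float:
    """Histogram-weighted color distance D_r between two regions.

    ``dmat`` is the full palette distance matrix
    (:func:`palette_distance_matrix`).
    """
    sub = dmat[np.ix_(h1.colors, h2.colors)]
    return float(h1.probs @ sub @ h2.probs)


def region_saliency(
    histograms: list[RegionColorHistogram],
    stats: list[RegionStats],
    config: SaliencyConfig,
    dmat: np.ndarray | None = None,
    palette: np.ndarray | None = None,
) -> np.ndarray:
    """Raw (unnormalized) saliency per region.

    Vectorized evaluation of the contrast sum; exact (to floating point)
    against a nested-loop evaluation.  A single-region image has an empty
    sum and returns ``[0.0]``.
    """
    n = len(histograms)
    if n != len(stats):
        raise ValueError("histograms and stats must be index-aligned")
    if n == 1:
        return np.zeros(1)
    if dmat is None:
        if palette is None:
            raise ValueError("either dmat or palette is required")
        dmat = palette_distance_matrix(palette, config.color_metric)
    # region-by-region histogram matrix (regions are few; dense is fine)
    n_colors = dmat.shape[0]
    P = np.zeros((n, n_colors))
    for h in histograms:
        P[h.region, h.colors] = h.probs
    dr = P @ dmat @ P.T
    cent = np.array([s.centroid for s in stats])
    omega = np.array([s.pixel_count for s in stats], dtype=float)
    ds = cdist(cent, cent)
    w = np.exp(-ds / config.sigma_s**2)
    contrib = w * dr * omega[None, :]
    np.fill_diagonal(contrib, 0.0)
    return contrib.sum(axis=1)


def normalize_and_render(raw: np.ndarray, region_map: RegionMap) -> SaliencyMap:
    """Min-max normalize region saliencies and broadcast to pixels.

    Degenerate inputs (single region, or all regions equally salient)
    render as an all-zero map so batch pipelines can proceed.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (region_map.n_regions,):
        raise ValueError("one raw value per region required")
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        values = (raw - lo) / (hi - lo)
    else:
        values = np.zeros_like(raw)
    return SaliencyMap(
        region_values=values,
        pixel_raster=values[region_map.labels],
        region_map=region_map,
    )


def compute_saliency(
    image: np.ndarray,
    config: SaliencyConfig | None = None,
    region_map: RegionMap | None = None,
) -> SaliencyMap:
    """End-to-end saliency map for an RGB image.

    Composition: graph segmentation -> color quantization -> region
    histograms -> contrast saliency -> min-max normalized pixel map.
    """
    config = config or SaliencyConfig()
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image")
    if region_map is None:
        region_map = segment_graph(
            image, k=config.seg_k, smooth_sigma=config.seg_sigma, min_size=config.seg_min_size
        )
    quant = quantize_colors(image, config.bins_per_channel)
    hists = build_region_histograms(quant, region_map)
    stats = compute_region_stats(region_map)
    dmat = palette_distance_matrix(quant.palette, config.color_metric)
    raw = region_saliency(hists, stats, config, dmat=dmat)
    return normalize_and_render(raw, region_map)
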