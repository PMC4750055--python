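"""Iterative GrabCut-style foreground refinement.

GrabCut alternates between (1) fitting Gaussian mixture color models to
the current foreground and background pixel sets and (2) relabeling all
pixels by solving an s-t min-cut on the pixel grid whose terminal
capacities are the negative log-likelihoods under the two mixtures and
whose pairwise capacities penalize cutting low-contrast edges:

    V(i, j) = gamma / dist(i, j) * exp(-beta * ||z_i - z_j||^2)

with ``beta = 1 / (2 <||z_i - z_j||^2>)`` estimated from the image.  The
initialization here is soft: every pixel is merely *probable* foreground
or background, so the cut may flip any pixel — which is what lets color
evidence recover thin object parts (legs, antennae) the saliency
threshold missed.

The mixtures are fit with :class:`sklearn.mixture.GaussianMixture` and
the cut is solved with igraph's max-flow; both are deterministic for a
fixed seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from igraph import Graph
from sklearn.mixture import GaussianMixture

__all__ = ["DegenerateInitError", "grabcut_refine"]

GAMMA = 50.0
N_COMPONENTS = 5


class DegenerateInitError(ValueError):
    """Raised when the initial mask has no foreground or no background."""


def _fit_gmm(pixels: np.ndarray, seed: int, rng: np.random.Generator) -> GaussianMixture:
    n_comp = min(N_COMPONENTS, len(np.unique(pixels, axis=0)), len(pixels))
    # subsample large pixel sets; the color model does not need every pixel
    if len(pixels) > 20000:
        idx = rng.choice(len(pixels), 20000, replace=False)
        fit_px = pixels[idx]
    else:
        fit_px = pixels
    gmm = GaussianMixture(
        n_components=max(n_comp, 1),
        covariance_type="full",
        reg_covar=1e-4,
        max_iter=10,
        n_init=1,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # few EM rounds per GrabCut iteration by design; no need to converge
        warnings.simplefilter("ignore", ConvergenceWarning)
        gmm.fit(fit_px)
    return gmm


def _pairwise_terms(img: np.ndarray):
    """Edge lists and contrast-sensitive capacities for the 8-neighborhood."""
    h, w = img.shape[:2]
    ids = np.arange(h * w).reshape(h, w)
    offsets = [
        ((0, 1), 1.0),          # right
        ((1, 0), 1.0),          # down
        ((1, 1), np.sqrt(2)),   # down-right
        ((1, -1), np.sqrt(2)),  # down-left
    ]
    edges_a, edges_b, sqdiffs, dists = [], [], [], []
    for (dy, dx), dist in offsets:
        ys = slice(0, h - dy)
        xs = slice(max(0, -dx), w - max(0, dx))
        ys2 = slice(dy, h)
        xs2 = slice(max(0, dx), w - max(0, -dx))
        a = ids[ys, xs].ravel()
        b = ids[ys2, xs2].ravel()
        d = img[ys, xs].reshape(-1, 3) - img[ys2, xs2].reshape(-1, 3)
        edges_a.append(a)
        edges_b.append(b)
        sqdiffs.append(np.sum(d * d, axis=1))
        dists.append(np.full(len(a), dist))
    a = np.concatenate(edges_a)
    b = np.concatenate(edges_b)
    sq = np.concatenate(sqdiffs)
    dist = np.concatenate(dists)
    beta = 1.0 / max(2.0 * sq.mean(), 1e-12)
    cap = GAMMA / dist * np.exp(-beta * sq)
    return a, b, cap


def grabcut_refine(image: np.ndarray, init_mask: np.ndarray, iters: int = 3, seed: int = 0) -> np.ndarray:
    """Refine a binary foreground mask by iterated GMM + graph cut.

    Parameters
    ----------
    image:
        ``H x W x 3`` RGB raster (8-bit or float).
    init_mask:
        Boolean raster; True pixels start as probable foreground.
    iters:
        Number of model-fit / cut rounds (the reference pipeline uses 3).
    seed:
        Seed for mixture initialization; fixed seed => identical masks.

    Raises
    ------
    DegenerateInitError
        If ``init_mask`` is empty or covers the whole image.
    """
    init_mask = np.asarray(init_mask, dtype=bool)
    if init_mask.ndim != 2:
        raise ValueError("init_mask must be a 2-D boolean raster")
    if not init_mask.any() or init_mask.all():
        raise DegenerateInitError("initial mask must contain both foreground and background")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB raster")
    if image.dtype == np.uint8:
        img = img / 255.0
    h, w = img.shape[:2]
    n = h * w
    pixels = img.reshape(-1, 3)
    a, b, pair_cap = _pairwise_terms(img)
    edges = np.stack(
        [
            np.concatenate([a, np.arange(n), np.arange(n)]),
            np.concatenate([b, np.full(n, n), np.full(n, n + 1)]),
        ],
        axis=1,
    )
    g = Graph(n=n + 2, edges=edges.tolist(), directed=False)
    rng = np.random.default_rng(seed)
    mask = init_mask.copy()
    for _ in range(iters):
        fg = pixels[mask.ravel()]
        bg = pixels[~mask.ravel()]
        if len(fg) == 0 or len(bg) == 0:
            break  # cut collapsed to one side; color models can no longer be fit
        fg_gmm = _fit_gmm(fg, seed, rng)
        bg_gmm = _fit_gmm(bg, seed, rng)
        # data terms: cost of assigning a pixel to each side
        d_fg = -fg_gmm.score_samples(pixels)
        d_bg = -bg_gmm.score_samples(pixels)
        lo = min(d_fg.min(), d_bg.min())
        # shift so capacities are non-negative; the cut is invariant to it
        cap_source = d_bg - lo  # source = foreground side
        cap_sink = d_fg - lo
        caps = np.concatenate([pair_cap, cap_source, cap_sink])
        cut = g.st_mincut(source=n, target=n + 1, capacity=caps.tolist())
        fg_side = set(cut.partition[0]) if n in cut.partition[0] else set(cut.partition[1])
        fg_side.discard(n)
        new_mask = np.zeros(n, dtype=bool)
        new_mask[list(fg_side)] = True
        mask = new_mask.reshape(h, w)
    return mask
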