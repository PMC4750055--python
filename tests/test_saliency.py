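"""Color quantization, region contrast, and the saliency map."""

import math

import numpy as np
import pytest

from conftest import random_region_instance
from pestvision.saliency import (
    RegionColorHistogram,
    SaliencyConfig,
    build_region_histograms,
    compute_saliency,
    normalize_and_render,
    palette_distance_matrix,
    quantize_colors,
    region_color_distance,
    region_saliency,
)
from pestvision.segmentation import RegionMap, RegionStats, compute_region_stats


def _img(pixels):
    return np.array(pixels, dtype=np.uint8).reshape(1, -1, 3)


class TestQuantization:
    def test_corner_pixels(self):
        q = quantize_colors(_img([[0, 0, 0], [255, 255, 255]]), 10)
        assert q.index_raster[0, 0] == 0
        assert q.index_raster[0, 1] == 999

    def test_palette_cardinality(self):
        q = quantize_colors(_img([[0, 0, 0]]), 10)
        assert q.palette.shape == (1000, 3)
        assert len({tuple(c) for c in q.palette}) == 1000

    def test_palette_entries_are_bin_centers(self):
        q = quantize_colors(_img([[37, 140, 250]]), 10)
        idx = q.index_raster[0, 0]
        assert idx == 1 * 100 + 5 * 10 + 9
        np.testing.assert_allclose(q.palette[idx], [1.5 * 25.6, 5.5 * 25.6, 9.5 * 25.6])

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            quantize_colors(_img([[0, 0, 0]]), 1)


class TestHistograms:
    def test_counting(self):
        img = _img([[0, 0, 0], [0, 0, 0], [0, 0, 0], [255, 255, 255]])
        rm = RegionMap(labels=np.zeros((1, 4), dtype=np.int32), n_regions=1)
        (h,) = build_region_histograms(quantize_colors(img, 10), rm)
        assert dict(zip(h.colors, h.probs)) == {0: 0.75, 999: 0.25}

    def test_histograms_sum_to_one(self):
        image, rm = random_region_instance(seed=0)
        hists = build_region_histograms(quantize_colors(image, 10), rm)
        for h in hists:
            assert h.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (h.probs > 0).all()

    def test_size_mismatch_rejected(self):
        img = _img([[0, 0, 0]])
        rm = RegionMap(labels=np.zeros((2, 2), dtype=np.int32), n_regions=1)
        with pytest.raises(ValueError):
            build_region_histograms(quantize_colors(img, 10), rm)


@pytest.fixture(scope="module")
def palette():
    return quantize_colors(_img([[0, 0, 0]]), 10).palette


@pytest.fixture(scope="module")
def dmat(palette):
    return palette_distance_matrix(palette, "lab")


class TestColorDistance:
    @pytest.mark.parametrize("metric", ["lab", "rgb"])
    def test_metric_axioms_and_scaling(self, palette, metric):
        d = palette_distance_matrix(palette, metric)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert d.max() == pytest.approx(1.0)

    def test_rgb_extremes_attain_the_maximum(self, palette):
        # brute force over all palette pairs: in RGB the black<->white
        # bin centers are (one of) the farthest pairs
        d = palette_distance_matrix(palette, "rgb")
        assert d[0, 999] == pytest.approx(1.0)

    def test_unknown_metric_rejected(self, palette):
        with pytest.raises(ValueError):
            palette_distance_matrix(palette, "xyz")


class TestRegionColorDistance:
    def test_identical_single_color_is_zero(self, dmat):
        h = RegionColorHistogram(0, np.array([5]), np.array([1.0]))
        assert region_color_distance(h, h, dmat) == 0.0

    def test_degenerate_double_sum(self, dmat):
        h1 = RegionColorHistogram(0, np.array([3]), np.array([1.0]))
        h2 = RegionColorHistogram(1, np.array([700]), np.array([1.0]))
        assert region_color_distance(h1, h2, dmat) == pytest.approx(dmat[3, 700])

    def test_mixed_histogram(self, dmat):
        h1 = RegionColorHistogram(0, np.array([3, 700]), np.array([0.5, 0.5]))
        h2 = RegionColorHistogram(1, np.array([700]), np.array([1.0]))
        assert region_color_distance(h1, h2, dmat) == pytest.approx(0.5 * dmat[3, 700])

    def test_symmetry_on_random_histograms(self, dmat):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n1, n2 = rng.integers(1, 8, 2)
            c1 = rng.choice(1000, n1, replace=False)
            c2 = rng.choice(1000, n2, replace=False)
            p1 = rng.dirichlet(np.ones(n1))
            p2 = rng.dirichlet(np.ones(n2))
            h1 = RegionColorHistogram(0, c1, p1)
            h2 = RegionColorHistogram(1, c2, p2)
            assert region_color_distance(h1, h2, dmat) == pytest.approx(
                region_color_distance(h2, h1, dmat), abs=1e-12
            )


def brute_force_saliency(hists, stats, config, dmat):
    """Independent nested-loop evaluation of the contrast sum."""
    out = []
    for k, hk in enumerate(hists):
        total = 0.0
        for i, hi in enumerate(hists):
            if i == k:
                continue
            dr = 0.0
            for ck, pk in zip(hk.colors, hk.probs):
                for ci, pi in zip(hi.colors, hi.probs):
                    dr += pk * pi * dmat[ck, ci]
            ds = math.dist(stats[k].centroid, stats[i].centroid)
            total += math.exp(-ds / config.sigma_s**2) * stats[i].pixel_count * dr
        out.append(total)
    return np.array(out)


class TestRegionSaliency:
    def test_single_region_is_zero(self):
        h = [RegionColorHistogram(0, np.array([0]), np.array([1.0]))]
        s = [RegionStats(100, (0.5, 0.5))]
        out = region_saliency(h, s, SaliencyConfig(), dmat=np.zeros((1000, 1000)))
        np.testing.assert_array_equal(out, [0.0])

    def test_two_region_closed_form(self):
        dmat = np.zeros((1000, 1000))
        delta = 0.37
        dmat[5, 900] = dmat[900, 5] = delta
        h = [
            RegionColorHistogram(0, np.array([5]), np.array([1.0])),
            RegionColorHistogram(1, np.array([900]), np.array([1.0])),
        ]
        s = [RegionStats(100, (0.2, 0.5)), RegionStats(300, (0.7, 0.5))]
        cfg = SaliencyConfig(sigma_s=0.45)
        out = region_saliency(h, s, cfg, dmat=dmat)
        w = math.exp(-0.5 / 0.45**2)
        assert out[0] == pytest.approx(w * 300 * delta, rel=1e-12)
        assert out[1] == pytest.approx(w * 100 * delta, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        image, rm = random_region_instance(seed=1000 + seed)
        quant = quantize_colors(image, 10)
        hists = build_region_histograms(quant, rm)
        stats = compute_region_stats(rm)
        cfg = SaliencyConfig()
        dmat = palette_distance_matrix(quant.palette, cfg.color_metric)
        fast = region_saliency(hists, stats, cfg, dmat=dmat)
        slow = brute_force_saliency(hists, stats, cfg, dmat)
        np.testing.assert_allclose(fast, slow, atol=1e-9)


class TestNormalizeAndRender:
    def test_minmax_endpoints(self):
        rm = RegionMap(labels=np.array([[0, 1]], dtype=np.int32), n_regions=2)
        out = normalize_and_render(np.array([5.0, 15.0]), rm)
        np.testing.assert_array_equal(out.region_values, [0.0, 1.0])
        np.testing.assert_array_equal(out.pixel_raster, [[0.0, 1.0]])

    def test_constant_raw_maps_to_zero(self):
        rm = RegionMap(labels=np.array([[0, 1]], dtype=np.int32), n_regions=2)
        out = normalize_and_render(np.array([3.0, 3.0]), rm)
        np.testing.assert_array_equal(out.region_values, [0.0, 0.0])


class TestComputeSaliency:
    def test_uniform_image_all_zero(self):
        img = np.full((64, 64, 3), 90, dtype=np.uint8)
        out = compute_saliency(img)
        assert out.pixel_raster.max() == 0.0

    def test_object_more_salient_than_background(self, easy_scenes):
        for scene in easy_scenes[:4]:
            smap = compute_saliency(scene.image)
            inside = smap.pixel_raster[scene.object_mask].mean()
            outside = smap.pixel_raster[~scene.object_mask].mean()
            assert inside > outside

    def test_deterministic(self, one_scene):
        a = compute_saliency(one_scene.image)
        b = compute_saliency(one_scene.image)
        np.testing.assert_array_equal(a.pixel_raster, b.pixel_raster)

    def test_map_range(self, one_scene):
        smap = compute_saliency(one_scene.image)
        assert smap.pixel_raster.min() >= 0.0 and smap.pixel_raster.max() <= 1.0


def test_sigma_s_monotonicity():
    """Larger sigma_s weakens the spatial decay: the weight increases."""
    ds = 0.5
    weights = [math.exp(-ds / s**2) for s in (0.2, 0.35, 0.45, 0.7, 1.2)]
    cfg_weights = []
    for sigma in (0.2, 0.35, 0.45, 0.7, 1.2):
        dmat = np.zeros((1000, 1000))
        dmat[0, 999] = dmat[999, 0] = 1.0
        h = [
            RegionColorHistogram(0, np.array([0]), np.array([1.0])),
            RegionColorHistogram(1, np.array([999]), np.array([1.0])),
        ]
        s = [RegionStats(10, (0.0, 0.0)), RegionStats(10, (0.3, 0.4))]
        out = region_saliency(h, s, SaliencyConfig(sigma_s=sigma), dmat=dmat)
        cfg_weights.append(out[0] / 10.0)
    assert all(b > a for a, b in zip(weights, weights[1:]))
    assert all(b > a for a, b in zip(cfg_weights, cfg_weights[1:]))
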