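"""Grayscale, thresholding, edges, labelling and calibrated measurements."""

import numpy as np
import pytest

from mpmorph import (
    AUTO,
    Micrograph,
    analyze_micrograph,
    binarize,
    extract_cluster,
    label_components,
    measure_particle,
    sobel_edges,
    to_grayscale,
)
from mpmorph.morphometry import GRAY_WEIGHTS, fill_holes, measure_all
from mpmorph.segmentation import flatten_image, run_kmeans
from mpmorph.synthetic import ParticleSpec, SceneSpec, generate_micrograph


def flood_fill_count(mask):
    """Independent 8-connectivity region counter (iterative flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


class TestGrayscale:
    def test_achromatic_pixel_maps_to_itself(self):
        m = Micrograph(np.full((4, 4, 3), 0.37), 1.0)
        np.testing.assert_allclose(to_grayscale(m), 0.37)

    def test_pure_green_gives_green_weight(self):
        img = np.zeros((4, 4, 3))
        img[..., 1] = 1.0
        assert to_grayscale(Micrograph(img, 1.0))[0, 0] == pytest.approx(GRAY_WEIGHTS[1])

    def test_linearity_of_mean(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(16, 16, 3))
        gray = to_grayscale(Micrograph(img, 1.0))
        expected = sum(w * img[..., i].mean() for i, w in enumerate(GRAY_WEIGHTS))
        assert gray.mean() == pytest.approx(expected, abs=1e-12)


class TestBinarize:
    @pytest.mark.parametrize("value,expect_full", [(0.6, False), (0.4, True)])
    def test_uniform_images(self, value, expect_full):
        mask = binarize(np.full((5, 5), value))
        assert mask.all() == expect_full and mask.any() == expect_full

    def test_half_and_half_counts(self):
        g = np.concatenate([np.full((4, 8), 0.2), np.full((4, 8), 0.8)])
        assert binarize(g).sum() == g.size // 2

    def test_bright_particle_polarity(self):
        g = np.full((4, 4), 0.9)
        assert binarize(g, particle_is_dark=False).all()

    def test_threshold_must_be_interior(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((3, 3)), threshold=1.0)


class TestSobel:
    def test_constant_image_zero_response(self):
        assert np.all(sobel_edges(np.full((6, 6), 0.7)) == 0.0)

    def test_vertical_step_hand_convolution(self):
        # unit step between columns 2 and 3; interior response on the two
        # step-adjacent columns is |Gx| = 4 (kernel rows 1,2,1 summed),
        # rescaled by the max so they read 1.0, and zero far away
        g = np.zeros((7, 8))
        g[:, 4:] = 1.0
        e = sobel_edges(g)
        assert np.all(e[:, 3] == 1.0)
        assert np.all(e[:, 4] == 1.0)
        assert np.all(e[:, :2] == 0.0)
        assert np.all(e[:, -2:] == 0.0)

    def test_transpose_equivariance(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(size=(9, 13))
        np.testing.assert_allclose(sobel_edges(g.T), sobel_edges(g).T, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            sobel_edges(np.zeros((2, 5)))


class TestLabelComponents:
    def test_single_rectangle(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 3:8] = True
        regions = label_components(mask, min_pixels=1)
        assert regions.n_regions == 1
        assert regions.pixel_count(1) == 15

    def test_diagonal_touch_is_one_region(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, min_pixels=1).n_regions == 1

    def test_min_pixels_prunes_noise(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True          # 9 px
        mask[8, 8] = True              # 1 px speck
        regions = label_components(mask, min_pixels=5)
        assert regions.n_regions == 1

    def test_labels_ordered_by_decreasing_size(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:2, 0:2] = True          # 4 px
        mask[5:10, 5:10] = True        # 25 px
        regions = label_components(mask, min_pixels=1)
        assert regions.pixel_count(1) == 25
        assert regions.pixel_count(2) == 4

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(20, 20)) < 0.35
        assert label_components(mask, min_pixels=1).n_regions == flood_fill_count(mask)


class TestMeasureParticle:
    def test_single_pixel_closed_form(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        regions = label_components(mask, min_pixels=1)
        p = measure_particle(regions, 1, 1.0)
        assert p.area_um2 == 1.0
        expected = 4.0 * np.sqrt(1.0 / 12.0)
        assert p.major_um == pytest.approx(expected, abs=1e-12)
        assert p.minor_um == pytest.approx(expected, abs=1e-12)

    def test_horizontal_line_moment_formula(self):
        mask = np.zeros((5, 14), dtype=bool)
        mask[2, 2:12] = True           # 1x10 line
        regions = label_components(mask, min_pixels=1)
        p = measure_particle(regions, 1, 1.0)
        assert p.major_um == pytest.approx(4.0 * np.sqrt((10**2 - 1) / 12.0 + 1.0 / 12.0), abs=1e-9)
        assert p.minor_um == pytest.approx(4.0 * np.sqrt(1.0 / 12.0), abs=1e-12)
        assert p.orientation_rad == pytest.approx(0.0, abs=1e-12)

    def test_rasterized_circle_axes_near_diameter(self):
        rr, cc = np.mgrid[0:80, 0:80]
        mask = (rr - 40.0) ** 2 + (cc - 40.0) ** 2 <= 30.0**2
        regions = label_components(mask, min_pixels=1)
        p = measure_particle(regions, 1, 1.0)
        assert p.major_um == pytest.approx(60.0, rel=0.02)
        assert p.minor_um == pytest.approx(60.0, rel=0.02)

    def test_scale_enters_area_quadratically_axes_linearly(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 3:6] = True
        regions = label_components(mask, min_pixels=1)
        p1 = measure_particle(regions, 1, 1.0)
        p2 = measure_particle(regions, 1, 2.5)
        assert p2.area_um2 == pytest.approx(p1.area_um2 * 2.5**2)
        assert p2.major_um == pytest.approx(p1.major_um * 2.5)
        assert p1.area_um2 / 1.0**2 == p1.pixel_count

    def test_translation_invariance_exact(self):
        base = np.zeros((30, 30), dtype=bool)
        base[3:9, 4:14] = True
        shifted = np.roll(np.roll(base, 11, axis=0), 9, axis=1)
        a = measure_particle(label_components(base, 1), 1, 1.0)
        b = measure_particle(label_components(shifted, 1), 1, 1.0)
        assert a.area_um2 == b.area_um2
        assert a.major_um == b.major_um
        assert a.minor_um == b.minor_um

    def test_rot90_invariance_exact(self):
        rng = np.random.default_rng(8)
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = np.mgrid[0:40, 0:40]
        mask[((rr - 20) / 12.0) ** 2 + ((cc - 20) / 6.0) ** 2 <= 1.0] = True
        a = measure_particle(label_components(mask, 1), 1, 1.0)
        b = measure_particle(label_components(np.rot90(mask), 1), 1, 1.0)
        assert a.major_um == pytest.approx(b.major_um, abs=1e-12)
        assert a.minor_um == pytest.approx(b.minor_um, abs=1e-12)

    def test_unknown_region_id_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        regions = label_components(mask, min_pixels=1)
        with pytest.raises(ValueError):
            measure_particle(regions, 2, 1.0)


class TestExtractCluster:
    def test_all_pixels_in_target_is_identity(self, flat_micrograph):
        fs = flatten_image(flat_micrograph)
        c = run_kmeans(fs, 1, seed=0)
        out = extract_cluster(flat_micrograph, c, 1)
        np.testing.assert_array_equal(out.pixels, flat_micrograph.pixels)

    def test_auto_selects_dark_blob_cluster(self, two_tone_micrograph):
        fs = flatten_image(two_tone_micrograph)
        c = run_kmeans(fs, 2, seed=0)
        out = extract_cluster(two_tone_micrograph, c, AUTO)
        # the kept pixels are exactly the dark square
        kept = out.pixels.sum(axis=2) > 0
        expected = np.zeros((24, 24), dtype=bool)
        expected[9:15, 9:15] = True
        np.testing.assert_array_equal(kept, expected)

    def test_empty_cluster_extraction_warns(self, flat_micrograph):
        fs = flatten_image(flat_micrograph)
        c = run_kmeans(fs, 1, seed=0)
        c.k = 2
        c.centroids = np.vstack([c.centroids, [[9.0, 9.0, 9.0]]])
        with pytest.warns(UserWarning, match="no pixels"):
            out = extract_cluster(flat_micrograph, c, 2)
        assert np.all(out.pixels == 0.0)

    def test_invalid_cluster_id_rejected(self, flat_micrograph):
        fs = flatten_image(flat_micrograph)
        c = run_kmeans(fs, 1, seed=0)
        with pytest.raises(ValueError):
            extract_cluster(flat_micrograph, c, 5)


class TestAnalyzeMicrograph:
    def test_blank_background_yields_empty_table(self):
        spec = SceneSpec(shape=(48, 48), particles=(), noise_sigma=0.01, seed=2)
        m, truth = generate_micrograph(spec)
        res = analyze_micrograph(m, k_range=range(2, 4), seed=0)
        assert len(res.measurements) == 0

    def test_single_ellipse_dimensions_within_tolerance(self, single_ellipse_scene):
        m, truth = single_ellipse_scene
        res = analyze_micrograph(m, seed=0)
        assert len(res.measurements) == 1
        row = res.measurements.iloc[0]
        assert row["major_um"] == pytest.approx(80.0, rel=0.05)
        assert row["minor_um"] == pytest.approx(40.0, rel=0.05)
        assert row["area_um2"] == pytest.approx(truth.iloc[0]["area_um2"], rel=0.03)

    def test_three_disjoint_particles_recovered(self):
        parts = tuple(
            ParticleSpec(shape="ellipse", center_um=c, major_um=mj, minor_um=mn)
            for c, mj, mn in [((30, 30), 24, 12), ((30, 95), 30, 20), ((95, 60), 40, 16)]
        )
        spec = SceneSpec(shape=(128, 128), particles=parts, seed=6)
        m, truth = generate_micrograph(spec)
        res = analyze_micrograph(m, seed=1)
        assert len(res.measurements) == 3
        got = np.sort(res.measurements["area_um2"].to_numpy())
        want = np.sort(truth["area_um2"].to_numpy())
        np.testing.assert_allclose(got, want, rtol=0.03)

    def test_pipeline_deterministic(self, single_ellipse_scene):
        m, _ = single_ellipse_scene
        a = analyze_micrograph(m, seed=7).measurements
        b = analyze_micrograph(m, seed=7).measurements
        assert a.equals(b)

    def test_hole_filling_counts_footprint(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = True
        mask[5:7, 5:7] = False
        filled = fill_holes(mask)
        assert filled.sum() == 64

    def test_measure_all_sorted_by_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:15, 6:15] = True
        df = measure_all(label_components(mask, 1), 1.0)
        assert df["area_um2"].is_monotonic_decreasing
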