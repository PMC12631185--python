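import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage import color as skcolor

from leafstack import handcrafted as hc
from leafstack.handcrafted import (
    HandcraftedParams,
    UnsegmentableImageError,
    color_histogram,
    dominant_colors,
    extract_handcrafted,
    glcm_features,
    kmeans_rgb,
    lbp_histogram,
    resize_image,
    segment_leaf,
    shape_descriptors,
    to_gray,
)
from .conftest import disk_image

rng_images = hnp.arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(4, 12), st.integers(4, 12), st.just(3)),
    elements=st.integers(0, 255),
)


class TestResize:
    def test_256_to_224(self):
        img = np.random.default_rng(0).integers(0, 256, (256, 256, 3), dtype=np.uint8)
        out = resize_image(img, 224)
        assert out.shape == (224, 224, 3)

    def test_identity_side(self):
        img = np.random.default_rng(1).integers(0, 256, (224, 224, 3), dtype=np.uint8)
        assert np.array_equal(resize_image(img, 224), img)

    def test_constant_color_preserved(self):
        img = np.full((256, 256, 3), (12, 200, 77), dtype=np.uint8)
        out = resize_image(img, 224)
        assert np.all(out == np.array([12, 200, 77]))

    def test_bad_side(self):
        with pytest.raises(ValueError):
            resize_image(np.zeros((8, 8, 3), np.uint8), 0)


class TestColorHistogram:
    @given(rng_images, st.sampled_from(["HSV", "LAB"]), st.integers(1, 16))
    @settings(max_examples=25, deadline=None)
    def test_count_conservation(self, img, space, bins):
        """Un-normalized per-channel counts always sum to the pixel count."""
        h = color_histogram(img, space, bins_per_channel=bins, normalize=False)
        n = img.shape[0] * img.shape[1]
        for c in range(3):
            assert h[c * bins : (c + 1) * bins].sum() == n

    def test_constant_image_single_bin(self):
        img = np.full((10, 10, 3), (50, 100, 150), dtype=np.uint8)
        for space in ("HSV", "LAB"):
            h = color_histogram(img, space, 8)
            for c in range(3):
                block = h[c * 8 : (c + 1) * 8]
                assert (block > 0).sum() == 1

    def test_hand_enumeration_hsv(self):
        """2x2 image of 3 red + 1 blue pixels: bins match converting the four
        pixels by hand (red H=0, blue H=2/3; S=V=1 for both)."""
        img = np.array(
            [[[255, 0, 0], [255, 0, 0]], [[255, 0, 0], [0, 0, 255]]], dtype=np.uint8
        )
        h = color_histogram(img, "HSV", 8)
        hue = h[:8]
        expected_hue = np.zeros(8)
        expected_hue[0] = 3  # H = 0
        expected_hue[int(2 / 3 * 8)] = 1  # H = 2/3 -> bin 5
        assert np.array_equal(hue, expected_hue)
        # full saturation and value for both colors -> everything in the top bin
        assert h[8 + 7] == 4 and h[16 + 7] == 4
        # cross-check against skimage's converter
        conv = skcolor.rgb2hsv(img / 255.0).reshape(-1, 3)
        assert np.allclose(sorted(conv[:, 0]), [0, 0, 0, 2 / 3])

    def test_normalized_blocks_sum_to_one(self):
        img = np.random.default_rng(2).integers(0, 256, (9, 7, 3), dtype=np.uint8)
        h = color_histogram(img, "LAB", 8, normalize=True)
        for c in range(3):
            assert h[c * 8 : (c + 1) * 8].sum() == pytest.approx(1.0)

    def test_unknown_space(self):
        with pytest.raises(ValueError, match="color space"):
            color_histogram(np.zeros((4, 4, 3), np.uint8), "XYZ")


class TestDominantColors:
    def test_exact_recovery_three_colors(self):
        """An image of exactly 3 colors at 0.6/0.3/0.1 is a zero-variance
        optimum: centroids equal the colors, proportions match."""
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[:6] = (200, 10, 10)
        img[6:9] = (10, 200, 10)
        img[9:] = (10, 10, 200)
        centroids, props = dominant_colors(img, seed=0)
        assert np.allclose(centroids, [[200, 10, 10], [10, 200, 10], [10, 10, 200]])
        assert np.allclose(props, [0.6, 0.3, 0.1])

    def test_constant_image_degenerate(self):
        img = np.full((8, 8, 3), (77, 88, 99), dtype=np.uint8)
        centroids, props = dominant_colors(img, seed=0)
        assert np.allclose(centroids, [77, 88, 99])
        assert props.sum() == pytest.approx(1.0)

    def test_two_color_objective_matches_bruteforce(self):
        """With <=2 distinct values, exhaustive assignment search gives the
        optimal k=3 objective (zero): Lloyd's must reach it."""
        img = np.zeros((6, 6, 3), dtype=np.uint8)
        img[:3] = (250, 0, 0)
        img[3:] = (0, 0, 250)
        pixels = img.reshape(-1, 3).astype(float)
        _, _, history = kmeans_rgb(pixels, k=3, seed=1, return_history=True)
        assert history[-1] == pytest.approx(0.0, abs=1e-9)

    def test_objective_never_increases(self):
        rng = np.random.default_rng(5)
        pixels = rng.integers(0, 256, (500, 3)).astype(float)
        _, _, history = kmeans_rgb(pixels, k=3, seed=2, return_history=True)
        assert all(a >= b - 1e-9 for a, b in zip(history, history[1:]))

    def test_matches_sklearn_objective(self):
        """Independent cross-check: our converged objective is no worse than
        scikit-learn's KMeans on the same pixels (within 1%)."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(8)
        pixels = np.vstack([
            rng.normal((200, 30, 30), 5, (300, 3)),
            rng.normal((30, 200, 30), 5, (200, 3)),
            rng.normal((30, 30, 200), 5, (100, 3)),
        ])
        _, _, history = kmeans_rgb(pixels, k=3, seed=3, return_history=True)
        sk = KMeans(n_clusters=3, n_init=5, random_state=0).fit(pixels)
        assert history[-1] <= sk.inertia_ * 1.01


class TestGrayAndLBP:
    def test_luma_coefficients(self):
        assert to_gray(np.full((2, 2, 3), 255, np.uint8))[0, 0] == pytest.approx(1.0)
        green = np.zeros((2, 2, 3), np.uint8)
        green[..., 1] = 255
        assert to_gray(green)[0, 0] == pytest.approx(0.587)

    @given(rng_images)
    @settings(max_examples=20, deadline=None)
    def test_gray_in_unit_interval(self, img):
        g = to_gray(img)
        assert g.min() >= 0 and g.max() <= 1

    def test_constant_image_all_codes_255(self):
        g = np.full((10, 10), 0.5)
        h = lbp_histogram(g, P=8, R=1)
        assert h[255] == 64  # (10-2)^2 interior pixels
        assert h.sum() == 64

    @given(hnp.arrays(np.float64, st.tuples(st.integers(3, 10), st.integers(3, 10)),
                      elements=st.floats(0, 1)))
    @settings(max_examples=20, deadline=None)
    def test_histogram_mass_equals_interior(self, g):
        h = lbp_histogram(g)
        H, W = g.shape
        assert h.sum() == (H - 2) * (W - 2)
        assert len(h) == 256

    def test_hand_computed_code(self):
        """Center 0.5 with ccw-from-right neighbors .6 .5 .4 .4 .4 .6 .6 .4
        gives code 1+2+32+64 = 99."""
        g = np.full((3, 3), 0.0)
        g[1, 1] = 0.5
        ccw = [(1, 2), (0, 2), (0, 1), (0, 0), (1, 0), (2, 0), (2, 1), (2, 2)]
        vals = [0.6, 0.5, 0.4, 0.4, 0.4, 0.6, 0.6, 0.4]
        for (r, c), v in zip(ccw, vals):
            g[r, c] = v
        h = lbp_histogram(g)
        assert h[99] == 1 and h.sum() == 1

    def test_too_small_image(self):
        with pytest.raises(ValueError, match="too small"):
            lbp_histogram(np.zeros((2, 5)))


class TestGLCM:
    def test_constant_image(self):
        contrast, asm = glcm_features(np.full((8, 8), 0.4))
        assert contrast == pytest.approx(0.0)
        assert asm == pytest.approx(1.0)

    def test_hand_cooccurrence_count(self):
        """2x2 quantized [[0,7],[0,7]] at angle 0 only, symmetric: two
        horizontal pairs -> P(0,7)=P(7,0)=0.5, contrast 49, ASM 0.5."""
        g = np.array([[0.0, 0.99], [0.0, 0.99]])
        contrast, asm = glcm_features(g, levels=8, angles=(0.0,))
        assert contrast == pytest.approx(49.0)
        assert asm == pytest.approx(0.5)

    @given(hnp.arrays(np.float64, st.tuples(st.integers(2, 12), st.integers(2, 12)),
                      elements=st.floats(0, 1)))
    @settings(max_examples=25, deadline=None)
    def test_bounds(self, g):
        contrast, asm = glcm_features(g, levels=8)
        assert 0.0 <= contrast <= 49.0  # (L-1)^2
        assert 0.0 < asm <= 1.0

    def test_levels_validation(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((4, 4)), levels=1)


class TestSegmentation:
    def test_bright_disk_recovered(self):
        img = disk_image(radius=40)
        mask = segment_leaf(img)
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        c = (img.shape[0] - 1) / 2.0
        dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        assert np.all(mask[dist <= 39])
        assert not np.any(mask[dist >= 41])

    def test_inverted_contrast_same_mask(self):
        bright = disk_image(radius=40, fg=200, bg=20)
        dark = disk_image(radius=40, fg=20, bg=200)
        assert np.array_equal(segment_leaf(bright), segment_leaf(dark))

    def test_speckle_noise_removed_by_largest_component(self):
        img = disk_image(radius=40)
        rng = np.random.default_rng(0)
        for _ in range(20):  # single-pixel bright speckles near the corners
            r, c = rng.integers(0, 25, 2)
            img[r, c] = 200
        mask = segment_leaf(img)
        from skimage.measure import label

        assert label(mask, connectivity=2).max() == 1
        assert mask.sum() == pytest.approx(np.pi * 40**2, rel=0.05)

    def test_constant_image_unsegmentable(self):
        with pytest.raises(UnsegmentableImageError):
            segment_leaf(np.full((16, 16, 3), 99, np.uint8))


class TestShapeDescriptors:
    def test_square_circularity(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        _, _, C = shape_descriptors(mask)
        assert C == pytest.approx(np.pi / 4, rel=0.05)

    @pytest.mark.parametrize("radius", [30, 60, 120])
    def test_disk_circularity_near_one(self, radius):
        mask = np.all(disk_image(radius) == 200, axis=-1)
        A, P, C = shape_descriptors(mask)
        assert 0.95 <= C <= 1.08
        assert A == pytest.approx(np.pi * radius**2, rel=0.03)

    def test_disk_circularity_scale_invariant(self):
        cs = []
        for radius in (30, 60, 120):
            mask = np.all(disk_image(radius) == 200, axis=-1)
            cs.append(shape_descriptors(mask)[2])
        assert max(cs) - min(cs) < 0.05

    def test_ellipse_against_ramanujan_perimeter(self):
        """Analytic oracle: C of a 2:1 ellipse matches 4*pi*a*b*pi / P_R^2
        with Ramanujan's perimeter approximation."""
        a, b = 60, 30
        yy, xx = np.mgrid[:160, :160]
        mask = ((xx - 80) / a) ** 2 + ((yy - 80) / b) ** 2 <= 1.0
        h = (a - b) ** 2 / (a + b) ** 2
        p_ramanujan = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        expected = 4 * np.pi * (np.pi * a * b) / p_ramanujan**2
        _, _, C = shape_descriptors(mask)
        assert C == pytest.approx(expected, rel=0.05)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            shape_descriptors(np.zeros((5, 5), bool))


class TestExtractHandcrafted:
    def test_default_dimension_and_layout(self, plain_spec):
        from leafstack.synthgen import generate_leaf_image

        v = extract_handcrafted(generate_leaf_image(plain_spec, seed=0))
        assert len(v.values) == 321
        assert v.blocks["hsv"] == slice(0, 24)
        assert v.blocks["lab"] == slice(24, 48)
        assert v.blocks["dominant"] == slice(48, 60)
        assert v.blocks["lbp"] == slice(60, 316)
        assert v.blocks["glcm"] == slice(316, 318)
        assert v.blocks["shape"] == slice(318, 321)
        assert np.all(np.isfinite(v.values))
        assert not v.segmentation_failed

    def test_deterministic(self, lesioned_spec):
        from leafstack.synthgen import generate_leaf_image

        img = generate_leaf_image(lesioned_spec, seed=2)
        v1 = extract_handcrafted(img)
        v2 = extract_handcrafted(img)
        assert np.array_equal(v1.values, v2.values)

    def test_background_change_moves_histograms_not_shape(self, plain_spec):
        from dataclasses import replace

        from leafstack.synthgen import generate_leaf_image

        other = replace(plain_spec, background_color=(10, 10, 80))
        v1 = extract_handcrafted(generate_leaf_image(plain_spec, seed=5))
        v2 = extract_handcrafted(generate_leaf_image(other, seed=5))
        assert not np.allclose(v1.block("hsv"), v2.block("hsv"))
        assert np.allclose(v1.block("shape"), v2.block("shape"), rtol=0.02)

    def test_unsegmentable_yields_zero_shape_and_warning(self):
        img = np.full((64, 64, 3), 120, np.uint8)
        with pytest.warns(UserWarning, match="unsegmentable"):
            v = extract_handcrafted(img, HandcraftedParams(side=64))
        assert np.all(v.block("shape") == 0)
        assert v.segmentation_failed
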