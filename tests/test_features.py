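import numpy as np
import pytest

from lungcad import features as ft
from lungcad import phantoms
from tests.conftest import disk_mask


def glcm_oracle(image, offset, n_levels, symmetric):
    """Brute-force double-loop co-occurrence oracle."""
    di, dj = offset
    counts = np.zeros((n_levels, n_levels))
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w:
                counts[image[i, j], image[ni, nj]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def texture_oracle(p):
    """Double-loop Haralick statistics used as the independent reference."""
    n = p.shape[0]
    contrast = homogeneity = entropy = 0.0
    mu_i = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * p[i, j] for i in range(n) for j in range(n))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    corr = 0.0
    for i in range(n):
        for j in range(n):
            contrast += p[i, j] * (i - j) ** 2
            homogeneity += p[i, j] / (1 + abs(i - j))
            if p[i, j] > 0:
                entropy -= p[i, j] * np.log2(p[i, j])
            corr += p[i, j] * (i - mu_i) * (j - mu_j)
    corr /= np.sqrt(var_i * var_j)
    return {"correlation": corr, "contrast": contrast,
            "homogeneity": homogeneity, "entropy": entropy}


class TestGlcm:
    def test_constant_image_single_cell(self):
        g = ft.compute_glcm(np.zeros((4, 4), dtype=int), (0, 1), n_levels=4)
        assert g.matrix[0, 0] == 1.0

    def test_two_row_example(self):
        img = np.array([[0, 0], [1, 1]])
        g = ft.compute_glcm(img, (0, 1), n_levels=2, symmetric=False)
        assert g.matrix[0, 0] == pytest.approx(0.5)
        assert g.matrix[1, 1] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            img = rng.integers(0, 8, size=(16, 16))
            for off in ft.DEFAULT_OFFSETS:
                got = ft.compute_glcm(img, off, n_levels=8).matrix
                want = glcm_oracle(img, off, 8, symmetric=True)
                assert np.abs(got - want).max() < 1e-12

    def test_matches_skimage_cross_check(self, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, size=(20, 20)).astype(np.uint8)
        got = ft.compute_glcm(img, (0, 1), n_levels=8, symmetric=True).matrix
        want = graycomatrix(img, [1], [0], levels=8, symmetric=True,
                            normed=True)[:, :, 0, 0]
        assert np.allclose(got, want)

    def test_zero_offset_and_oversized_offset_rejected(self):
        with pytest.raises(ValueError):
            ft.compute_glcm(np.zeros((4, 4), int), (0, 0))
        with pytest.raises(ValueError):
            ft.compute_glcm(np.zeros((4, 4), int), (0, 9))


class TestTextureFeatures:
    def test_constant_image_degenerate_values(self):
        g = ft.compute_glcm(np.zeros((6, 6), int), (0, 1), n_levels=4)
        t = ft.texture_features(g)
        assert t["contrast"] == 0.0
        assert t["homogeneity"] == 1.0
        assert t["entropy"] == 0.0
        assert t["correlation"] is None  # zero marginal variance

    def test_checkerboard_contrast_one(self):
        img = np.indices((8, 8)).sum(axis=0) % 2
        g = ft.compute_glcm(img, (0, 1), n_levels=2)
        assert ft.texture_features(g)["contrast"] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            img = rng.integers(0, 8, size=(16, 16))
            g = ft.compute_glcm(img, (1, 1), n_levels=8)
            got = ft.texture_features(g)
            want = texture_oracle(g.matrix)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10)


class TestShapeFeatures:
    def test_single_pixel_area(self):
        m = np.zeros((8, 8), bool)
        m[3, 3] = True
        assert ft.shape_features(m, spacing_mm=1.0)["area"] == 1.0

    def test_closed_form_square_circularity(self):
        # ideal 10x10 square in the continuous-perimeter convention
        assert ft.isoperimetric_ratio(100.0, 40.0) == pytest.approx(np.pi / 4)

    def test_digital_disk_roundness(self):
        r = ft.shape_features(disk_mask(20))["roundness"]
        assert 0.85 <= r <= 1.1

    def test_translation_invariance(self, rng):
        img = rng.uniform(0, 100, size=(48, 48))
        mask = disk_mask(8, 48)
        shifted_mask = np.roll(np.roll(mask, 3, axis=0), 5, axis=1)
        shifted_img = np.roll(np.roll(img, 3, axis=0), 5, axis=1)
        a = ft.shape_features(mask)
        b = ft.shape_features(shifted_mask)
        for k in a:
            assert a[k] == pytest.approx(b[k])
        ia = ft.intensity_features(img, mask)
        ib = ft.intensity_features(shifted_img, shifted_mask)
        for k in ia:
            assert ia[k] == pytest.approx(ib[k])

    def test_spacing_scaling(self):
        mask = disk_mask(10)
        a = ft.shape_features(mask, spacing_mm=1.0)
        b = ft.shape_features(mask, spacing_mm=2.0)
        assert b["area"] == pytest.approx(4 * a["area"])
        assert b["perimeter"] == pytest.approx(2 * a["perimeter"])
        assert b["circularity"] == pytest.approx(a["circularity"])

    def test_circularity_respects_isoperimetric_bound(self):
        # discrete boundaries may exceed the continuous bound slightly
        for seed in range(10):
            s = phantoms.make_phantom(phantoms.PhantomSpec(
                seed=seed, nodule_diameter_mm=8, image_size=48))
            assert ft.shape_features(s.mask)["circularity"] <= 1.15

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ft.shape_features(np.zeros((4, 4), bool))


class TestIntensityFeatures:
    def test_single_intensity_region(self):
        img = np.full((6, 6), 42.0)
        mask = np.ones((6, 6), bool)
        f = ft.intensity_features(img, mask)
        assert f["uniformity"] == 1.0
        assert f["variance"] == 0.0
        assert f["smoothness"] == 0.0

    def test_unit_variance_smoothness(self):
        # two equiprobable intensities {0, 2}: M=1, var=1, skew=0, kurt=1
        img = np.array([[0.0, 2.0], [2.0, 0.0]])
        f = ft.intensity_features(img, np.ones((2, 2), bool))
        assert f["mean"] == pytest.approx(1.0)
        assert f["variance"] == pytest.approx(1.0)
        assert f["skewness"] == pytest.approx(0.0)
        assert f["kurtosis"] == pytest.approx(1.0)
        assert f["smoothness"] == pytest.approx(0.5)


class TestSemanticFeatures:
    @pytest.mark.parametrize("radius,expected", [
        (2, "<4 mm"), (3, "4-7 mm"), (5, "8-20 mm"), (12, ">20 mm")])
    def test_size_bins(self, radius, expected):
        mask = disk_mask(radius, 64)
        sem = ft.semantic_features(mask, spacing_mm=1.0)
        # the digital disk's equivalent diameter tracks 2*radius
        assert abs(sem["diameter_mm"] - 2 * radius) < 1.5
        assert sem["size_bin"] == expected

    def test_perfect_disk_is_smooth(self):
        sem = ft.semantic_features(disk_mask(20), spacing_mm=1.0)
        assert sem["spiculation"] < 0.2
        assert sem["morphology"] == "Smooth"

    def test_missing_spacing_rejected(self):
        with pytest.raises(ValueError):
            ft.semantic_features(disk_mask(5), spacing_mm=0.0)


class TestFeatureVector:
    def test_deterministic_and_documented_length(self, small_dataset):
        s = small_dataset[0]
        cfg = ft.FeatureConfig(include_sensor=True)
        a = ft.extract_feature_vector(s, cfg)
        b = ft.extract_feature_vector(s, cfg)
        assert np.array_equal(a.to_array(), b.to_array())
        assert len(a.to_array()) == len(a.names()) == 4 + 5 + 6 + 5 + 5

    def test_malignant_has_lower_circularity_at_matched_diameter(self):
        ordered = 0
        for seed in range(30):
            lo = phantoms.make_phantom(phantoms.PhantomSpec(
                seed=seed, nodule_diameter_mm=12, spiculation_level=0.05))
            hi = phantoms.make_phantom(phantoms.PhantomSpec(
                seed=seed, nodule_diameter_mm=12, spiculation_level=0.7,
                nodule_class="malignant"))
            c_lo = ft.shape_features(lo.mask)["circularity"]
            c_hi = ft.shape_features(hi.mask)["circularity"]
            ordered += c_hi < c_lo
        assert ordered >= 27
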