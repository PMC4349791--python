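"""Region descriptors: EDT, skeleton, Gabor, GLCM, Radon, orientation hist."""

import numpy as np
import pytest

from spineret.region_features import (
    GaborBank,
    edt,
    gabor_features,
    glcm,
    glcm_features,
    glcm_symmetric,
    orientation_histogram,
    quantize,
    radon_features,
    radon_projection,
    region_feature_set,
    watershed_skeleton,
)


# ---------------------------------------------------------------- oracles
def brute_force_edt(mask):
    """O(n^2) nearest-background search; outside counts as background only
    when there is no background pixel at all (matching the documented
    convention)."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    for y, x in np.argwhere(mask):
        if len(bg):
            out[y, x] = np.sqrt(((bg - [y, x]) ** 2).sum(axis=1).min())
        else:
            out[y, x] = min(y + 1, h - y, x + 1, w - x)
    return out


def hand_glcm(img, offset, levels):
    dx, dy = offset
    h, w = img.shape
    counts = np.zeros((levels, levels))
    n = 0
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                counts[img[y, x], img[y2, x2]] += 1
                n += 1
    return counts / n


def hand_glcm_features(p):
    g = p.shape[0]
    cn = en = et = ho = va = num = 0.0
    mu_i = mu_j = 0.0
    for i in range(g):
        for j in range(g):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    s_i = s_j = 0.0
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            cn += (i - j) ** 2 * v
            en += v * v
            if v > 0:
                et -= v * np.log2(v)
            ho += v / (1 + abs(i - j))
            va += (i - mu_i) ** 2 * v
            s_i += (i - mu_i) ** 2 * v
            s_j += (j - mu_j) ** 2 * v
            num += (i - mu_i) * (j - mu_j) * v
    co = num / np.sqrt(s_i * s_j) if s_i > 0 and s_j > 0 else 0.0
    return np.array([cn, en, et, ho, co, va])


# ---------------------------------------------------------------- tests
class TestEDT:
    def test_all_background_zero(self):
        assert np.array_equal(edt(np.zeros((5, 5), bool)), np.zeros((5, 5)))

    def test_single_pixel_distance_one(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        assert edt(mask)[3, 3] == 1.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = rng.random((16, 16)) < rng.uniform(0.2, 0.8)
            assert np.array_equal(edt(mask), brute_force_edt(mask))

    def test_all_foreground_uses_border_convention(self):
        mask = np.ones((6, 8), bool)
        assert np.array_equal(edt(mask), brute_force_edt(mask))

    def test_lipschitz_invariant(self, rng):
        mask = rng.random((32, 32)) < 0.6
        d = edt(mask)
        assert np.all(np.abs(np.diff(d, axis=0)) <= np.sqrt(2) + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=1)) <= np.sqrt(2) + 1e-9)


class TestWatershedSkeleton:
    def test_empty_mask_empty_skeleton(self):
        assert not watershed_skeleton(np.zeros((10, 10))).any()

    def test_rectangle_contains_medial_band(self):
        """On a solid rectangle the skeleton must pass through the
        distance-maximal medial band, checked column by column against the
        brute-force distance maxima."""
        mask = np.zeros((20, 60), bool)
        mask[:, :] = True
        d = edt(mask)
        skel = watershed_skeleton(d)
        assert skel.any()
        for col in range(15, 45):  # central columns, away from the X-junctions
            col_max = d[:, col].max()
            band = np.where(d[:, col] >= col_max - 1e-9)[0]
            skel_rows = np.where(skel[:, col])[0]
            assert len(skel_rows) > 0
            assert np.any(np.isin(skel_rows, band))

    def test_skeleton_subset_of_foreground(self, rng):
        for _ in range(100):
            mask = np.zeros((24, 24), bool)
            yy, xx = np.mgrid[0:24, 0:24]
            for _blob in range(rng.integers(1, 4)):
                cy, cx = rng.uniform(4, 20, 2)
                r = rng.uniform(2, 6)
                mask |= (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
            skel = watershed_skeleton(edt(mask))
            assert not (skel & ~mask).any()


class TestGabor:
    def test_zero_image_zero_vector(self):
        bank = GaborBank(levels=2, f_max=0.25)
        fv = gabor_features(np.zeros((32, 32)), bank)
        assert np.allclose(fv.values, 0.0)
        assert len(fv) == 2

    def test_impulse_response_equals_kernel_statistics(self):
        bank = GaborBank(levels=1, orientations_deg=(30.0,), f_max=0.25)
        kr, ki = bank.kernels[0][0]
        size = kr.shape[0] + 10
        img = np.zeros((size, size))
        img[size // 2, size // 2] = 1.0
        fv = gabor_features(img, bank)
        expected = (np.abs(kr).sum() + np.abs(ki).sum()) / (2 * size * size)
        assert abs(fv.values[0] - expected) < 1e-9

    def test_vector_length_equals_frequency_levels(self):
        bank = GaborBank(levels=3, f_max=0.3)
        fv = gabor_features(np.random.default_rng(1).random((64, 64)), bank)
        assert len(fv) == 3

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            gabor_features(np.zeros((16, 16)), GaborBank(levels=4))

    def test_real_kernel_even_symmetric(self):
        bank = GaborBank(levels=1, orientations_deg=(0.0,))
        kr, ki = bank.kernels[0][0]
        assert np.allclose(kr, kr[:, ::-1])  # even along the oscillation axis
        assert np.allclose(ki, -ki[:, ::-1])  # odd part


class TestGLCM:
    def test_constant_image_single_diagonal_cell(self):
        img = np.full((8, 8), 3)
        m = glcm(img, (0, 1), levels=8)
        assert m[3, 3] == 1.0 and m.sum() == 1.0

    def test_matches_hand_enumeration_on_toy_image(self):
        img = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        for offset in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            assert np.array_equal(glcm(img, offset, 4), hand_glcm(img, offset, 4))

    def test_normalization_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 8, size=(12, 12))
            assert abs(glcm(img, (1, 1), 8).sum() - 1.0) < 1e-12

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            glcm(np.zeros((4, 4), int), (5, 0), 8)


class TestGLCMFeatures:
    def test_degenerate_distribution(self):
        p = np.zeros((8, 8))
        p[2, 2] = 1.0
        fv = glcm_features(p)
        cn, en, et, ho, _, va = fv.values
        assert cn == 0 and en == 1 and et == 0 and ho == 1 and va == 0

    def test_uniform_matrix_closed_form(self):
        p = np.full((4, 4), 1 / 16)
        fv = glcm_features(p)
        assert abs(fv.values[1] - 1 / 16) < 1e-12  # energy
        assert abs(fv.values[2] - 4.0) < 1e-12  # entropy, bits

    def test_matches_independent_formula_oracle(self, rng):
        for _ in range(30):
            p = rng.random((8, 8))
            p /= p.sum()
            assert np.allclose(glcm_features(p).values, hand_glcm_features(p),
                               atol=1e-12)

    def test_symmetric_matrix_invariant_under_transpose(self, rng):
        img = rng.integers(0, 8, size=(20, 20))
        m = glcm_symmetric(img, 8)
        assert np.allclose(m, m.T, atol=1e-15)
        assert np.allclose(glcm_features(m).values, glcm_features(m.T).values,
                           atol=1e-12)

    def test_feature_length_six(self, rng):
        p = rng.random((8, 8))
        assert len(glcm_features(p / p.sum())) == 6


class TestRadon:
    def test_empty_skeleton_all_zeros(self):
        fv = radon_features(np.zeros((16, 16)))
        assert len(fv) == 180
        assert np.allclose(fv.values, 0.0)

    def test_horizontal_line_projections(self):
        img = np.zeros((21, 21))
        img[10, 5:15] = 1.0  # horizontal 10 px line through the center row
        fv = radon_features(img)
        assert abs(fv.values[0] - 10.0) < 1e-9  # stacks into one bin at 0 deg
        assert abs(fv.values[90] - 1.0) < 1e-9  # spreads over 10 bins at 90 deg

    def test_mass_conservation_every_angle(self, rng):
        img = (rng.random((24, 24)) < 0.2).astype(float)
        total = img.sum()
        for theta in range(180):
            assert abs(radon_projection(img, float(theta)).sum() - total) < 1e-6


class TestOrientationHistogram:
    def test_constant_image_zero_histogram(self):
        fv = orientation_histogram(np.full((16, 16), 0.7))
        assert len(fv) == 18
        assert np.allclose(fv.values, 0.0)

    def test_vertical_ramp_mass_in_90_degree_bin(self):
        yy = np.mgrid[0:20, 0:20][0].astype(float) / 20
        fv = orientation_histogram(yy)
        assert fv.values[9] == fv.values.sum()  # bin [90, 100)
        assert fv.values[9] > 0

    def test_bin_mass_conservation(self, rng):
        img = rng.random((24, 24))
        fv = orientation_histogram(img)
        from scipy.ndimage import correlate1d

        rx = correlate1d(img, [-1.0, 0, 1.0], axis=1, mode="nearest")[1:-1, 1:-1]
        ry = correlate1d(img, [-1.0, 0, 1.0], axis=0, mode="nearest")[1:-1, 1:-1]
        assert abs(fv.values.sum() - np.hypot(rx, ry).sum()) < 1e-9

    def test_count_mode(self, rng):
        img = rng.random((16, 16))
        fv = orientation_histogram(img, mode="count")
        assert fv.values.sum() <= 14 * 14
        assert np.all(fv.values == fv.values.astype(int))


class TestPipeline:
    def test_feature_lengths_on_vertebra_mask(self, cervical_dataset):
        from spineret.workbench import rasterize_contour, representation_contour

        rec = cervical_dataset.records[0]
        contour = representation_contour(rec.shape.points, "9-APR")
        mask = rasterize_contour(contour, cervical_dataset.spec.image_size)
        feats = region_feature_set(mask)
        assert len(feats["GW"]) == 4
        assert len(feats["GLCM"]) == 6
        assert len(feats["RT"]) == 180
        assert len(feats["OH"]) == 18
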