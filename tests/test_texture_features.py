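import math

import numpy as np
import pytest

from flrw.texture_features import (
    GLCM_STAT_NAMES,
    FeatureWindowSpec,
    extract_features,
    feature_maps,
    glcm_matrix,
    glcm_statistics,
    haar_bank,
    haar_features,
    hog_feature,
    lbp_code,
    lbp_feature,
    quantize_levels,
)


def oracle_lbp_code(window, center, r, N):
    """Independent per-bit enumeration with its own bilinear interpolation."""
    ci, cj = center
    code = 0
    for n in range(N):
        ang = 2 * math.pi * n / N
        dy, dx = -r * math.sin(ang), r * math.cos(ang)
        y, x = ci + dy, cj + dx
        y0, x0 = int(math.floor(y)), int(math.floor(x))
        fy, fx = y - y0, x - x0
        v = 0.0
        for (yy, wy) in ((y0, 1 - fy), (y0 + 1, fy)):
            for (xx, wx) in ((x0, 1 - fx), (x0 + 1, fx)):
                if wy * wx > 0:
                    v += wy * wx * window[yy, xx]
        if fy == 0 and fx == 0:
            v = window[y0, x0]
        if v >= window[ci, cj] - 1e-9:
            code += 2**n
    return code


class TestLBP:
    def test_constant_window_all_ties_set(self):
        win = np.full((5, 5), 3.0)
        assert lbp_code(win, (2, 2), 1, 8) == 2**8 - 1

    def test_dominant_center_gives_zero(self):
        win = np.zeros((5, 5))
        win[2, 2] = 10.0
        assert lbp_code(win, (2, 2), 1, 8) == 0

    def test_random_patches_match_per_bit_oracle(self, rng):
        for _ in range(50):
            win = rng.integers(0, 50, size=(3, 3)).astype(float)
            assert lbp_code(win, (1, 1), 1, 8) == oracle_lbp_code(win, (1, 1), 1, 8)

    def test_circle_outside_window_raises(self):
        with pytest.raises(ValueError):
            lbp_code(np.zeros((3, 3)), (0, 0), 1, 8)

    def test_monotone_intensity_invariance(self, rng):
        win = rng.uniform(0, 9, size=(7, 7))
        base = lbp_code(win, (3, 3), 1, 8)
        assert lbp_code(win + 17.3, (3, 3), 1, 8) == base

    def test_feature_vector_layout_and_values(self, rng, micro_spec):
        m = micro_spec.lbp_margin
        win = rng.uniform(0, 99, size=(micro_spec.h + 2 * m, micro_spec.w + 2 * m))
        feat = lbp_feature(win, micro_spec)
        assert feat.shape == (micro_spec.h * micro_spec.w,)
        k = 0
        for i in range(micro_spec.h):
            for j in range(micro_spec.w):
                assert feat[k] == lbp_code(win, (i + m, j + m), micro_spec.lbp_radius, micro_spec.lbp_neighbors)
                k += 1

    def test_constant_image_feature(self, micro_spec):
        m = micro_spec.lbp_margin
        win = np.full((micro_spec.h + 2 * m, micro_spec.w + 2 * m), 5.0)
        assert np.all(lbp_feature(win, micro_spec) == 2**micro_spec.lbp_neighbors - 1)


class TestGLCM:
    def test_constant_window_single_cell(self):
        win = np.full((5, 5), 2, dtype=int)
        g = glcm_matrix(win, 1, 0, 8)
        assert g.sum() == pytest.approx(1.0)
        assert g[2, 2] == pytest.approx(1.0)

    def test_vertical_stripes_mass_split(self):
        win = np.tile([0, 1], (4, 4))[:, :8]  # alternating columns of levels 0/1
        g = glcm_matrix(win, 1, 0, 2)
        assert g[0, 1] == pytest.approx(0.5)
        assert g[1, 0] == pytest.approx(0.5)
        stats = glcm_statistics(g)
        assert stats[GLCM_STAT_NAMES.index("contrast")] == pytest.approx(1.0)

    def test_symmetric_and_normalized(self, rng):
        win = rng.integers(0, 6, size=(9, 9))
        for theta in (0, 45, 90, 135):
            g = glcm_matrix(win, 1, theta, 6)
            assert g.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(g, g.T)

    def test_pair_counts_match_loop_oracle(self, rng):
        win = rng.integers(0, 4, size=(6, 7))
        g = glcm_matrix(win, 1, 0, 4)
        counts = np.zeros((4, 4))
        for i in range(6):
            for j in range(6):
                a, b = win[i, j], win[i, j + 1]
                counts[a, b] += 1
                counts[b, a] += 1
        np.testing.assert_allclose(g, counts / counts.sum())

    def test_window_smaller_than_displacement(self):
        with pytest.raises(ValueError):
            glcm_matrix(np.zeros((1, 1), dtype=int), 1, 0, 2)

    def test_constant_statistics(self):
        g = glcm_matrix(np.full((4, 4), 1, dtype=int), 1, 0, 4)
        stats = dict(zip(GLCM_STAT_NAMES, glcm_statistics(g)))
        assert stats["energy"] == pytest.approx(1.0)
        assert stats["contrast"] == 0.0
        assert stats["entropy"] == pytest.approx(0.0)
        assert stats["maximum_probability"] == pytest.approx(1.0)
        assert stats["correlation"] == 0.0  # degenerate marginals

    def test_statistic_ranges(self, rng):
        for _ in range(10):
            win = rng.integers(0, 8, size=(8, 8))
            stats = dict(zip(GLCM_STAT_NAMES, glcm_statistics(glcm_matrix(win, 1, 45, 8))))
            assert 0 <= stats["energy"] <= 1
            assert stats["contrast"] >= 0
            assert stats["entropy"] >= 0


class TestHaar:
    def test_constant_window_all_zero(self):
        np.testing.assert_allclose(haar_features(np.full((11, 11), 4.2)), 0.0, atol=1e-12)

    def test_vertical_edge_response(self):
        win = np.zeros((10, 10))
        win[:, :5] = 1.0  # left half bright
        feats = haar_features(win)
        names = [(s, sc) for sc in (1.0, 0.5, 0.25) for s in ("edge_h", "edge_v", "line_h", "line_v", "center_surround")]
        assert feats[names.index(("edge_v", 1.0))] == pytest.approx(1.0)
        assert feats[names.index(("edge_h", 1.0))] == pytest.approx(0.0, abs=1e-12)

    def test_integral_equals_naive_rectangle_sums(self, rng):
        # 200 random windows, 1e-9 relative agreement with double-loop sums
        for _ in range(200):
            h = int(rng.integers(4, 13))
            w = int(rng.integers(4, 13))
            win = rng.uniform(-5, 5, size=(h, w))
            feats = haar_features(win)
            naive = np.zeros(15)
            for k, (_, _, rects) in enumerate(haar_bank(h, w)):
                val = 0.0
                for rect in rects:
                    if rect[0] == "surround":
                        _, (ot, ol, oh, ow), (ct, cl, ch, cw), area_s = rect
                        s = 0.0
                        for i in range(ot, ot + oh):
                            for j in range(ol, ol + ow):
                                if not (ct <= i < ct + ch and cl <= j < cl + cw):
                                    s += win[i, j]
                        val -= s / area_s
                    else:
                        r0, c0, hh, ww, sign = rect
                        s = sum(win[i, j] for i in range(r0, r0 + hh) for j in range(c0, c0 + ww))
                        val += sign * s / (hh * ww)
                naive[k] = val
            np.testing.assert_allclose(feats, naive, rtol=1e-9, atol=1e-9)


class TestHOG:
    def test_horizontal_ramp_single_orientation(self):
        win = np.tile(np.arange(9.0), (9, 1))  # gradient points east: angle 0
        f = hog_feature(win, 9)
        assert f[0] == pytest.approx(1.0)
        assert f.sum() == pytest.approx(1.0)

    def test_constant_window_zero_vector(self):
        np.testing.assert_array_equal(hog_feature(np.full((7, 7), 2.0), 6), 0.0)

    def test_random_window_matches_accumulation_oracle(self, rng):
        K = 7
        win = rng.uniform(0, 10, size=(9, 8))
        f = hog_feature(win, K)
        assert f.sum() == pytest.approx(1.0)
        oracle = np.zeros(K)
        for i in range(1, 8):
            for j in range(1, 7):
                gx = (win[i, j + 1] - win[i, j - 1]) / 2
                gy = (win[i + 1, j] - win[i - 1, j]) / 2
                mag = math.hypot(gx, gy)
                ang = math.degrees(math.atan2(gy, gx)) % 180.0
                oracle[min(int(ang / (180.0 / K)), K - 1)] += mag
        np.testing.assert_allclose(f, oracle / oracle.sum(), rtol=1e-12)


class TestExtractFeatures:
    def test_default_layout_length(self):
        spec = FeatureWindowSpec()
        assert spec.n_features == 121 + 12 + 15 + 9 == 157
        fv = extract_features(np.random.default_rng(0).random((20, 20)), (10, 10), spec)
        assert fv.values.shape == (157,)

    def test_constant_image_identical_vectors(self, micro_spec):
        img = np.full((16, 16), 9.0)
        a = extract_features(img, (3, 4), micro_spec).values
        b = extract_features(img, (12, 8), micro_spec).values
        np.testing.assert_array_equal(a, b)

    def test_spans_slice_back_to_extractors(self, rng, micro_spec):
        img = rng.uniform(0, 255, size=(18, 18))
        i, j = 9, 8
        fv = extract_features(img, (i, j), micro_spec)
        h2, w2 = micro_spec.h // 2, micro_spec.w // 2
        win = img[i - h2 : i + h2 + 1, j - w2 : j + w2 + 1]
        np.testing.assert_allclose(fv.span("haar"), haar_features(win))
        hog_win = img[i - h2 - 1 : i + h2 + 2, j - w2 - 1 : j + w2 + 2]
        np.testing.assert_allclose(fv.span("hog"), hog_feature(hog_win, micro_spec.hog_bins))
        q = quantize_levels(img, micro_spec.glcm_levels)
        qwin = q[i - h2 : i + h2 + 1, j - w2 : j + w2 + 1]
        d, theta = micro_spec.glcm_offsets[0]
        np.testing.assert_allclose(
            fv.span("glcm"), glcm_statistics(glcm_matrix(qwin, d, theta, micro_spec.glcm_levels))
        )

    def test_feature_maps_match_per_pixel_path(self, rng, micro_spec):
        img = rng.uniform(0, 255, size=(15, 17))
        maps = feature_maps(img, micro_spec)
        flat = maps.reshape(maps.shape[0], -1)
        for i, j in [(0, 0), (0, 16), (14, 0), (14, 16), (7, 9), (2, 13)]:
            fv = extract_features(img, (i, j), micro_spec)
            np.testing.assert_allclose(flat[:, i * 17 + j], fv.values, atol=1e-9)

    def test_translation_consistency(self, rng, micro_spec):
        img = rng.uniform(0, 255, size=(40, 40))
        shifted = np.roll(img, (2, 3), axis=(0, 1))
        a = extract_features(img, (20, 20), micro_spec).values
        b = extract_features(shifted, (22, 23), micro_spec).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_intensity_shift_invariance(self, rng, micro_spec):
        img = rng.uniform(0, 200, size=(20, 20))
        a = extract_features(img, (10, 10), micro_spec)
        b = extract_features(img + 31.0, (10, 10), micro_spec)
        for span in ("lbp", "glcm", "hog"):
            np.testing.assert_allclose(a.span(span), b.span(span), atol=1e-9)
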