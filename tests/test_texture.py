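"""Hankel embedding, quantization, GLCM and Haralick feature correctness.

The Haralick implementation is checked against an independently coded
literal-formula oracle (plain Python loops over the level indices), and
GLCM counting against scikit-image's graycomatrix.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from eegtexture import (
    GLCM,
    HARALICK_FEATURE_NAMES,
    HankelTextureExtractor,
    compute_glcm,
    extract_subject,
    hankelize,
    haralick_features,
    quantize,
    segment,
)

from conftest import make_recording


# ---------------------------------------------------------------------------
# independent oracle: literal double/marginal sums, plain loops, 1-based levels
# ---------------------------------------------------------------------------

def haralick_oracle(p: np.ndarray) -> dict:
    G = p.shape[0]
    px = [sum(p[i][j] for j in range(G)) for i in range(G)]
    py = [sum(p[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum((i + 1) * px[i] for i in range(G))
    mu_y = sum((j + 1) * py[j] for j in range(G))
    sx = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(G)))
    sy = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(G)))
    psum = {k: 0.0 for k in range(2, 2 * G + 1)}
    pdiff = {k: 0.0 for k in range(0, G)}
    for i in range(G):
        for j in range(G):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    hx, hy = ent(px), ent(py)
    hxy = ent(p.ravel())
    hxy1 = -sum(
        p[i][j] * math.log(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if px[i] * py[j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(G) for j in range(G)])

    out = {}
    out["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(G) for j in range(G)
    )
    out["contrast"] = sum(
        (i - j) ** 2 * p[i][j] for i in range(G) for j in range(G)
    )
    out["correlation"] = (
        (out["autocorrelation"] - mu_x * mu_y) / (sx * sy) if sx * sy > 0 else 0.0
    )
    out["cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(G) for j in range(G)
    )
    out["cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(G) for j in range(G)
    )
    out["dissimilarity"] = sum(
        abs(i - j) * p[i][j] for i in range(G) for j in range(G)
    )
    out["energy"] = sum(p[i][j] ** 2 for i in range(G) for j in range(G))
    out["entropy"] = hxy
    out["homogeneity"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G)
    )
    out["inverse_difference"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(G) for j in range(G)
    )
    out["max_probability"] = p.max()
    out["sum_average"] = sum(k * psum[k] for k in psum)
    out["sum_entropy"] = ent(psum.values())
    out["sum_variance"] = sum((k - out["sum_average"]) ** 2 * psum[k] for k in psum)
    out["sum_of_squares_variance"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(G) for j in range(G)
    )
    out["difference_entropy"] = ent(pdiff.values())
    dmean = sum(k * pdiff[k] for k in pdiff)
    out["difference_variance"] = sum((k - dmean) ** 2 * pdiff[k] for k in pdiff)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


def glcm_from_p(p, total=1000):
    counts = np.round(np.asarray(p, dtype=float) * total).astype(int)
    g = GLCM(counts=counts, offset=(0, 1))
    return g


class TestSegment:
    def test_truncates_remainder(self):
        windows = segment(np.arange(503), n_windows=50)
        assert windows.shape == (50, 10)
        assert windows[-1][-1] == 499  # samples 500..502 dropped

    def test_unit_windows(self):
        assert segment(np.arange(50), 50).shape == (50, 1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            segment(np.arange(49), 50)


class TestHankelize:
    def test_three_point_example(self):
        np.testing.assert_array_equal(
            hankelize([1, 2, 3]), [[1, 2, 3], [2, 3, 2], [3, 2, 1]]
        )

    def test_singleton_and_pair(self):
        np.testing.assert_array_equal(hankelize([5]), [[5]])
        np.testing.assert_array_equal(hankelize([3, 7]), [[3, 7], [7, 3]])

    @settings(max_examples=100, deadline=None)
    @given(
        arrays(
            np.float64,
            st.integers(2, 30),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_antidiagonals_constant_first_col_last_row(self, x):
        H = hankelize(x)
        L = x.size
        i, j = np.indices((L, L))
        for s in range(2 * L - 1):
            vals = H[i + j == s]
            assert np.all(vals == vals[0])
        np.testing.assert_array_equal(H[:, 0], x)
        np.testing.assert_array_equal(H[-1, :], x[::-1])


class TestQuantize:
    def test_linear_scaling_example(self):
        q = quantize(np.array([[0.0, 3.5, 7.0]]), levels=8, gray_limits=(0, 7))
        np.testing.assert_array_equal(q.values, [[1, 5, 8]])

    def test_constant_image_maps_to_level_one(self):
        q = quantize(np.full((4, 4), 2.5), levels=8)
        assert np.all(q.values == 1)

    def test_limits_clamped(self):
        q = quantize(np.array([[-10.0, 0.0, 7.0, 99.0]]), levels=8, gray_limits=(0, 7))
        assert q.values[0, 0] == 1 and q.values[0, -1] == 8

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((12, 12))
        base = quantize(img).values
        for c in (1e-3, 7.2, 1e4):
            np.testing.assert_array_equal(quantize(c * img).values, base)


class TestGLCM:
    def test_hand_enumerated_example(self):
        q = np.array([[1, 1, 2], [1, 2, 2], [2, 2, 2]])
        g = compute_glcm(q, offset=(0, 1), levels=2)
        np.testing.assert_array_equal(g.counts, [[1, 2], [0, 3]])

    def test_count_conservation_horizontal(self):
        rng = np.random.default_rng(1)
        for L in (2, 5, 17):
            q = rng.integers(1, 9, size=(L, L))
            g = compute_glcm(q, offset=(0, 1), levels=8)
            assert g.counts.sum() == L * (L - 1)

    @pytest.mark.parametrize("offset", [(1, 0), (1, 1), (-1, 1), (0, 2), (2, -1)])
    def test_count_conservation_any_offset(self, offset):
        rng = np.random.default_rng(2)
        q = rng.integers(1, 5, size=(9, 9))
        g = compute_glcm(q, offset=offset, levels=4)
        # brute-force enumeration of in-bounds pairs
        dr, dc = offset
        expected = sum(
            1
            for r in range(9)
            for c in range(9)
            if 0 <= r + dr < 9 and 0 <= c + dc < 9
        )
        assert g.counts.sum() == expected

    def test_constant_image_single_cell(self):
        g = compute_glcm(np.ones((6, 6), dtype=int), offset=(0, 1), levels=8)
        assert g.counts[0, 0] == 30
        assert g.counts.sum() == 30

    def test_matches_scikit_image(self):
        skimage_feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(3)
        q = rng.integers(1, 9, size=(20, 20))
        ours = compute_glcm(q, offset=(0, 1), levels=8).counts
        theirs = skimage_feature.graycomatrix(
            (q - 1).astype(np.uint8), distances=[1], angles=[0], levels=8
        )[:, :, 0, 0]
        np.testing.assert_array_equal(ours, theirs)

    def test_symmetric_counts(self):
        rng = np.random.default_rng(4)
        q = rng.integers(1, 5, size=(8, 8))
        g = compute_glcm(q, offset=(0, 1), levels=4, symmetric=True)
        assert np.array_equal(g.counts, g.counts.T)
        assert g.counts.sum() == 2 * 8 * 7

    def test_marginals_sum_to_one(self):
        rng = np.random.default_rng(5)
        q = rng.integers(1, 9, size=(10, 10))
        g = compute_glcm(q, levels=8)
        assert g.normalized.sum() == pytest.approx(1.0)
        assert g.px.sum() == pytest.approx(1.0)
        assert g.py.sum() == pytest.approx(1.0)
        assert g.p_sum.sum() == pytest.approx(1.0)
        assert g.p_diff.sum() == pytest.approx(1.0)

    def test_image_too_small_for_offset(self):
        with pytest.raises(ValueError, match="too small"):
            compute_glcm(np.ones((1, 1), dtype=int), offset=(0, 1), levels=2)
        with pytest.raises(ValueError, match="nonzero"):
            compute_glcm(np.ones((3, 3), dtype=int), offset=(0, 0), levels=2)


class TestHaralick:
    def test_degenerate_single_cell(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 0] = 42
        v = dict(zip(HARALICK_FEATURE_NAMES,
                     haralick_features(GLCM(counts, offset=(0, 1)))))
        assert v["contrast"] == 0
        assert v["dissimilarity"] == 0
        assert v["energy"] == 1
        assert v["entropy"] == 0
        assert v["max_probability"] == 1
        assert v["homogeneity"] == 1
        assert v["correlation"] == 0  # zero marginal variance convention

    def test_uniform_closed_forms(self):
        v = dict(zip(HARALICK_FEATURE_NAMES,
                     haralick_features(GLCM(np.ones((8, 8), dtype=int), (0, 1)))))
        assert v["energy"] == pytest.approx(1 / 64)
        assert v["entropy"] == pytest.approx(np.log(64))
        assert v["max_probability"] == pytest.approx(1 / 64)

    def test_two_level_hand_example(self):
        g = glcm_from_p([[0.5, 0.25], [0.0, 0.25]], total=4)
        v = dict(zip(HARALICK_FEATURE_NAMES, haralick_features(g)))
        assert v["contrast"] == pytest.approx(0.25)
        assert v["dissimilarity"] == pytest.approx(0.25)
        assert v["energy"] == pytest.approx(0.375)
        assert v["max_probability"] == pytest.approx(0.5)

    @pytest.mark.parametrize("levels", [2, 4, 8])
    def test_matches_literal_oracle_on_random_glcms(self, levels):
        rng = np.random.default_rng(123)
        for _ in range(100):
            counts = rng.integers(0, 20, size=(levels, levels))
            if counts.sum() == 0:
                counts[0, 0] = 1
            g = GLCM(counts=counts, offset=(0, 1))
            ours = dict(zip(HARALICK_FEATURE_NAMES, haralick_features(g)))
            oracle = haralick_oracle(g.normalized)
            for name in HARALICK_FEATURE_NAMES:
                assert ours[name] == pytest.approx(
                    oracle[name], rel=1e-10, abs=1e-12
                ), name

    def test_invariant_ranges(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = rng.integers(0, 50, size=(8, 8))
            counts[0, 0] += 1
            v = dict(zip(HARALICK_FEATURE_NAMES,
                         haralick_features(GLCM(counts, (0, 1)))))
            assert 0 < v["energy"] <= 1
            assert v["entropy"] >= 0
            assert 0 < v["max_probability"] <= 1
            assert v["contrast"] >= 0
            assert 0 <= v["imc2"] <= 1


class TestExtractSubject:
    @pytest.mark.parametrize(
        "n_channels,n_windows,expected",
        [(1, 3, 57), (2, 3, 114), (3, 5, 285)],
    )
    def test_vector_length(self, n_channels, n_windows, expected):
        rec = make_recording(n_channels=n_channels, n_samples=300)
        vec, fids = extract_subject(rec, n_windows=n_windows)
        assert vec.shape == (expected,)
        assert len(fids) == expected

    def test_feature_id_ordering(self):
        rec = make_recording(n_channels=2, n_samples=120)
        _, fids = extract_subject(rec, n_windows=3)
        assert fids[0] == ("ch00", 0, "autocorrelation")
        assert fids[19] == ("ch00", 1, "autocorrelation")
        assert fids[3 * 19] == ("ch01", 0, "autocorrelation")
        assert fids[-1] == ("ch01", 2, "sum_variance")

    def test_window_scaling_invariance(self):
        rec = make_recording(n_channels=1, n_samples=200, seed=6)
        scaled = make_recording(n_channels=1, n_samples=200, seed=6)
        scaled.data *= 250.0
        v1, _ = extract_subject(rec, n_windows=4)
        v2, _ = extract_subject(scaled, n_windows=4)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_short_channel_names_offender(self):
        rec = make_recording(n_channels=2, n_samples=30)
        with pytest.raises(ValueError, match="ch00"):
            extract_subject(rec, n_windows=50)


class TestHankelTextureExtractor:
    def test_sklearn_contract(self):
        ext = HankelTextureExtractor(n_windows=4, levels=8)
        params = ext.get_params()
        assert params["n_windows"] == 4
        ext.set_params(n_windows=3)
        assert ext.n_windows == 3

    def test_transform_matrix_input(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((5, 2, 120))
        ext = HankelTextureExtractor(n_windows=3).fit(X)
        out = ext.transform(X)
        assert out.shape == (5, 2 * 3 * 19)
        names = ext.get_feature_names_out()
        assert names[0] == "ch00.0.autocorrelation"

    def test_matches_extract_subject(self):
        rec = make_recording(n_channels=2, n_samples=120, seed=13)
        ext = HankelTextureExtractor(n_windows=3).fit([rec])
        out = ext.transform([rec])
        vec, _ = extract_subject(rec, n_windows=3)
        np.testing.assert_array_equal(out[0], vec)
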