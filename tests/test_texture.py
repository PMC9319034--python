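"""Co-occurrence matrices and the five Delta-E-weighted statistics,
checked against brute-force pair-enumeration and literal-formula oracles."""

import numpy as np
import pytest

from dermccm import colorspace as cs
from dermccm import palette as pal
from dermccm import texture as tx

from conftest import make_lab_palette


def brute_force_counts(idx, n, offsets, symmetric):
    H, W = idx.shape
    cnt = np.zeros((n, n), dtype=np.int64)
    for dy, dx in offsets:
        for y in range(H):
            for x in range(W):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < H and 0 <= x2 < W:
                    cnt[idx[y, x], idx[y2, x2]] += 1
                    if symmetric:
                        cnt[idx[y2, x2], idx[y, x]] += 1
    return cnt


def brute_force_five_stats(P, coords, dE):
    """Literal double-loop transcription of the five formulas."""
    n = P.shape[0]
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] != n:
        coords = coords.T
    H = sum(P[i, j] / (1 + dE(i, j) ** 2) for i in range(n) for j in range(n))
    mu = sum(coords[i] * P[i, j] for i in range(n) for j in range(n))
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    mu_i = sum(coords[i] * p_row[i] for i in range(n))
    mu_j = sum(coords[j] * p_col[j] for j in range(n))
    d_i = [np.linalg.norm(coords[i] - mu_i) for i in range(n)]
    d_j = [np.linalg.norm(coords[j] - mu_j) for j in range(n)]
    var = sum(d_i[i] ** 2 * P[i, j] for i in range(n) for j in range(n))
    s_i = np.sqrt(sum(p_row[i] * d_i[i] ** 2 for i in range(n)))
    s_j = np.sqrt(sum(p_col[j] * d_j[j] ** 2 for j in range(n)))
    if s_i * s_j > 0:
        rho = sum(
            d_i[i] * d_j[j] * P[i, j] for i in range(n) for j in range(n)
        ) / (s_i * s_j)
    else:
        rho = 0.0
    S = -sum(P[i, j] * np.log(P[i, j]) for i in range(n) for j in range(n) if P[i, j] > 0)
    return H, mu, var, rho, S


class TestOffsetSpec:
    def test_zero_offset_rejected(self):
        with pytest.raises(tx.TextureError):
            tx.OffsetSpec(((0, 0),))

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(tx.TextureError):
            tx.OffsetSpec(((0, 1), (0, 1)))


class TestGLCM:
    def test_two_by_two_example(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        m = tx.compute_glcm(img, levels=2, value_range=(0, 1),
                            spec=tx.OffsetSpec(((0, 1),), symmetric=True))
        assert np.allclose(m.P, [[0.5, 0], [0, 0.5]])

    def test_constant_image_single_diagonal_entry(self):
        m = tx.compute_glcm(np.full((5, 5), 30.0), levels=8, value_range=(0, 100))
        assert m.P.sum() == pytest.approx(1.0)
        assert np.count_nonzero(m.P) == 1
        k = int((8 * 30) // 100)
        assert m.P[k, k] == pytest.approx(1.0)

    def test_normalization_and_symmetry(self, rng):
        img = rng.uniform(0, 100, (12, 15))
        m = tx.compute_glcm(img, levels=6)
        assert m.P.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(m.P, m.P.T)

    def test_matches_skimage_single_offset(self, rng):
        from skimage.feature import graycomatrix

        idx = rng.integers(0, 4, (10, 10))
        m = tx.compute_glcm(idx.astype(float), levels=4, value_range=(0, 4),
                            spec=tx.OffsetSpec(((0, 1),), symmetric=True))
        ref = graycomatrix(idx.astype(np.uint8), [1], [0], levels=4,
                           symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(m.P, ref)

    def test_offset_larger_than_image_rejected(self):
        with pytest.raises(tx.TextureError):
            tx.compute_glcm(np.zeros((3, 3)), levels=2, value_range=(0, 1),
                            spec=tx.OffsetSpec(((0, 5),)))


class TestGLCMFeatures:
    def test_constant_image(self):
        m = tx.compute_glcm(np.full((6, 6), 10.0), levels=4, value_range=(0, 100))
        f = tx.glcm_features(m)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.variance == pytest.approx(0.0)
        assert f.correlation == 0.0
        assert f.entropy == pytest.approx(0.0)

    def test_checkerboard_entropy_ln2(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        m = tx.compute_glcm(board.astype(float), levels=2, value_range=(0, 1),
                            spec=tx.OffsetSpec(((0, 1), (-1, 0)), symmetric=True))
        # every 4-neighbor pair straddles the two levels
        assert np.allclose(np.diag(m.P), 0.0)
        f = tx.glcm_features(m)
        assert f.entropy == pytest.approx(np.log(2))

    def test_random_image_matches_literal_formulas(self, rng):
        img = rng.uniform(0, 100, (8, 8))
        m = tx.compute_glcm(img, levels=5)
        f = tx.glcm_features(m)
        H, mu, var, rho, S = brute_force_five_stats(
            m.P, np.arange(5, dtype=float)[:, None], lambda i, j: abs(i - j)
        )
        assert f.homogeneity == pytest.approx(H)
        assert f.mean_color[0] == pytest.approx(float(mu[0]))
        assert f.variance == pytest.approx(var)
        assert f.correlation == pytest.approx(rho)
        assert f.entropy == pytest.approx(S)

    def test_kind_mismatch_rejected(self, gray_palette):
        q = pal.QuantizedImage(indices=np.zeros((4, 4), dtype=int), palette=gray_palette)
        m = tx.compute_ccm(q)
        with pytest.raises(tx.TextureError):
            tx.glcm_features(m)


class TestCCM:
    def test_constant_quantized_image(self, gray_palette):
        q = pal.QuantizedImage(indices=np.full((6, 6), 3), palette=gray_palette)
        m = tx.compute_ccm(q)
        assert m.P[3, 3] == pytest.approx(1.0)
        assert np.count_nonzero(m.P) == 1

    def test_vertical_stripes_off_diagonal(self, gray_palette):
        idx = np.tile([0, 1], (4, 3))[:, :6]
        q = pal.QuantizedImage(indices=idx, palette=gray_palette)
        m = tx.compute_ccm(q, tx.OffsetSpec(((0, 1),), symmetric=True))
        assert m.P[0, 1] == pytest.approx(0.5)
        assert m.P[1, 0] == pytest.approx(0.5)
        assert m.P[0, 0] == m.P[1, 1] == 0

    def test_matches_brute_force_enumeration(self, rng, gray_palette):
        spec = tx.OffsetSpec()
        for _ in range(20):
            h, w = rng.integers(2, 17, 2)
            idx = rng.integers(0, 5, (h, w))
            q = pal.QuantizedImage(indices=idx, palette=gray_palette)
            m = tx.compute_ccm(q, spec)
            cnt = brute_force_counts(idx, 5, spec.offsets, spec.symmetric)
            assert np.allclose(m.P, cnt / cnt.sum())


class TestDistanceTable:
    def test_zero_diagonal_symmetric(self, rgb_palette):
        D = tx.ccm_distance_table(rgb_palette)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)

    def test_spot_check_against_scalar_delta_e(self, rgb_palette):
        D = tx.ccm_distance_table(rgb_palette)
        c = rgb_palette.colors
        assert D[0, 3] == pytest.approx(float(cs.delta_e_lab(c[0], c[3])))


class TestCCMFeatures:
    def test_constant_image_conventions(self, gray_palette):
        q = pal.QuantizedImage(indices=np.full((6, 6), 2), palette=gray_palette)
        f = tx.ccm_features(tx.compute_ccm(q))
        assert f.homogeneity == pytest.approx(1.0)
        assert np.allclose(f.mean_color, gray_palette.colors[2])
        assert f.variance == pytest.approx(0.0)
        assert f.correlation == 0.0  # sigma = 0 convention
        assert f.entropy == pytest.approx(0.0)

    def test_two_color_checkerboard_closed_form(self):
        d = 7.0
        p = make_lab_palette([[40, 0, 0], [40 + d, 0, 0]])
        board = np.indices((8, 8)).sum(axis=0) % 2
        q = pal.QuantizedImage(indices=board, palette=p)
        m = tx.compute_ccm(q, tx.OffsetSpec(((0, 1), (-1, 0)), symmetric=True))
        f = tx.ccm_features(m)
        # all mass is off-diagonal at distance d
        assert f.homogeneity == pytest.approx(1.0 / (1.0 + d * d))
        assert f.entropy == pytest.approx(np.log(2))
        # each color holds half the marginal mass -> variance = (d/2)^2
        assert f.variance == pytest.approx((d / 2) ** 2)
        assert np.allclose(f.mean_color, [40 + d / 2, 0, 0])

    def test_random_matches_literal_formulas(self, rng, rgb_palette):
        idx = rng.integers(0, 5, (9, 9))
        q = pal.QuantizedImage(indices=idx, palette=rgb_palette)
        m = tx.compute_ccm(q)
        f = tx.ccm_features(m)
        coords = rgb_palette.colors
        D = rgb_palette.distance_table()
        H, mu, var, rho, S = brute_force_five_stats(m.P, coords, lambda i, j: D[i, j])
        assert f.homogeneity == pytest.approx(H)
        assert np.allclose(f.mean_color, mu)
        assert f.variance == pytest.approx(var)
        assert f.correlation == pytest.approx(rho)
        assert f.entropy == pytest.approx(S)

    def test_palette_relabeling_invariance(self, rng, rgb_palette):
        idx = rng.integers(0, 5, (8, 8))
        perm = np.array([3, 0, 4, 2, 1])
        permuted = pal.Palette(
            centroids=tuple(rgb_palette.centroids[i] for i in perm), space="lab"
        )
        inv = np.argsort(perm)
        f1 = tx.ccm_features(tx.compute_ccm(
            pal.QuantizedImage(indices=idx, palette=rgb_palette)))
        f2 = tx.ccm_features(tx.compute_ccm(
            pal.QuantizedImage(indices=inv[idx], palette=permuted)))
        for attr in ("homogeneity", "variance", "correlation", "entropy"):
            assert abs(getattr(f1, attr) - getattr(f2, attr)) < 1e-12
        assert np.allclose(f1.mean_color, f2.mean_color)

    def test_entropy_and_homogeneity_ranges(self, rng, rgb_palette):
        for _ in range(10):
            idx = rng.integers(0, 5, (10, 10))
            f = tx.ccm_features(tx.compute_ccm(
                pal.QuantizedImage(indices=idx, palette=rgb_palette)))
            assert 0 < f.homogeneity <= 1
            assert 0 <= f.entropy <= np.log(25)
            assert f.variance >= 0

    def test_detached_palette_rejected(self, gray_palette):
        q = pal.QuantizedImage(indices=np.zeros((4, 4), dtype=int), palette=gray_palette)
        m = tx.compute_ccm(q)
        bad = tx.CooccurrenceMatrix(P=m.P, spec=m.spec, kind="color", palette=None)
        with pytest.raises(tx.TextureError):
            tx.ccm_features(bad)

    def test_glcm_reduces_to_ccm_on_unit_spaced_grays(self, rng, gray_palette):
        """With centroids spaced exactly 1 apart in the working space,
        Delta-E(C_i, C_j) = |i - j| and the CCM statistics coincide with
        the GLCM statistics of the same index map."""
        idx = rng.integers(0, 5, (12, 12))
        fc = tx.ccm_features(tx.compute_ccm(
            pal.QuantizedImage(indices=idx, palette=gray_palette)))
        fg = tx.glcm_features(tx.compute_glcm(
            idx.astype(float), levels=5, value_range=(0, 5)))
        assert fc.homogeneity == pytest.approx(fg.homogeneity)
        assert fc.variance == pytest.approx(fg.variance)
        assert fc.correlation == pytest.approx(fg.correlation)
        assert fc.entropy == pytest.approx(fg.entropy)
        assert fc.mean_color[0] == pytest.approx(fg.mean_color[0])


class TestImageFeatures:
    def test_constant_image_both_modes(self, rgb_palette):
        img = np.full((8, 8, 3), 0.4)
        for mode in ("ccm", "glcm_L"):
            rec = tx.image_features(img, rgb_palette, mode=mode)
            assert rec["homogeneity"] == pytest.approx(1.0)
            assert rec["variance"] == pytest.approx(0.0)
            assert rec["entropy"] == pytest.approx(0.0)

    def test_rotation_invariance_with_4dir_offsets(self, rng, rgb_palette):
        img = rng.random((10, 10, 3))
        a = tx.image_features(img, rgb_palette, mode="ccm")
        b = tx.image_features(np.rot90(img).copy(), rgb_palette, mode="ccm")
        for k in tx.FEATURE_NAMES:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_matches_manual_pipeline(self, rgb_palette):
        img = np.zeros((6, 6, 3))
        img[:, ::2] = rgb_palette.srgb[0]
        img[:, 1::2] = rgb_palette.srgb[2]
        spec = tx.OffsetSpec(((0, 1),), symmetric=True)
        rec = tx.image_features(img, rgb_palette, mode="ccm", spec=spec)
        q = pal.quantize(img, rgb_palette)
        manual = tx.ccm_features(tx.compute_ccm(q, spec)).as_record()
        for k in tx.FEATURE_NAMES:
            assert rec[k] == pytest.approx(manual[k])

    def test_unknown_mode_rejected(self, rgb_palette):
        with pytest.raises(tx.TextureError):
            tx.image_features(np.zeros((4, 4, 3)), rgb_palette, mode="wavelet")
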