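"""GLCM / first-order feature unit tests against hand and brute-force oracles."""

import numpy as np
import pytest

from sonotexture.texture import (
    GLCMConfig,
    GrayLevelCooccurrence,
    compute_glcm,
    extract_features,
    first_order,
    haralick,
    quantize,
    FIRST_ORDER_NAMES,
    HARALICK_NAMES,
)
from sonotexture.synthetic import make_texture_patch
from sonotexture.types import ImagePatch


def checkerboard(n=4):
    return (np.indices((n, n)).sum(axis=0) % 2).astype(np.uint8)


def random_glcm(rng, levels):
    """A random normalized co-occurrence object (not necessarily symmetric)."""
    p = rng.random((levels, levels))
    p /= p.sum()
    return GrayLevelCooccurrence(
        p=p, levels=levels, distance=1, angles=(0.0,), symmetric=False,
        per_direction=p[:, :, None],
    )


def naive_haralick(glcm):
    """Independent double-loop evaluation of every Haralick descriptor."""
    p = glcm.p
    G = glcm.levels
    px = [sum(p[i][j] for j in range(G)) for i in range(G)]
    py = [sum(p[i][j] for i in range(G)) for j in range(G)]
    psum = [0.0] * (2 * G - 1)
    pdiff = [0.0] * G
    for i in range(G):
        for j in range(G):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    def H(dist):
        return -sum(q * np.log2(q) for q in dist if q > 0)

    asm = sum(p[i][j] ** 2 for i in range(G) for j in range(G))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(G) for j in range(G))
    mx = sum(i * px[i] for i in range(G))
    my = sum(j * py[j] for j in range(G))
    sx = np.sqrt(sum((i - mx) ** 2 * px[i] for i in range(G)))
    sy = np.sqrt(sum((j - my) ** 2 * py[j] for j in range(G)))
    corr = 0.0
    if sx > 0 and sy > 0:
        corr = (sum(i * j * p[i][j] for i in range(G) for j in range(G)) - mx * my) / (sx * sy)
    variance = sum((i - mx) ** 2 * px[i] for i in range(G))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    savg = sum(k * psum[k] for k in range(2 * G - 1))
    svar = sum((k - savg) ** 2 * psum[k] for k in range(2 * G - 1))
    sent = H(psum)
    ent = H([p[i][j] for i in range(G) for j in range(G)])
    dmean = sum(d * pdiff[d] for d in range(G))
    dvar = sum((d - dmean) ** 2 * pdiff[d] for d in range(G))
    dent = H(pdiff)
    hx, hy = H(px), H(py)
    hxy1 = -sum(
        p[i][j] * np.log2(px[i] * py[j])
        for i in range(G) for j in range(G)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(G) for j in range(G)
        if px[i] * py[j] > 0
    )
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(1 - np.exp(-2 * np.log(2) * (hxy2 - ent)), 0.0))
    return dict(
        asm=asm, contrast=contrast, correlation=corr, variance=variance, idm=idm,
        sum_average=savg, sum_variance=svar, sum_entropy=sent, entropy=ent,
        difference_variance=dvar, difference_entropy=dent, imc1=imc1, imc2=imc2,
    )


class TestQuantize:
    def test_two_levels(self):
        q = quantize(np.array([[0, 255], [255, 0]]), levels=2)
        assert set(q.ravel()) == {0, 1}

    def test_constant_patch_maps_to_zero(self):
        q = quantize(np.full((4, 4), 77), levels=32)
        assert (q == 0).all()

    def test_uniform_range_bins_are_equal_width(self):
        x = np.arange(256).reshape(16, 16)
        q = quantize(x, levels=32)
        # brute-force: value v falls in bin floor(v/8), 255 clipped into 31
        expect = np.minimum(x // 8, 31)
        assert (q == expect).all()

    def test_level_bounds_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4)), levels=257)
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4)), levels=1)


class TestGLCM:
    def test_checkerboard_horizontal_hand_count(self):
        g = compute_glcm(checkerboard(), GLCMConfig(levels=2, angles=(0.0,)))
        assert g.p[0, 1] == pytest.approx(0.5)
        assert g.p[1, 0] == pytest.approx(0.5)
        assert g.p[0, 0] == 0.0 and g.p[1, 1] == 0.0

    def test_constant_patch_point_mass(self):
        g = compute_glcm(np.zeros((4, 4), dtype=np.uint8), GLCMConfig(levels=2))
        assert g.p[0, 0] == pytest.approx(1.0)

    def test_normalization_and_symmetry(self):
        rng = np.random.default_rng(1)
        q = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        g = compute_glcm(q, GLCMConfig(levels=8))
        assert g.p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g.p, g.p.T, atol=1e-15)
        assert g.p_x.sum() == pytest.approx(1.0)
        assert g.p_sum.sum() == pytest.approx(1.0)
        assert g.p_diff.sum() == pytest.approx(1.0)

    def test_average_matrix_is_mean_of_directions(self):
        rng = np.random.default_rng(2)
        q = rng.integers(0, 6, size=(10, 10)).astype(np.uint8)
        g = compute_glcm(q, GLCMConfig(levels=6))
        np.testing.assert_allclose(g.p, g.per_direction.mean(axis=2), atol=1e-15)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((1, 5), dtype=np.uint8), GLCMConfig(levels=2))


class TestHaralick:
    def test_checkerboard_hand_values(self):
        g = compute_glcm(checkerboard(), GLCMConfig(levels=2, angles=(0.0,)))
        h = haralick(g)
        assert h.asm == pytest.approx(0.5)
        assert h.contrast == pytest.approx(1.0)
        assert h.entropy == pytest.approx(1.0)
        assert h.correlation == pytest.approx(-1.0)
        assert h.sum_entropy == pytest.approx(0.0)
        assert h.difference_variance == pytest.approx(0.0)
        assert h.imc1 == pytest.approx(-1.0)

    def test_constant_patch_degenerate_values(self):
        g = compute_glcm(np.zeros((4, 4), dtype=np.uint8), GLCMConfig(levels=2))
        h = haralick(g)
        assert h.asm == pytest.approx(1.0)
        assert h.contrast == pytest.approx(0.0)
        assert h.idm == pytest.approx(1.0)
        assert h.entropy == pytest.approx(0.0)
        assert h.correlation == 0.0 and h.imc1 == 0.0  # degenerate conventions
        assert h.degenerate

    @pytest.mark.parametrize("levels", [2, 4, 9])
    def test_matches_naive_double_loop_oracle(self, levels):
        rng = np.random.default_rng(levels)
        for _ in range(25):
            g = random_glcm(rng, levels)
            mine = haralick(g)
            theirs = naive_haralick(g)
            for name, val in theirs.items():
                assert getattr(mine, name) == pytest.approx(val, abs=1e-12), name

    def test_gibbs_inequality_imc1_nonpositive(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            g = random_glcm(rng, int(rng.integers(2, 12)))
            assert haralick(g).imc1 <= 1e-12

    def test_imc2_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            h = haralick(random_glcm(rng, 6))
            assert 0.0 <= h.imc2 <= 1.0


class TestFirstOrder:
    def test_symmetric_sample(self):
        fo = first_order(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        assert fo.mean == pytest.approx(3.0)
        assert fo.median == pytest.approx(3.0)
        assert fo.skewness == pytest.approx(0.0, abs=1e-12)

    def test_uniform_levels_entropy(self):
        # 8 equally occupied levels -> 3 bits
        x = np.repeat(np.arange(8), 4).reshape(8, 4) * (255 / 7)
        fo = first_order(x, levels=8)
        assert fo.shannon_entropy == pytest.approx(3.0)

    def test_skewness_brute_force(self):
        fo = first_order(np.array([[0.0, 0.0], [0.0, 10.0]]))
        assert fo.skewness == pytest.approx(2 / np.sqrt(3), abs=1e-12)
        # m4 = (3*2.5^4 + 7.5^4)/4 = 820.3125, m2^2 = 351.5625
        assert fo.kurtosis_excess == pytest.approx(820.3125 / 351.5625 - 3, abs=1e-10)

    def test_constant_patch_flagged(self):
        fo = first_order(np.full((3, 3), 9.0))
        assert fo.degenerate
        assert fo.skewness == 0.0 and fo.kurtosis_excess == 0.0 and fo.shannon_entropy == 0.0


class TestInvariances:
    def patch(self, seed=0):
        rng = np.random.default_rng(seed)
        return rng.integers(10, 240, size=(20, 20)).astype(float)

    def test_transpose_invariance_full_direction_set(self):
        x = self.patch()
        a = haralick(compute_glcm(quantize(x), GLCMConfig()))
        b = haralick(compute_glcm(quantize(x.T), GLCMConfig()))
        for name in HARALICK_NAMES:
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-10), name

    def test_constant_shift_leaves_glcm_features_unchanged(self):
        x = self.patch(3) * 0.5 + 50  # keep room to shift
        a = haralick(compute_glcm(quantize(x)))
        b = haralick(compute_glcm(quantize(x + 30)))
        for name in HARALICK_NAMES:
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-10), name
        foa, fob = first_order(x), first_order(x + 30)
        assert fob.mean == pytest.approx(foa.mean + 30)
        assert fob.median == pytest.approx(foa.median + 30)


class TestExtractFeatures:
    def _patches(self, n=6):
        out = []
        combos = [(t, w) for t in ("placenta", "PUM", "FM") for w in ("20w", "30w")]
        for i, (t, w) in enumerate(combos[:n]):
            out.append(make_texture_patch(120, 25, 2, 0, 32, seed=i, tissue=t, window=w))
        return out

    def test_full_subject_arity(self):
        row = extract_features(self._patches(6))
        assert len(row) == 6 * 19
        assert not row.isna().any()
        assert "PUM_30w_glcm_imc1" in row.index

    def test_missing_patch_block_is_nan(self):
        row = extract_features(self._patches(5))  # drops FM_30w
        block = row.filter(like="FM_30w")
        assert block.isna().all()
        assert len(block) == 19

    def test_duplicate_patch_rejected(self):
        patches = self._patches(2) + self._patches(1)
        with pytest.raises(ValueError, match="duplicate"):
            extract_features(patches)

    def test_contrast_decreases_with_correlation_length(self):
        means = []
        for L in (1.0, 3.0):
            vals = [
                haralick(compute_glcm(quantize(
                    make_texture_patch(120, 30, L, 0, 64, seed=s).pixels
                ))).contrast
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[1] < means[0]
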