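"""Tests of parametric maps, quantization, and GLCM texture features,
including equivalence with an independent co-occurrence implementation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import refqus as rq
from refqus.agreement import FEATURE_NAMES
from refqus.texture import (
    INVALID_LEVEL,
    GLCMSpec,
    ParametricMap,
    compute_glcm,
    glcm_features,
    quantize_map,
    texture_of_map,
)


class _Box:
    def __init__(self, r, c, h, w):
        self.axial_start, self.lateral_start = r, c
        self.n_axial, self.n_lateral = h, w


class TestParametricMap:
    def test_two_overlapping_blocks_average(self):
        blocks = [_Box(0, 0, 2, 3), _Box(0, 2, 2, 3)]
        pm = rq.build_parametric_map([1.0, 3.0], blocks, (2, 5))
        assert np.all(pm.values[:, :2] == 1.0)
        assert np.all(pm.values[:, 2] == 2.0)  # overlap column
        assert np.all(pm.values[:, 3:] == 3.0)
        assert pm.valid_mask.all()

    def test_non_overlapping_tiling(self):
        blocks = [_Box(0, 0, 2, 2), _Box(2, 0, 2, 2)]
        pm = rq.build_parametric_map([5.0, -1.0], blocks, (4, 2))
        assert np.all(pm.values[:2] == 5.0) and np.all(pm.values[2:] == -1.0)

    def test_matches_brute_force_membership_oracle(self, rng):
        shape = (30, 25)
        blocks = [
            _Box(rng.integers(0, 20), rng.integers(0, 15), 8, 6) for _ in range(12)
        ]
        vals = rng.standard_normal(12)
        pm = rq.build_parametric_map(vals, blocks, shape)
        for i in range(shape[0]):
            for j in range(shape[1]):
                members = [
                    v
                    for v, b in zip(vals, blocks)
                    if b.axial_start <= i < b.axial_start + b.n_axial
                    and b.lateral_start <= j < b.lateral_start + b.n_lateral
                ]
                if members:
                    assert pm.valid_mask[i, j]
                    assert pm.values[i, j] == pytest.approx(np.mean(members))
                else:
                    assert not pm.valid_mask[i, j]

    def test_empty_grid_flagged(self):
        pm = rq.build_parametric_map([], [], (4, 4))
        assert pm.empty and not pm.valid_mask.any()


class TestQuantize:
    def test_identity_labeling(self):
        v = np.arange(16, dtype=float).reshape(4, 4)
        pm = ParametricMap(v, np.ones_like(v, dtype=bool))
        q = quantize_map(pm, 16)
        assert np.array_equal(q, np.arange(16).reshape(4, 4))

    def test_constant_map_single_level(self):
        v = np.full((3, 3), 2.5)
        q = quantize_map(ParametricMap(v, np.ones_like(v, bool)), 16)
        assert np.all(q == 0)

    def test_pigeonhole(self, rng):
        v = rng.standard_normal((20, 20))
        q = quantize_map(ParametricMap(v, np.ones_like(v, bool)), 16)
        assert np.unique(q).size <= 16

    def test_invalid_pixels_sentineled(self):
        v = np.arange(9, dtype=float).reshape(3, 3)
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        q = quantize_map(ParametricMap(v, mask), 4)
        assert q[0, 0] == INVALID_LEVEL

    @settings(derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        gain=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, seed, gain, offset):
        """Min–max quantization is invariant to a·x + b with a > 0."""
        v = np.random.default_rng(seed).normal(0, 1, (12, 12))
        mask = np.ones_like(v, bool)
        q1 = quantize_map(ParametricMap(v, mask), 16)
        q2 = quantize_map(ParametricMap(gain * v + offset, mask), 16)
        assert np.array_equal(q1, q2)


class TestGLCM:
    def test_hand_counted_fixture(self):
        """[[0,1],[0,1]], d=1, 0°: P(0,1)=P(1,0)=1/2 → CON=1, HOM=ENE=1/2, COR=−1."""
        levels = np.array([[0, 1], [0, 1]])
        P = compute_glcm(levels, 0, 1, GLCMSpec(n_levels=2))
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)
        con, cor, hom, ene = glcm_features(P)
        assert con == pytest.approx(1.0)
        assert hom == pytest.approx(0.5)
        assert ene == pytest.approx(0.5)
        assert cor == pytest.approx(-1.0)

    def test_constant_grid_single_diagonal_entry(self):
        P = compute_glcm(np.zeros((5, 5), int), 90, 2, GLCMSpec(n_levels=4))
        assert P[0, 0] == pytest.approx(1.0)
        con, cor, hom, ene = glcm_features(P)
        assert con == 0.0 and hom == pytest.approx(1.0) and ene == pytest.approx(1.0)
        assert np.isnan(cor)

    def test_normalized_and_symmetric(self, rng):
        levels = rng.integers(0, 16, (20, 30))
        for ang in (0, 45, 90, 135):
            for d in (1, 2, 3, 4):
                P = compute_glcm(levels, ang, d)
                assert P.sum() == pytest.approx(1.0)
                assert np.allclose(P, P.T)

    def test_invalid_pixels_never_paired(self):
        levels = np.array([[0, INVALID_LEVEL], [0, 1]])
        P = compute_glcm(levels, 0, 1, GLCMSpec(n_levels=2))
        # only the (0,1) pair in the bottom row is countable
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)

    def test_no_valid_pairs_returns_none(self):
        levels = np.full((3, 3), INVALID_LEVEL)
        assert compute_glcm(levels, 0, 1) is None
        assert compute_glcm(np.zeros((2, 2), int), 0, 3) is None  # offset too large

    def test_matches_skimage_counting(self, rng):
        """Our co-occurrence counting equals skimage.graycomatrix (symmetric,
        normalized) on fully valid maps, for all 16 offsets."""
        from skimage.feature import graycomatrix

        # skimage's row axis points the other way: its π/4 diagonal is our
        # 135° offset and vice versa (identical sets once symmetrised)
        angle_rad = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        for _ in range(5):
            levels = rng.integers(0, 16, (24, 18))
            for ang in (0, 45, 90, 135):
                for d in (1, 2, 3, 4):
                    ours = compute_glcm(levels, ang, d)
                    # our distances are per-axis steps; skimage's are Euclidean
                    d_sk = d * np.sqrt(2.0) if ang in (45, 135) else d
                    ref = graycomatrix(
                        levels.astype(np.uint8),
                        distances=[d_sk],
                        angles=[angle_rad[ang]],
                        levels=16,
                        symmetric=True,
                        normed=True,
                    )[:, :, 0, 0]
                    assert np.allclose(ours, ref, atol=1e-12)

    def test_features_match_brute_force_oracle(self, rng):
        """CON/COR/HOM/ENE agree with a double-loop evaluation to 1e-10."""
        for _ in range(20):
            levels = rng.integers(0, 8, (15, 15))
            P = compute_glcm(levels, 45, 2, GLCMSpec(n_levels=8))
            con = sum(
                P[i, j] * (i - j) ** 2 for i in range(8) for j in range(8)
            )
            hom = sum(
                P[i, j] / (1 + abs(i - j)) for i in range(8) for j in range(8)
            )
            ene = sum(P[i, j] ** 2 for i in range(8) for j in range(8))
            pi = P.sum(axis=1)
            mu = sum(i * pi[i] for i in range(8))
            var = sum((i - mu) ** 2 * pi[i] for i in range(8))
            cor = sum(
                P[i, j] * (i - mu) * (j - mu) for i in range(8) for j in range(8)
            ) / var
            c, r, h, e = glcm_features(P)
            assert c == pytest.approx(con, abs=1e-10)
            assert h == pytest.approx(hom, abs=1e-10)
            assert e == pytest.approx(ene, abs=1e-10)
            assert r == pytest.approx(cor, abs=1e-10)

    def test_energy_one_iff_single_cell(self, rng):
        P = np.zeros((4, 4))
        P[1, 1] = 1.0
        assert glcm_features(P)[3] == pytest.approx(1.0)
        # random multi-cell matrix: ENE strictly below 1
        Q = rng.uniform(0.1, 1.0, (4, 4))
        Q = (Q + Q.T) / 2
        Q /= Q.sum()
        assert glcm_features(Q)[3] < 1.0

    def test_contrast_zero_iff_diagonal(self, rng):
        D = np.diag(rng.uniform(0.1, 1.0, 5))
        D /= D.sum()
        assert glcm_features(D)[0] == 0.0
        Q = np.zeros((5, 5))
        Q[0, 1] = Q[1, 0] = 0.5
        assert glcm_features(Q)[0] > 0.0


class TestAggregate:
    def test_constant_map_textures(self):
        v = np.full((10, 10), 3.0)
        tex = texture_of_map(ParametricMap(v, np.ones_like(v, bool)))
        assert tex["con"] == 0.0
        assert tex["hom"] == pytest.approx(1.0)
        assert tex["ene"] == pytest.approx(1.0)
        assert np.isnan(tex["cor"])  # undefined on every GLCM, excluded

    def test_isotropic_map_angles_agree(self):
        """0° and 90° features agree on isotropic random maps (≥20 draws)."""
        rng = np.random.default_rng(123)
        diffs = []
        for _ in range(20):
            v = rng.normal(0, 1, (40, 40))
            pm = ParametricMap(v, np.ones_like(v, bool))
            levels = quantize_map(pm, 16)
            c0 = glcm_features(compute_glcm(levels, 0, 2))[0]
            c90 = glcm_features(compute_glcm(levels, 90, 2))[0]
            diffs.append(c0 - c90)
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.5)

    def test_feature_set_has_25_names(self):
        maps = {
            n: ParametricMap(np.random.default_rng(1).normal(0, 1, (12, 12)),
                             np.ones((12, 12), bool))
            for n in ("MBF", "SS", "SI", "ASD", "AAC")
        }
        tex = rq.aggregate_texture(maps)
        assert len(tex) == 20
        assert set(tex) | {"MBF", "SS", "SI", "ASD", "AAC"} == set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 25

    def test_affine_rescaling_leaves_textures_unchanged(self):
        rng = np.random.default_rng(9)
        v = rng.normal(0, 1, (30, 30))
        pm1 = ParametricMap(v, np.ones_like(v, bool))
        pm2 = ParametricMap(3.5 * v - 11.0, np.ones_like(v, bool))
        t1, t2 = texture_of_map(pm1), texture_of_map(pm2)
        for k in t1:
            assert t1[k] == pytest.approx(t2[k], abs=1e-12)
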