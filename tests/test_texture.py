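"""Texture matrices and features against exhaustive brute-force enumeration."""

import numpy as np
import pytest

from oracles import bf_glcm, bf_gldm, bf_glrlm, bf_glszm, bf_ngtdm
from radrep.features import (
    COARSENESS_CAP,
    DIRECTIONS_13,
    TextureMatrixSet,
    texture_features,
    texture_matrices,
)


class TestMatricesAgainstOracle:
    def test_glcm_hand_enumeration_1x1x3(self):
        levels = np.array([[[1, 1, 2]]])
        mats = texture_matrices(levels, 2)
        k = DIRECTIONS_13.index((0, 0, 1))
        m = mats.glcm[k]
        assert m[0, 0] == 2  # (1,1) both orders
        assert m[0, 1] == 1 and m[1, 0] == 1
        assert m.sum() == 4

    def test_uniform_roi_single_zone(self):
        levels = np.ones((3, 4, 2), dtype=int)
        mats = texture_matrices(levels, 1)
        assert mats.glszm.shape[0] == 1
        assert mats.glszm[0, -1] == 1  # one zone of size 24
        assert mats.glszm.sum() == 1

    @pytest.mark.parametrize("shape,n_levels", [((3, 3, 3), 2), ((4, 4, 4), 3), ((5, 5, 5), 4)])
    def test_all_matrices_match_brute_force(self, shape, n_levels, random_levels):
        levels = random_levels(shape, n_levels)
        mats = texture_matrices(levels, n_levels)

        for k, d in enumerate(DIRECTIONS_13):
            assert (mats.glcm[k] == bf_glcm(levels, n_levels, d)).all(), f"GLCM {d}"
            oracle = bf_glrlm(levels, n_levels, d, mats.glrlm.shape[2])
            assert (mats.glrlm[k] == oracle).all(), f"GLRLM {d}"

        assert (mats.glszm == bf_glszm(levels, n_levels, mats.glszm.shape[1])).all()
        assert (mats.gldm == bf_gldm(levels, n_levels)).all()
        s, n = bf_ngtdm(levels, n_levels)
        assert np.allclose(mats.ngtdm_s, s)
        assert (mats.ngtdm_n == n).all()

    def test_out_of_roi_neighbours_ignored(self):
        levels = np.array([[[1, 0, 1]]])  # gap breaks the run and the pair
        mats = texture_matrices(levels, 1)
        k = DIRECTIONS_13.index((0, 0, 1))
        assert mats.glcm[k].sum() == 0
        assert mats.glrlm[k, 0, 0] == 2  # two runs of length 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            texture_matrices(np.ones((2, 2, 2), dtype=int), 0)
        with pytest.raises(ValueError):
            texture_matrices(np.full((2, 2, 2), 5), 3)


class TestFeaturesAgainstFormulae:
    def test_single_entry_glcm_idm_is_one(self):
        levels = np.array([[[1, 1]]])
        feats = texture_features(texture_matrices(levels, 1))
        assert feats["glcm_inverse_difference_moment"] == pytest.approx(1.0)

    def test_uniform_roi_coarseness_capped(self):
        levels = np.ones((3, 3, 3), dtype=int)
        feats = texture_features(texture_matrices(levels, 1))
        assert feats["ngtdm_coarseness"] == COARSENESS_CAP

    def test_features_match_direct_formula_evaluation(self, random_levels):
        levels = random_levels((4, 4, 4), 3)
        mats = texture_matrices(levels, 3)
        feats = texture_features(mats)

        # GLCM: averaged per-direction direct sums
        idms, shades = [], []
        for k in range(len(DIRECTIONS_13)):
            m = mats.glcm[k].astype(float)
            if m.sum() == 0:
                continue
            p = m / m.sum()
            L = p.shape[0]
            idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
            mx = sum((i + 1) * p[i, j] for i in range(L) for j in range(L))
            my = sum((j + 1) * p[i, j] for i in range(L) for j in range(L))
            shade = sum(
                (i + 1 + j + 1 - mx - my) ** 3 * p[i, j] for i in range(L) for j in range(L)
            )
            idms.append(idm)
            shades.append(shade)
        assert feats["glcm_inverse_difference_moment"] == pytest.approx(np.mean(idms))
        assert feats["glcm_cluster_shade"] == pytest.approx(np.mean(shades))

        # GLRLM non-uniformities
        glns, rlns = [], []
        for k in range(len(DIRECTIONS_13)):
            m = mats.glrlm[k].astype(float)
            nr = m.sum()
            if nr == 0:
                continue
            glns.append(sum(m[i, :].sum() ** 2 for i in range(m.shape[0])) / nr)
            rlns.append(sum(m[:, j].sum() ** 2 for j in range(m.shape[1])) / nr)
        assert feats["glrlm_gray_level_non_uniformity"] == pytest.approx(np.mean(glns))
        assert feats["glrlm_run_length_non_uniformity"] == pytest.approx(np.mean(rlns))

        # GLSZM
        m = mats.glszm.astype(float)
        nz = m.sum()
        L, Z = m.shape
        sae = sum(m[i, j] / (j + 1) ** 2 for i in range(L) for j in range(Z)) / nz
        szn = sum(m[:, j].sum() ** 2 for j in range(Z)) / nz
        gln = sum(m[i, :].sum() ** 2 for i in range(L)) / nz
        lalgle = (
            sum(m[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(L) for j in range(Z)) / nz
        )
        assert feats["glszm_small_area_emphasis"] == pytest.approx(sae)
        assert feats["glszm_size_zone_non_uniformity"] == pytest.approx(szn)
        assert feats["glszm_size_zone_non_uniformity_normalized"] == pytest.approx(szn / nz)
        assert feats["glszm_gray_level_non_uniformity"] == pytest.approx(gln)
        assert feats["glszm_large_area_low_gray_level_emphasis"] == pytest.approx(lalgle)

        # GLDM
        m = mats.gldm.astype(float)
        nz = m.sum()
        dn = sum(m[:, d].sum() ** 2 for d in range(m.shape[1])) / nz
        gln = sum(m[i, :].sum() ** 2 for i in range(m.shape[0])) / nz
        assert feats["gldm_dependence_non_uniformity"] == pytest.approx(dn)
        assert feats["gldm_gray_level_non_uniformity"] == pytest.approx(gln)

        # NGTDM coarseness
        n_tot = mats.ngtdm_n.sum()
        denom = sum(
            mats.ngtdm_n[i] / n_tot * mats.ngtdm_s[i] for i in range(len(mats.ngtdm_n))
        )
        assert feats["ngtdm_coarseness"] == pytest.approx(1.0 / denom)

    def test_empty_matrices_flagged_as_nan(self):
        empty = TextureMatrixSet(
            glcm=np.zeros((13, 2, 2), dtype=np.int64),
            glrlm=np.zeros((13, 2, 1), dtype=np.int64),
            glszm=np.zeros((2, 1), dtype=np.int64),
            gldm=np.zeros((2, 27), dtype=np.int64),
            ngtdm_s=np.zeros(2),
            ngtdm_n=np.zeros(2, dtype=np.int64),
            n_levels=2,
        )
        feats = texture_features(empty)
        assert all(np.isnan(v) for v in feats.values())
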