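"""Scalar texture features from the texture-matrix families.

Per-direction features (GLCM, GLRLM) are computed on each of the 13
directional matrices and averaged over directions. Degenerate matrices
(no counts) yield NaN, flagged to the caller rather than raising.
"""

from __future__ import annotations

import numpy as np

from .texture_matrices import TextureMatrixSet

#: cap returned when the NGTDM coarseness denominator vanishes (uniform ROI)
COARSENESS_CAP = 1.0e6


# ------------------------------------------------------------------- GLCM
def _glcm_single(m: np.ndarray) -> dict[str, float]:
    total = m.sum()
    if total == 0:
        return {"glcm_inverse_difference_moment": np.nan, "glcm_cluster_shade": np.nan}
    p = m / total
    L = m.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    mu_x = float((ii * p).sum())
    mu_y = float((jj * p).sum())
    shade = float(((ii + jj - mu_x - mu_y) ** 3 * p).sum())
    return {"glcm_inverse_difference_moment": idm, "glcm_cluster_shade": shade}


# ------------------------------------------------------------------ GLRLM
def _glrlm_single(m: np.ndarray) -> dict[str, float]:
    nr = m.sum()
    if nr == 0:
        return {
            "glrlm_gray_level_non_uniformity": np.nan,
            "glrlm_run_length_non_uniformity": np.nan,
        }
    gln = float((m.sum(axis=1) ** 2).sum() / nr)
    rln = float((m.sum(axis=0) ** 2).sum() / nr)
    return {
        "glrlm_gray_level_non_uniformity": gln,
        "glrlm_run_length_non_uniformity": rln,
    }


# ------------------------------------------------------------------ GLSZM
def _glszm(m: np.ndarray) -> dict[str, float]:
    nz = m.sum()
    keys = (
        "glszm_small_area_emphasis",
        "glszm_size_zone_non_uniformity",
        "glszm_size_zone_non_uniformity_normalized",
        "glszm_gray_level_non_uniformity",
        "glszm_large_area_low_gray_level_emphasis",
    )
    if nz == 0:
        return {k: np.nan for k in keys}
    L, Z = m.shape
    i = np.arange(1, L + 1)[:, None]
    j = np.arange(1, Z + 1)[None, :]
    sae = float((m / j**2).sum() / nz)
    szn = float((m.sum(axis=0) ** 2).sum() / nz)
    glnu = float((m.sum(axis=1) ** 2).sum() / nz)
    lalgle = float((m * j**2 / i**2).sum() / nz)
    return {
        "glszm_small_area_emphasis": sae,
        "glszm_size_zone_non_uniformity": szn,
        "glszm_size_zone_non_uniformity_normalized": szn / float(nz),
        "glszm_gray_level_non_uniformity": glnu,
        "glszm_large_area_low_gray_level_emphasis": lalgle,
    }


# ------------------------------------------------------------------- GLDM
def _gldm(m: np.ndarray) -> dict[str, float]:
    nz = m.sum()
    if nz == 0:
        return {
            "gldm_dependence_non_uniformity": np.nan,
            "gldm_gray_level_non_uniformity": np.nan,
        }
    dn = float((m.sum(axis=0) ** 2).sum() / nz)
    gln = float((m.sum(axis=1) ** 2).sum() / nz)
    return {
        "gldm_dependence_non_uniformity": dn,
        "gldm_gray_level_non_uniformity": gln,
    }


# ------------------------------------------------------------------ NGTDM
def _ngtdm(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    total = n.sum()
    if total == 0:
        return {"ngtdm_coarseness": np.nan}
    p = n / total
    denom = float((p * s).sum())
    coarse = COARSENESS_CAP if denom == 0 else min(1.0 / denom, COARSENESS_CAP)
    return {"ngtdm_coarseness": coarse}


def texture_features(mats: TextureMatrixSet) -> dict[str, float]:
    """Named scalar features from a :class:`TextureMatrixSet`.

    GLCM and GLRLM features are averaged over the 13 directions.
    """
    def _dir_mean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else np.nan

    out: dict[str, float] = {}
    per_dir = [_glcm_single(mats.glcm[k]) for k in range(mats.glcm.shape[0])]
    for key in per_dir[0]:
        out[key] = _dir_mean([d[key] for d in per_dir])
    per_dir = [_glrlm_single(mats.glrlm[k]) for k in range(mats.glrlm.shape[0])]
    for key in per_dir[0]:
        out[key] = _dir_mean([d[key] for d in per_dir])
    out.update(_glszm(mats.glszm))
    out.update(_gldm(mats.gldm))
    out.update(_ngtdm(mats.ngtdm_s, mats.ngtdm_n))
    return out
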