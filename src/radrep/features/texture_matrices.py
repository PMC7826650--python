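"""Grey-level texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) in 3D.

All matrices are computed from a discretised ROI: an integer volume with grey
levels ``1..n_levels`` inside the mask and 0 outside. Neighbour relations use
the 13 unique 3D direction pairs at distance 1 (GLCM, GLRLM) or the full
26-connected neighbourhood (GLSZM zones, GLDM dependencies, NGTDM sums).
Voxels outside the ROI never contribute: they break runs, are excluded from
zones, and are ignored when averaging neighbour grey tones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

#: the 13 unique direction pairs of the 26-neighbourhood (positive half-space)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


@dataclass
class TextureMatrixSet:
    """The five texture-matrix families for one ROI.

    glcm : (13, L, L) symmetric co-occurrence counts per direction
    glrlm : (13, L, R) run-length counts per direction (R = longest run)
    glszm : (L, Z) size-zone counts (Z = largest zone size)
    gldm : (L, 27) dependence counts (column d = d dependent neighbours)
    ngtdm_s : (L,) per-level sums of |level - mean neighbour level|
    ngtdm_n : (L,) per-level voxel counts (voxels with >= 1 ROI neighbour)
    n_levels : L
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_n: np.ndarray
    n_levels: int


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Pairs (level_here, level_there) for all in-ROI voxel pairs at offset."""
    sl_a, sl_b = [], []
    for o in offset:
        if o > 0:
            sl_a.append(slice(0, -o if o else None))
            sl_b.append(slice(o, None))
        elif o < 0:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(0, o))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


def glcm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """(13, L, L) symmetrised co-occurrence counts at distance 1."""
    out = np.zeros((len(DIRECTIONS_13), n_levels, n_levels), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS_13):
        a, b = _shifted_pairs(levels, d)
        m = np.zeros((n_levels, n_levels), dtype=np.int64)
        np.add.at(m, (a - 1, b - 1), 1)
        out[k] = m + m.T
    return out


def glrlm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """(13, L, R) run-length counts: maximal same-level collinear ROI runs."""
    shape = levels.shape
    max_run = max(shape)
    out = np.zeros((len(DIRECTIONS_13), n_levels, max_run), dtype=np.int64)
    coords = np.argwhere(levels > 0)
    coord_set = {tuple(c): levels[tuple(c)] for c in coords}

    def level_at(p):
        return coord_set.get(p, 0)

    for k, d in enumerate(DIRECTIONS_13):
        for c in coords:
            p = tuple(c)
            lev = coord_set[p]
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if level_at(prev) == lev:
                continue  # not a run start
            length = 1
            nxt = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            while level_at(nxt) == lev:
                length += 1
                nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
            out[k, lev - 1, length - 1] += 1
    # trim trailing all-zero run lengths
    used = max(1, int(np.max(np.nonzero(out.sum(axis=(0, 1)))[0])) + 1) if out.any() else 1
    return out[:, :, :used]


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """(L, Z) size-zone counts: 26-connected same-level zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    n_vox = int((levels > 0).sum())
    out = np.zeros((n_levels, n_vox), dtype=np.int64)
    for lev in range(1, n_levels + 1):
        lab, nz = ndimage.label(levels == lev, structure=structure)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            out[lev - 1, s - 1] += 1
    used = max(1, int(np.max(np.nonzero(out.sum(axis=0))[0])) + 1) if out.any() else 1
    return out[:, :used]


def _neighbour_stack(levels: np.ndarray) -> np.ndarray:
    """(26, *shape) array of neighbour levels, 0 where out of grid/ROI."""
    padded = np.pad(levels, 1)
    stacks = []
    sz = levels.shape
    for d in OFFSETS_26:
        sl = tuple(slice(1 + o, 1 + o + n) for o, n in zip(d, sz))
        stacks.append(padded[sl])
    return np.stack(stacks)


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """(L, 27) dependence counts: column d = # of 26-neighbours within alpha."""
    neigh = _neighbour_stack(levels)
    roi = levels > 0
    dependent = (neigh > 0) & (np.abs(neigh - levels[None]) <= alpha)
    dep_count = dependent.sum(axis=0)
    out = np.zeros((n_levels, 27), dtype=np.int64)
    np.add.at(out, (levels[roi] - 1, dep_count[roi]), 1)
    return out


def ngtdm_components(levels: np.ndarray, n_levels: int):
    """Per-level sums s_i = sum |i - A_v| and counts n_i.

    ``A_v`` is the mean grey level of the in-ROI 26-neighbours of voxel v;
    voxels with no in-ROI neighbour are excluded from both s and n.
    """
    neigh = _neighbour_stack(levels)
    roi = levels > 0
    valid = neigh > 0
    cnt = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_neigh = np.where(cnt > 0, neigh.sum(axis=0) / np.maximum(cnt, 1), np.nan)
    use = roi & (cnt > 0)
    s = np.zeros(n_levels)
    n = np.zeros(n_levels, dtype=np.int64)
    diffs = np.abs(levels[use] - mean_neigh[use])
    np.add.at(s, levels[use] - 1, diffs)
    np.add.at(n, levels[use] - 1, 1)
    return s, n


def texture_matrices(levels: np.ndarray, n_levels: int) -> TextureMatrixSet:
    """Compute all five matrix families for a discretised ROI."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = np.asarray(levels)
    if levels.ndim != 3:
        raise ValueError("expected a 3D labelled volume")
    if levels.max(initial=0) > n_levels:
        raise ValueError("grey levels exceed n_levels")
    s, n = ngtdm_components(levels, n_levels)
    return TextureMatrixSet(
        glcm=glcm_matrix(levels, n_levels),
        glrlm=glrlm_matrix(levels, n_levels),
        glszm=glszm_matrix(levels, n_levels),
        gldm=gldm_matrix(levels, n_levels),
        ngtdm_s=s,
        ngtdm_n=n,
        n_levels=n_levels,
    )
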