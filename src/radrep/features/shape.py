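"""Shape features of a binary lesion mask.

Shape features depend only on the mask and the voxel size, never on image
intensities, so they are unaffected by intensity normalisation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

MESH_FEATURES = (
    "mesh_volume",
    "surface_area",
    "sphericity",
)


#: Gaussian pre-smoothing (voxels) applied to the mask before triangulation;
#: suppresses the staircase surface-area inflation of a raw binary isosurface
MESH_SMOOTHING_SIGMA = 0.7


def _mesh(mask: np.ndarray, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated 0.5-isosurface of the (zero-padded) mask, world units."""
    from scipy import ndimage

    padded = np.pad(mask.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, MESH_SMOOTHING_SIGMA)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            smoothed, level=0.5, spacing=tuple(voxel_size)
        )
        vol, _ = _mesh_volume_area(verts, faces)
    except (ValueError, RuntimeError):
        vol = 0.0
    # thin masks can be smoothed below the iso-level; fall back to the raw mask
    if vol < 0.5 * mask.sum() * float(np.prod(voxel_size)):
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=tuple(voxel_size)
        )
    return verts, faces

def _mesh_volume_area(verts: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    # signed tetrahedron volumes against the origin; orientation is consistent
    vol = abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()
    return float(vol), float(area)


def shape_features(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Volume, surface, sphericity, elongation, axis lengths, max diameter.

    ``voxel_volume`` is voxel count times the voxel volume. ``mesh_volume``
    and ``surface_area`` come from a triangulated isosurface of the mask.
    ``sphericity = (36 pi V^2)^(1/3) / A`` (1 for a perfect sphere).
    ``elongation = sqrt(l2 / l1)`` and ``major_axis_length = 4 sqrt(l1)``
    with ``l1 >= l2 >= l3`` the eigenvalues of the voxel-coordinate
    covariance. ``max_3d_diameter`` is the largest pairwise distance between
    surface voxel centres. A single-voxel mask has no meaningful mesh; those
    features are returned as NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must contain at least one voxel")
    voxel_size = np.asarray(voxel_size, dtype=float)
    n = int(mask.sum())
    out: dict[str, float] = {"voxel_volume": n * float(np.prod(voxel_size))}

    coords = np.argwhere(mask) * voxel_size  # world coordinates (mm)

    if n == 1:
        out.update({k: np.nan for k in MESH_FEATURES})
        out.update(
            elongation=np.nan,
            major_axis_length=np.nan,
            max_3d_diameter=0.0,
        )
        return out

    verts, faces = _mesh(mask, voxel_size)
    vol, area = _mesh_volume_area(verts, faces)
    out["mesh_volume"] = vol
    out["surface_area"] = area
    out["sphericity"] = float((36.0 * np.pi * vol**2) ** (1.0 / 3.0) / area)

    cov = np.cov(coords, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    out["major_axis_length"] = float(4.0 * np.sqrt(eig[0]))
    out["elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan

    out["max_3d_diameter"] = _max_diameter(mask, voxel_size)
    return out


def _max_diameter(mask: np.ndarray, voxel_size) -> float:
    """Max pairwise distance between surface-voxel centres (hull-accelerated)."""
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    surface = mask & ~eroded
    pts = np.argwhere(surface) * np.asarray(voxel_size, dtype=float)
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # coplanar / degenerate point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))
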