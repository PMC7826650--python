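"""Synthetic two-visit feature tables and variable-flip-angle phantoms.

The generators encode known ground truth so that every downstream estimator
(ICC(1,1), RC, Box-Cox lambda, the voxelwise T1 fit) can be validated by
parameter recovery:

* :func:`simulate_feature_table` draws from a one-way random-effects model
  ``x_ij = mu + b_i + e_ij`` with between-lesion SD ``sigma_b`` and
  within-lesion SD ``sigma_w``, so the true ICC is
  ``sigma_b^2 / (sigma_b^2 + sigma_w^2)`` and the true repeatability
  coefficient is ``1.96 * sqrt(2) * sigma_w``. An optional inverse Box-Cox
  map induces a known non-Gaussian skew that the forward transform with the
  same lambda removes exactly.
* :func:`simulate_vfa_phantom` builds multi-flip-angle spoiled gradient-echo
  volumes from known M0/T1 maps with an ellipsoidal lesion, plus additive
  Gaussian noise.

Lesions are treated as independent sampling units (patient-level clustering
is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import special

from .tables import FeatureTable


# --------------------------------------------------------------------- tables
@dataclass(frozen=True)
class RandomEffectsSpec:
    """Generative truth for a two-visit feature under a one-way random-effects model.

    Parameters
    ----------
    mu : float
        Feature mean (feature units).
    sigma_b : float
        Between-lesion SD (>= 0).
    sigma_w : float
        Within-lesion SD (> 0).
    n_lesions : int
        Number of independent lesions (>= 2).
    n_visits : int
        Repeat measurements per lesion; 2 for a standard test-retest design.
    lambda_skew : float or None
        If given, values are passed through the *inverse* Box-Cox map with
        this lambda, inducing a known skew; the forward Box-Cox transform
        with the same lambda restores exact Gaussianity.
    seed : int
        Seed for the generator; identical spec + seed give identical tables.
    name : str
        Column name of the generated feature.
    """

    mu: float
    sigma_b: float
    sigma_w: float
    n_lesions: int
    n_visits: int = 2
    lambda_skew: float | None = None
    seed: int = 0
    name: str = "synthetic_feature"

    def __post_init__(self) -> None:
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be > 0")
        if self.n_lesions < 2:
            raise ValueError("n_lesions must be >= 2")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")

    @property
    def true_icc(self) -> float:
        """sigma_b^2 / (sigma_b^2 + sigma_w^2), in [0, 1)."""
        return self.sigma_b**2 / (self.sigma_b**2 + self.sigma_w**2)

    @property
    def true_rc(self) -> float:
        """Repeatability coefficient implied by the generative within-lesion SD."""
        return 1.96 * np.sqrt(2.0) * self.sigma_w


def inverse_boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    """Inverse of the Box-Cox transform; rejects out-of-domain input.

    For ``lam != 0`` the forward map only reaches ``y > -1/lam`` (lam > 0) or
    ``y < -1/lam`` (lam < 0); values outside that range are not invertible and
    raise rather than being clipped, so that generative truth stays exact.
    """
    y = np.asarray(y, dtype=float)
    if lam != 0.0:
        arg = lam * y + 1.0
        if np.any(arg <= 0):
            raise ValueError(
                f"inverse Box-Cox undefined for lambda={lam} over data range "
                f"[{y.min():.4g}, {y.max():.4g}]: lambda*y + 1 must stay positive"
            )
    return special.inv_boxcox(y, lam)


def simulate_feature_table(
    spec: RandomEffectsSpec, rng: np.random.Generator | None = None
) -> FeatureTable:
    """Draw a two-visit (or k-visit) feature table with known variance components."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    b = rng.normal(0.0, spec.sigma_b, size=spec.n_lesions)
    e = rng.normal(0.0, spec.sigma_w, size=(spec.n_lesions, spec.n_visits))
    values = spec.mu + b[:, None] + e
    if spec.lambda_skew is not None:
        values = inverse_boxcox(values, spec.lambda_skew)

    import pandas as pd

    index = pd.MultiIndex.from_product(
        [range(1, spec.n_lesions + 1), range(1, spec.n_visits + 1)],
        names=["lesion_id", "visit"],
    )
    data = pd.DataFrame({spec.name: values.ravel()}, index=index)
    return FeatureTable(data, {"spec": spec})


def simulate_multifeature_table(specs: list[RandomEffectsSpec]) -> FeatureTable:
    """Several features on a shared lesion set (independent across features)."""
    if len({(s.n_lesions, s.n_visits) for s in specs}) != 1:
        raise ValueError("all specs must share n_lesions and n_visits")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    from .tables import concat_features

    return concat_features([simulate_feature_table(s) for s in specs])


# ------------------------------------------------------------------- phantoms
@dataclass(frozen=True)
class PhantomSpec:
    """Multi-flip-angle SPGR phantom with an ellipsoidal lesion of known T1."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)  # mm
    flip_angles: tuple[float, ...] = (2.0, 10.0, 20.0)  # degrees
    tr: float = 4.0  # ms
    t1_background: float = 500.0  # ms (liver-like at 1.5 T)
    t1_lesion: float = 800.0  # ms
    m0: float = 1000.0  # arbitrary units
    noise_sd: float = 0.0  # signal units
    lesion_centre: tuple[float, float, float] = (16.0, 16.0, 16.0)  # voxels
    lesion_semiaxes: tuple[float, float, float] = (8.0, 6.0, 4.0)  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.flip_angles) == 0:
            raise ValueError("at least one flip angle required")
        fa = np.asarray(self.flip_angles, dtype=float)
        if np.any(fa <= 0) or np.any(fa > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.t1_background <= 0 or self.t1_lesion <= 0:
            raise ValueError("T1 values must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c, a, n in zip(self.lesion_centre, self.lesion_semiaxes, self.grid_shape):
            if a <= 0:
                raise ValueError("lesion semi-axes must be positive")
            if c - a < -0.5 or c + a > n - 0.5:
                raise ValueError("lesion must fit inside the grid")


def ellipsoid_mask(
    shape: tuple[int, int, int],
    centre: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of voxels whose centres satisfy the ellipsoid inequality."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semiaxes))
    return q <= 1.0


def simulate_vfa_phantom(spec: PhantomSpec):
    """Return (VfaSeries, truth QT1Map, lesion mask) for a known-T1 phantom."""
    from .t1_mapping import QT1Map, VfaSeries, spgr_signal

    rng = np.random.default_rng(spec.seed)
    mask = ellipsoid_mask(spec.grid_shape, spec.lesion_centre, spec.lesion_semiaxes)
    t1 = np.where(mask, spec.t1_lesion, spec.t1_background).astype(float)
    m0 = np.full(spec.grid_shape, spec.m0, dtype=float)

    volumes = []
    for alpha in spec.flip_angles:
        clean = spgr_signal(m0, t1, alpha, spec.tr)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape) if spec.noise_sd else clean
        volumes.append(noisy)

    series = VfaSeries(
        volumes=volumes,
        flip_angles=list(spec.flip_angles),
        tr=spec.tr,
        voxel_size=spec.voxel_size,
    )
    truth = QT1Map(t1=t1, m0=m0, fit_ok=np.ones(spec.grid_shape, dtype=bool))
    return series, truth, mask


# ----------------------------------------------------------------------- IO
def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_nifti(volume: np.ndarray, voxel_size, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(voxel_size))
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms
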