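"""Intensity normalisation, fixed-bin-width discretisation, mask resampling.

Normalisation is the standard linear map to mean 0 / SD 100 computed over the
whole volume (not restricted to the ROI; configurable). Discretisation uses
fixed-width bins anchored at the ROI minimum:

    level(v) = floor((x_v - min_ROI) / bin_width) + 1

so grey levels are translation-invariant and the number of bins adapts to the
ROI intensity range. Mask resampling between image resolutions is
nearest-neighbour in world coordinates, which guarantees binary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

DEFAULT_TARGET_MEAN = 0.0
DEFAULT_TARGET_SD = 100.0
DEFAULT_BIN_WIDTH = 5.0


@dataclass
class RoiImage:
    """A 3D intensity volume with a binary region-of-interest mask."""

    image: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def roi_values(self) -> np.ndarray:
        return self.image[self.mask]


def normalise_image(
    img: RoiImage,
    target_mean: float = DEFAULT_TARGET_MEAN,
    target_sd: float = DEFAULT_TARGET_SD,
    roi_only: bool = False,
) -> RoiImage:
    """Linear intensity normalisation: (x - mean) / sd * target_sd + target_mean.

    Statistics are computed over the whole volume by default (``roi_only``
    restricts them to the mask). A constant volume has no defined scaling and
    raises.
    """
    ref = img.roi_values if roi_only else img.image
    mean = float(np.mean(ref))
    sd = float(np.std(ref))
    if sd == 0.0:
        raise ValueError("cannot normalise a constant image (SD = 0)")
    out = (img.image - mean) / sd * target_sd + target_mean
    return RoiImage(out, img.mask, img.voxel_size, {**img.meta, "normalised": True})


def discretise(img: RoiImage, bin_width: float = DEFAULT_BIN_WIDTH):
    """Fixed-bin-width grey-level discretisation of the ROI.

    Returns
    -------
    levels : int array, same shape as the image; grey level 1..n_bins inside
        the mask, 0 outside.
    n_bins : int
        The maximum grey level observed in the ROI.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = img.roi_values
    lo = vals.min()
    levels = np.zeros(img.image.shape, dtype=np.int64)
    inside = np.floor((img.image[img.mask] - lo) / bin_width).astype(np.int64) + 1
    levels[img.mask] = inside
    return levels, int(inside.max())


def resample_mask(
    mask: np.ndarray,
    source_voxel_size: tuple[float, float, float],
    target_voxel_size: tuple[float, float, float],
    target_shape: tuple[int, int, int],
) -> np.ndarray:
    """Nearest-neighbour mask resampling between voxel grids (world coords).

    Both grids share the same world-space corner (voxel edges aligned), so an
    integer up-sampling of an axis-aligned cuboid is exact.
    """
    if any(v <= 0 for v in source_voxel_size) or any(v <= 0 for v in target_voxel_size):
        raise ValueError("voxel sizes must be positive")
    if any(n <= 0 for n in target_shape):
        raise ValueError("target shape must be positive")
    # SimpleITK uses (x, y, z) spacing against numpy (z, y, x) arrays
    src = sitk.GetImageFromArray(np.asarray(mask, dtype=np.uint8))
    src.SetSpacing(tuple(float(v) for v in source_voxel_size[::-1]))
    resampler = sitk.ResampleImageFilter()
    resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    resampler.SetOutputSpacing(tuple(float(v) for v in target_voxel_size[::-1]))
    resampler.SetSize(tuple(int(n) for n in target_shape[::-1]))
    # align grid corners: ITK origin is the centre of voxel (0,0,0)
    origin = tuple(
        (t - s) / 2.0
        for s, t in zip(source_voxel_size[::-1], target_voxel_size[::-1])
    )
    resampler.SetOutputOrigin(origin)
    resampler.SetOutputDirection(src.GetDirection())
    out = resampler.Execute(src)
    return sitk.GetArrayFromImage(out).astype(bool)
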