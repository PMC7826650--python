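"""Full extraction of the implemented feature set from one ROI image."""

from __future__ import annotations

import numpy as np

from ..preprocessing import DEFAULT_BIN_WIDTH, RoiImage, discretise
from .first_order import first_order_features
from .shape import shape_features
from .texture_features import texture_features
from .texture_matrices import texture_matrices

#: provenance of each feature class: (class name, matrix parameters)
FEATURE_CLASSES = {
    "shape": {"source": "mask only"},
    "first_order": {"source": "ROI intensities"},
    "glcm": {"directions": 13, "distance": 1, "aggregation": "mean over directions"},
    "glrlm": {"directions": 13, "aggregation": "mean over directions"},
    "glszm": {"connectivity": 26},
    "gldm": {"connectivity": 26, "alpha": 0},
    "ngtdm": {"connectivity": 26},
}


def extract_features(
    img: RoiImage, bin_width: float = DEFAULT_BIN_WIDTH
) -> dict[str, float]:
    """All implemented shape, first-order and texture features of one lesion.

    Texture features are computed on the fixed-bin-width discretised ROI;
    ``n_bins`` (the grey-level count of this lesion) is included so the
    pipeline can report the median bin count across lesions.
    """
    voxvol = float(np.prod(img.voxel_size))
    out: dict[str, float] = {}
    for name, value in shape_features(img.mask, img.voxel_size).items():
        out[f"shape_{name}"] = value
    for name, value in first_order_features(img.roi_values, voxvol).items():
        out[f"first_order_{name}"] = value
    levels, n_bins = discretise(img, bin_width)
    out.update(texture_features(texture_matrices(levels, n_bins)))
    out["n_bins"] = float(n_bins)
    return out
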