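"""First-order (intensity histogram) features of ROI voxel values."""

from __future__ import annotations

import numpy as np
from scipy import stats


def first_order_features(
    values: np.ndarray, voxel_volume_mm3: float = 1.0
) -> dict[str, float]:
    """Standard first-order statistics of the ROI intensities.

    ``energy`` is the sum of squared intensities; ``total_energy`` scales it
    by the physical voxel volume. ``skewness``/``kurtosis`` are the biased
    Fisher-Pearson moment coefficients and need >= 3 voxels; with fewer they
    are returned as NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("ROI must contain at least one voxel")
    out = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": float(x.var()),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "energy": float((x**2).sum()),
        "total_energy": float((x**2).sum() * voxel_volume_mm3),
        "mean_absolute_deviation": float(np.abs(x - x.mean()).mean()),
        "interquartile_range": float(np.percentile(x, 75) - np.percentile(x, 25)),
    }
    if x.size >= 3 and x.std() > 0:
        out["skewness"] = float(stats.skew(x, bias=True))
        out["kurtosis"] = float(stats.kurtosis(x, bias=True, fisher=False))
    elif x.std() == 0:
        out["skewness"] = 0.0
        out["kurtosis"] = np.nan
    else:
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    return out
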