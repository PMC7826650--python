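"""Pair-wise comparison of ICCs across datasets via Fisher's Z-test.

ICC estimates from two datasets are compared on the variance-stabilised
scale ``z = atanh(icc)``. The difference ``z_a - z_b`` is approximately
normal with variance ``1/(n_a - 3/2) + 1/(n_b - 3/2)`` (Fisher's variance
for intraclass correlations with k = 2 measurements; the classic
inter-class ``1/(n - 3)`` is available via ``se_variant='classic'``).
Significance is gated at a Bonferroni-corrected ``alpha / n_features``.

Cohorts are treated as independent even when the same lesions appear in
both datasets — an unpaired comparison, a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .repeatability import IccResult
from .tables import FeatureTable

DEFAULT_ALPHA = 0.05
DEFAULT_N_FEATURES = 105


@dataclass
class IccComparison:
    """Fisher-Z difference of two ICC estimates with CI and significance."""

    z_diff: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool
    se: float
    feature_name: str = ""


def fisher_z(icc: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(icc)."""
    icc = float(icc)
    if not -1.0 < icc < 1.0:
        raise ValueError(f"Fisher Z undefined for |icc| >= 1 (got {icc})")
    return float(np.arctanh(icc))


def _se_term(n: int, variant: str) -> float:
    if variant == "intraclass":
        d = n - 1.5
    elif variant == "classic":
        d = n - 3.0
    else:
        raise ValueError(f"unknown se_variant: {variant}")
    if d <= 0:
        raise ValueError(f"cohort too small for Fisher-Z SE (n={n})")
    return 1.0 / d


def compare_iccs(
    a: IccResult,
    b: IccResult,
    alpha: float = DEFAULT_ALPHA,
    n_features: int = DEFAULT_N_FEATURES,
    se_variant: str = "intraclass",
    feature_name: str = "",
) -> IccComparison:
    """Unpaired Fisher-Z test of two ICC estimates.

    ``significant`` is judged at the Bonferroni-corrected level
    ``alpha / n_features``; the reported CI is a two-sided ``1 - alpha``
    interval on the Z-scale difference (uncorrected, as plotted error bars).
    """
    if min(a.n_subjects, b.n_subjects) < 4:
        raise ValueError("need n >= 4 per cohort")
    z_diff = fisher_z(a.icc) - fisher_z(b.icc)
    se = float(np.sqrt(_se_term(a.n_subjects, se_variant) + _se_term(b.n_subjects, se_variant)))
    p = float(2.0 * stats.norm.sf(abs(z_diff) / se))
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return IccComparison(
        z_diff=float(z_diff),
        ci_low=float(z_diff - crit * se),
        ci_high=float(z_diff + crit * se),
        p=p,
        significant=p < alpha / n_features,
        se=se,
        feature_name=feature_name,
    )


def volume_confounding(
    table: FeatureTable, reference: str = "shape_mesh_volume"
) -> dict[str, float]:
    """Absolute Spearman correlation of every feature with a reference feature.

    Values are pooled over visits. Constant features have undefined rank
    correlation and are returned as NaN.
    """
    if reference not in table.feature_names:
        raise ValueError(f"reference feature {reference!r} not in table")
    ref = table.data[reference].to_numpy(float)
    out: dict[str, float] = {}
    for name in table.feature_names:
        if name == reference:
            out[name] = 1.0
            continue
        x = table.data[name].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(ref) == 0:
            out[name] = np.nan
            continue
        rho = stats.spearmanr(x, ref).statistic
        out[name] = float(abs(rho))
    return out
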