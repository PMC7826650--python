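"""ICC(1,1) and repeatability-coefficient estimation with 95% CIs.

Model: one-way random effects, ``x_ij = mu + b_i + e_ij`` with
``b_i ~ N(0, sigma_b^2)`` (between-subject) and ``e_ij ~ N(0, sigma_w^2)``
(within-subject, i.e. measurement error). From the one-way ANOVA mean
squares MSB (between, df n-1) and MSW (within, df n(k-1)):

* ``ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW)`` — the single-measurement
  intraclass correlation; its exact CI follows from the F distribution of
  MSB/MSW (McGraw-Wong form for the one-way model).
* ``RC = 1.96 sqrt(2) * wsd`` with ``wsd^2 = MSW`` — the bound within which
  95% of test-retest differences are expected to fall; its CI follows from
  the chi-square distribution of ``n(k-1) wsd^2 / sigma_w^2``.

Negative ICC estimates are reported as computed (no clamping), preserving
the estimator's sampling distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

RC_FACTOR = 1.96 * np.sqrt(2.0)


@dataclass
class IccResult:
    """ICC(1,1) point estimate with a two-sided confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k: int
    msb: float = np.nan
    msw: float = np.nan


@dataclass
class RcResult:
    """Repeatability coefficient with a two-sided confidence interval."""

    rc: float
    ci_low: float
    ci_high: float
    wsd: float
    n_subjects: int
    k: int


def _anova_ms(values: np.ndarray) -> tuple[float, float, int, int]:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n x k matrix of repeated measurements")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 measurements")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed (complete-case design)")
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float(msb), float(msw), n, k


def icc_1_1(values: np.ndarray, confidence: float = 0.95) -> IccResult:
    """One-way random-effects, single-measurement intraclass correlation.

    The CI is exact under the Gaussian one-way model: with
    ``F = MSB/MSW ~ F(n-1, n(k-1))`` scaled by the true variance ratio,
    the interval is ``(FL-1)/(FL+k-1), (FU-1)/(FU+k-1)`` where
    ``FL = F / F_{1-a/2}(n-1, n(k-1))`` and
    ``FU = F * F_{1-a/2}(n(k-1), n-1)``.
    """
    msb, msw, n, k = _anova_ms(values)
    if msw == 0 and msb == 0:
        raise ValueError("all measurements identical; ICC undefined")
    icc = (msb - msw) / (msb + (k - 1) * msw) if msw > 0 or msb > 0 else np.nan
    a = 1.0 - confidence
    df1, df2 = n - 1, n * (k - 1)
    if msw == 0:
        return IccResult(1.0, np.nan, 1.0, n, k, msb, msw)
    f_obs = msb / msw
    fl = f_obs / stats.f.ppf(1 - a / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - a / 2, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return IccResult(float(icc), float(ci_low), float(ci_high), n, k, msb, msw)


def rc(values: np.ndarray, coverage: float = 0.95, confidence: float = 0.95) -> RcResult:
    """Repeatability coefficient from the within-subject mean square.

    For k = 2 the point estimate reduces to
    ``RC = 1.96 sqrt(2) sqrt(sum d_i^2 / (2n))`` with ``d_i`` the visit
    differences. ``coverage`` sets the normal quantile (0.95 -> 1.96-like);
    ``confidence`` sets the CI level on the estimate.
    """
    msb, msw, n, k = _anova_ms(values)
    z = float(stats.norm.ppf(0.5 + coverage / 2.0))
    factor = RC_FACTOR if coverage == 0.95 else z * np.sqrt(2.0)
    wsd = float(np.sqrt(msw))
    point = factor * wsd
    df = n * (k - 1)
    a = 1.0 - confidence
    lo_var = df * msw / stats.chi2.ppf(1 - a / 2, df)
    hi_var = df * msw / stats.chi2.ppf(a / 2, df)
    return RcResult(
        rc=point,
        ci_low=float(factor * np.sqrt(lo_var)),
        ci_high=float(factor * np.sqrt(hi_var)),
        wsd=wsd,
        n_subjects=n,
        k=k,
    )


def icc_cov_across_datasets(iccs) -> float:
    """Coefficient of variation (SD/mean) of ICC point estimates across datasets."""
    x = np.asarray(list(iccs), dtype=float)
    if x.size < 2:
        raise ValueError("need ICCs from at least 2 datasets")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CoV undefined: mean ICC is 0")
    return float(x.std(ddof=1) / mean)
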