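"""Voxelwise quantitative T1 estimation from variable-flip-angle SPGR volumes.

The steady-state spoiled gradient-echo signal at flip angle ``alpha`` and
repetition time ``TR`` is

    S(alpha) = M0 * sin(alpha) * (1 - E) / (1 - E * cos(alpha)),
    E = exp(-TR / T1).

Given signals at two or more flip angles, (M0, T1) are estimated per voxel by
Levenberg-Marquardt nonlinear least squares, initialised from the closed-form
DESPOT1 linearisation (regression of S/sin(alpha) on S/tan(alpha), whose
slope is E). The LM iteration is run as a vectorised batch over all voxels:
for a two-parameter model the normal equations are 2x2 and solvable in closed
form, which makes whole-volume fitting cheap and exactly deterministic.

Out-of-bound or failed solutions are flagged in ``fit_ok``, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNDEFINED_T1 = np.nan

DEFAULT_T1_BOUNDS = (1.0, 10000.0)  # ms


@dataclass
class VfaSeries:
    """Multi-flip-angle SPGR acquisition: one volume per flip angle."""

    volumes: list[np.ndarray]
    flip_angles: list[float]  # degrees
    tr: float  # ms
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.flip_angles):
            raise ValueError("one volume per flip angle required")
        if len(set(np.round(self.flip_angles, 9))) < 2:
            raise ValueError("at least 2 distinct flip angles required")
        fa = np.asarray(self.flip_angles, dtype=float)
        if np.any(fa <= 0) or np.any(fa > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        shapes = {np.shape(v) for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"volumes disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return np.shape(self.volumes[0])

    def stacked(self) -> np.ndarray:
        """(n_flip_angles, *shape) signal array."""
        return np.stack([np.asarray(v, dtype=float) for v in self.volumes])


@dataclass
class QT1Map:
    """Fitted quantitative T1 map: T1 (ms), M0, and per-voxel success flag."""

    t1: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)


def spgr_signal(m0, t1, alpha_deg, tr):
    """Spoiled gradient-echo steady-state signal. Arrays broadcast.

    Parameters are M0 (arbitrary units), T1 (ms), flip angle (degrees, in
    (0, 90]), TR (ms).
    """
    t1 = np.asarray(t1, dtype=float)
    alpha_deg = np.asarray(alpha_deg, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if np.any(alpha_deg <= 0) or np.any(alpha_deg > 90):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    if tr <= 0:
        raise ValueError("TR must be positive")
    a = np.deg2rad(alpha_deg)
    e = np.exp(-tr / t1)
    return m0 * np.sin(a) * (1.0 - e) / (1.0 - e * np.cos(a))


def ernst_angle(t1: float, tr: float) -> float:
    """Flip angle (degrees) maximising SPGR signal for given T1, TR."""
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def despot1_fit(signals: np.ndarray, flip_angles_deg: np.ndarray, tr: float):
    """Closed-form linearised T1 estimate (DESPOT1).

    Regresses ``y = S/sin(alpha)`` on ``x = S/tan(alpha)``; the slope equals
    ``E = exp(-TR/T1)`` and the intercept ``M0 (1 - E)``.

    Parameters
    ----------
    signals : (n_alpha, n_vox) array
    flip_angles_deg : (n_alpha,) array
    tr : float

    Returns
    -------
    t1, m0 : (n_vox,) arrays, NaN where the linear fit is degenerate or E
        falls outside (0, 1).
    """
    a = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))[:, None]
    s = np.asarray(signals, dtype=float)
    y = s / np.sin(a)
    x = s / np.tan(a)
    n = x.shape[0]
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
        t1 = -tr / np.log(slope)
        m0 = intercept / (1.0 - slope)
    bad = ~np.isfinite(slope) | (slope <= 0) | (slope >= 1) | (sxx <= 0)
    t1 = np.where(bad, np.nan, t1)
    m0 = np.where(bad, np.nan, m0)
    return t1, m0


def _lm_batch(signals, flip_angles_deg, tr, t1_0, m0_0, max_iter=60, tol=1e-12):
    """Vectorised Levenberg-Marquardt for (M0, T1) per voxel.

    signals: (n_alpha, n_vox); returns (m0, t1, converged).
    """
    a = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))[:, None]
    sin_a, cos_a = np.sin(a), np.cos(a)
    s = np.asarray(signals, dtype=float)

    m0 = np.array(m0_0, dtype=float)
    t1 = np.array(t1_0, dtype=float)
    lam = np.full(m0.shape, 1e-3)

    def model_and_jac(m0, t1):
        e = np.exp(-tr / t1)
        denom = 1.0 - e * cos_a
        f = sin_a * (1.0 - e) / denom  # signal per unit M0
        pred = m0 * f
        # dS/dE = m0 sin(a) (cos a - 1) / denom^2 ; dE/dT1 = e * tr / t1^2
        ds_de = m0 * sin_a * (cos_a - 1.0) / denom**2
        de_dt1 = e * tr / t1**2
        return pred, f, ds_de * de_dt1

    pred, j_m0, j_t1 = model_and_jac(m0, t1)
    r = pred - s
    cost = (r**2).sum(axis=0)

    for _ in range(max_iter):
        # normal equations, 2x2 per voxel
        a11 = (j_m0 * j_m0).sum(axis=0)
        a12 = (j_m0 * j_t1).sum(axis=0)
        a22 = (j_t1 * j_t1).sum(axis=0)
        g1 = (j_m0 * r).sum(axis=0)
        g2 = (j_t1 * r).sum(axis=0)
        d11 = a11 * (1.0 + lam)
        d22 = a22 * (1.0 + lam)
        det = d11 * d22 - a12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            dm0 = -(d22 * g1 - a12 * g2) / det
            dt1 = -(d11 * g2 - a12 * g1) / det
        dm0 = np.where(np.isfinite(dm0), dm0, 0.0)
        dt1 = np.where(np.isfinite(dt1), dt1, 0.0)

        t1_new = t1 + dt1
        m0_new = m0 + dm0
        valid = t1_new > 0
        t1_try = np.where(valid, t1_new, t1)
        m0_try = np.where(valid, m0_new, m0)
        pred_new, f_new, jt1_new = model_and_jac(m0_try, t1_try)
        r_new = pred_new - s
        cost_new = (r_new**2).sum(axis=0)

        improved = valid & (cost_new < cost)
        m0 = np.where(improved, m0_try, m0)
        t1 = np.where(improved, t1_try, t1)
        lam = np.where(improved, lam * 0.3, lam * 5.0)
        lam = np.clip(lam, 1e-12, 1e8)
        pred, j_m0, j_t1 = model_and_jac(m0, t1)
        r = pred - s
        old_cost = cost
        cost = np.where(improved, cost_new, cost)
        if np.all(np.abs(old_cost - cost) <= tol * (cost + 1e-30)):
            break

    converged = np.isfinite(t1) & np.isfinite(m0) & (t1 > 0)
    return m0, t1, converged


def fit_t1_map(
    series: VfaSeries,
    mask: np.ndarray | None = None,
    bounds: tuple[float, float] = DEFAULT_T1_BOUNDS,
) -> QT1Map:
    """Fit (M0, T1) voxelwise by batch Levenberg-Marquardt with DESPOT1 init.

    ``fit_ok`` is False where signals are all ~0, where the solver fails, or
    where the solution leaves ``bounds``; such voxels keep NaN T1 rather than
    clamped values.
    """
    t1_min, t1_max = bounds
    if not (0 < t1_min < t1_max):
        raise ValueError("bounds must satisfy 0 < t1_min < t1_max")
    shape = series.shape
    stacked = series.stacked().reshape(len(series.flip_angles), -1)

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape must match volumes")
        sel = mask.ravel()
    else:
        sel = np.ones(stacked.shape[1], dtype=bool)

    sig = stacked[:, sel]
    scale = np.abs(sig).max(axis=0)
    nonzero = scale > 1e-12 * max(1.0, float(np.abs(sig).max(initial=0.0)))

    t1_full = np.full(stacked.shape[1], UNDEFINED_T1)
    m0_full = np.full(stacked.shape[1], np.nan)
    ok_full = np.zeros(stacked.shape[1], dtype=bool)

    if nonzero.any():
        sub = sig[:, nonzero]
        fa = np.asarray(series.flip_angles, dtype=float)
        t1_0, m0_0 = despot1_fit(sub, fa, series.tr)
        # fall back to a mid-range start where the linearisation is degenerate
        t1_0 = np.where(np.isfinite(t1_0) & (t1_0 > 0), t1_0, 1000.0)
        peak = spgr_signal(1.0, t1_0, fa[np.argmax(np.abs(sub).max(axis=1))], series.tr)
        m0_0 = np.where(np.isfinite(m0_0) & (m0_0 != 0), m0_0, np.abs(sub).max(axis=0) / np.maximum(peak, 1e-12))
        m0_fit, t1_fit, conv = _lm_batch(sub, fa, series.tr, t1_0, m0_0)
        ok = conv & (t1_fit >= t1_min) & (t1_fit <= t1_max)
        t1_out = np.where(ok, t1_fit, UNDEFINED_T1)
        m0_out = np.where(ok, m0_fit, np.nan)
        idx = np.flatnonzero(sel)[nonzero]
        t1_full[idx] = t1_out
        m0_full[idx] = m0_out
        ok_full[idx] = ok

    return QT1Map(
        t1=t1_full.reshape(shape),
        m0=m0_full.reshape(shape),
        fit_ok=ok_full.reshape(shape),
        voxel_size=series.voxel_size,
        meta={"tr": series.tr, "flip_angles": list(series.flip_angles), "bounds": bounds},
    )
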