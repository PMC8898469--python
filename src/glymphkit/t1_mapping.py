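"""B1+ mapping by the double-angle method and linearized VFA-SPGR T1 fitting.

The T1 estimator follows the classical linearization of the spoiled
gradient-echo steady state: with effective flip angles theta_i = B1 *
theta_nominal_i,

    S_i / sin(theta_i) = E1 * S_i / tan(theta_i) + M0 (1 - E1),

so an ordinary (unweighted) least-squares line through the points
(x_i, y_i) = (S_i/tan, S_i/sin) has slope m = E1 = exp(-TR/T1) and
intercept c = M0 (1 - E1).  Hence T1 = -TR / ln m and M0 = c / (1 - m).
Degenerate fits (m outside (0, 1), vanishing sines) are flagged invalid,
never clipped: the downstream tracer-window cluster rule must not count
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .protocol import AcquisitionProtocol

__all__ = ["B1Map", "T1Volume", "compute_b1_map", "fit_t1_voxel", "fit_t1_volume"]


@dataclass
class B1Map:
    """Per-voxel multiplicative transmit scale with validity mask."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("B1 values and validity mask differ in shape")


@dataclass
class T1Volume:
    """Fitted T1/M0 volumes with validity mask and per-voxel residuals."""

    t1_ms: np.ndarray
    m0: np.ndarray
    valid: np.ndarray
    rss: np.ndarray


def compute_b1_map(img_alpha: np.ndarray, img_2alpha: np.ndarray,
                   alpha_nominal_deg: float,
                   signal_floor_frac: float = 0.05,
                   smooth_sigma: float = 2.0) -> B1Map:
    """Double-angle B1+ map from the (alpha, 2*alpha) image pair.

    In the long-TR regime S_2a/S_a = sin(2 B1 a)/sin(B1 a) = 2 cos(B1 a),
    so B1 = arccos(S_2a / (2 S_a)) / a.  The ratio is clamped to [-1, 1].
    Voxels whose base-angle signal falls below ``signal_floor_frac`` of
    the image's 99th percentile are flagged invalid (arccos is
    ill-conditioned at low SNR).  ``smooth_sigma > 0`` applies a
    validity-weighted 3D Gaussian smoothing, the standard regularisation
    for double-angle maps; pass 0 to disable.
    """
    img_alpha = np.asarray(img_alpha, dtype=float)
    img_2alpha = np.asarray(img_2alpha, dtype=float)
    if img_alpha.shape != img_2alpha.shape:
        raise ValueError(
            f"image shapes differ: {img_alpha.shape} vs {img_2alpha.shape}")
    if not (0.0 < alpha_nominal_deg <= 90.0):
        raise ValueError(f"alpha_nominal_deg must lie in (0, 90], got {alpha_nominal_deg}")

    floor = signal_floor_frac * np.percentile(img_alpha, 99.0)
    valid = img_alpha > max(floor, 0.0)

    alpha = np.deg2rad(alpha_nominal_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(img_2alpha / (2.0 * img_alpha), -1.0, 1.0)
    b1 = np.where(valid, np.arccos(r) / alpha, np.nan)

    if smooth_sigma > 0 and valid.any():
        w = valid.astype(float)
        num = ndimage.gaussian_filter(np.where(valid, b1, 0.0), smooth_sigma)
        den = ndimage.gaussian_filter(w, smooth_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = num / den
        b1 = np.where(valid, smoothed, np.nan)

    return B1Map(values=b1, valid=valid)


def fit_t1_voxel(signals, protocol: AcquisitionProtocol, b1: float
                 ) -> tuple[float, float, float, bool]:
    """Linearized unweighted least-squares fit for a single voxel.

    Returns ``(t1_ms, m0, rss, valid)``; invalid fits return NaNs with
    ``valid=False`` rather than raising.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (len(protocol.flip_angles_deg),):
        raise ValueError(
            f"expected {len(protocol.flip_angles_deg)} signals, got shape {signals.shape}")
    res = fit_t1_volume(signals.reshape(-1, 1), B1Map(
        values=np.array([float(b1)]), valid=np.array([True])),
        mask=np.array([True]), protocol=protocol)
    return (float(res.t1_ms[0]), float(res.m0[0]), float(res.rss[0]),
            bool(res.valid[0]))


def fit_t1_volume(series: np.ndarray, b1map: B1Map, mask: np.ndarray | None,
                  protocol: AcquisitionProtocol) -> T1Volume:
    """Vectorised linearized VFA fit over the masked voxels of a volume.

    ``series`` has shape ``(n_angles,) + grid``; ``mask`` selects the
    voxels to fit (all voxels when None).  Validity requires a usable B1,
    all effective-angle sines nonzero, at least two angles, and a slope
    in (0, 1).
    """
    series = np.asarray(series, dtype=float)
    n_ang = len(protocol.flip_angles_deg)
    if series.shape[0] != n_ang:
        raise ValueError(f"series has {series.shape[0]} angles, protocol expects {n_ang}")
    grid = series.shape[1:]
    if b1map.values.shape != grid:
        raise ValueError(f"B1 map shape {b1map.values.shape} != image grid {grid}")
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != image grid {grid}")

    t1 = np.full(grid, np.nan)
    m0 = np.full(grid, np.nan)
    rss = np.full(grid, np.nan)
    valid = np.zeros(grid, dtype=bool)

    sel = mask & b1map.valid & np.isfinite(b1map.values)
    if not sel.any():
        return T1Volume(t1_ms=t1, m0=m0, valid=valid, rss=rss)

    s = series[:, sel]                                    # (n_ang, N)
    b1 = b1map.values[sel]                                # (N,)
    theta = np.deg2rad(np.asarray(protocol.flip_angles_deg))[:, None] * b1[None, :]

    sin_t = np.sin(theta)
    usable = np.all(np.abs(sin_t) > 1e-12, axis=0) & np.all(np.isfinite(s), axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        y = s / sin_t
        x = s / np.tan(theta)
    xbar = x.mean(axis=0)
    ybar = y.mean(axis=0)
    dx = x - xbar
    dy = y - ybar
    sxx = np.sum(dx * dx, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.sum(dx * dy, axis=0) / sxx
    c = ybar - m * xbar
    resid = y - (m * x + c)
    rss_v = np.sum(resid * resid, axis=0)

    ok = usable & np.isfinite(m) & (m > 0.0) & (m < 1.0) & (sxx > 0.0)
    t1_v = np.full(m.shape, np.nan)
    m0_v = np.full(m.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_v[ok] = -protocol.tr_ms / np.log(m[ok])
        m0_v[ok] = c[ok] / (1.0 - m[ok])
    ok &= np.isfinite(t1_v) & (t1_v > 0.0)

    t1[sel] = t1_v
    m0[sel] = m0_v
    rss[sel] = np.where(ok, rss_v, np.nan)
    v = np.zeros(grid, dtype=bool)
    v[sel] = ok
    return T1Volume(t1_ms=t1, m0=m0, valid=v, rss=rss)
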