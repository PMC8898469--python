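"""Synthetic AQP4 immunofluorescence micrographs with known ground truth.

Each vessel is rendered as a bright annulus (the perivascular astrocytic
endfoot sheath) on a flat background.  ``diameter_um`` is the *outer*
wall diameter, so the segmented, hole-filled object has an equivalent
diameter matching the ground truth and the 10 um capillary/small-vessel
rule applies consistently.  Two ground-truth dials are honoured by
construction:

* the polarization index: the brightest vessel pixel is set exactly to
  ``pi_true * background_median``;
* the radial heterogeneity: a single-mode angular modulation
  ``1 + a cos(phi - phi0)`` is applied to the wall, with the amplitude
  ``a`` solved numerically so the wedge-based radial CV of the noiseless
  object equals ``radial_cv_true``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["VesselSpec", "MicrographSpec", "make_vessel_micrograph",
           "wedge_cv", "CAPILLARY_DIAMETER_UM"]

#: Objects with equivalent diameter below this are capillaries, at or
#: above it small vessels.
CAPILLARY_DIAMETER_UM = 10.0


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: centre (um), outer diameter, wall thickness, targets."""

    center_um: tuple[float, float]      # (x, y) in micrometres
    diameter_um: float
    wall_thickness_um: float = 1.5
    pi_true: float = 10.0
    radial_cv_true: float = 0.0
    phase_deg: float = 0.0              # orientation of the angular mode

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        if not (0 < self.wall_thickness_um < self.diameter_um / 2):
            raise ValueError("wall thickness must be positive and below the radius")
        if self.pi_true < 1:
            raise ValueError("pi_true must be >= 1")
        if self.radial_cv_true < 0:
            raise ValueError("radial_cv_true must be >= 0")

    @property
    def truth_class(self) -> str:
        return "capillary" if self.diameter_um < CAPILLARY_DIAMETER_UM else "small_vessel"


@dataclass(frozen=True)
class MicrographSpec:
    image_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.325
    background_median: float = 10.0
    vessels: tuple[VesselSpec, ...] = ()
    noise_sd: float = 0.0
    poisson: bool = False
    expansion_um: float = 32.5          # background-annulus radius downstream
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.background_median <= 0:
            raise ValueError("background_median must be positive")
        object.__setattr__(self, "vessels", tuple(self.vessels))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MicrographSpec":
        raw = json.loads(Path(path).read_text())
        raw["image_shape_px"] = tuple(raw["image_shape_px"])
        raw["vessels"] = tuple(
            VesselSpec(center_um=tuple(v.pop("center_um")), **v) for v in raw["vessels"])
        return cls(**raw)


def _check_layout(spec: MicrographSpec) -> None:
    """Reject layouts whose expanded background annuli touch another vessel
    or whose walls leave the image."""
    w_um = spec.image_shape_px[1] * spec.pixel_size_um
    h_um = spec.image_shape_px[0] * spec.pixel_size_um
    for i, v in enumerate(spec.vessels):
        r = v.diameter_um / 2
        x, y = v.center_um
        if not (r <= x <= w_um - r and r <= y <= h_um - r):
            raise ValueError(f"vessel {i} (centre {v.center_um} um) leaves the image")
        for j, u in enumerate(spec.vessels[i + 1:], start=i + 1):
            d = float(np.hypot(x - u.center_um[0], y - u.center_um[1]))
            min_d = r + u.diameter_um / 2 + spec.expansion_um
            if d < min_d:
                raise ValueError(
                    f"vessels {i} and {j} are {d:.1f} um apart; the "
                    f"{spec.expansion_um} um background expansion requires >= {min_d:.1f} um")


def _render_vessel(v: VesselSpec, spec: MicrographSpec, amplitude: float
                   ) -> tuple[np.ndarray, tuple[slice, slice], np.ndarray, np.ndarray]:
    """Additive wall intensity of one vessel in a local window.

    Returns (additive image, window slices, wall mask, filled-disk mask).
    The additive part is scaled so its maximum pixel is exactly
    (pi_true - 1) * background_median.
    """
    px = spec.pixel_size_um
    r_out = v.diameter_um / 2
    r_in = r_out - v.wall_thickness_um
    cx, cy = v.center_um
    pad = int(np.ceil(r_out / px)) + 2
    ci, cj = int(round(cy / px)), int(round(cx / px))
    sl = (slice(max(ci - pad, 0), min(ci + pad + 1, spec.image_shape_px[0])),
          slice(max(cj - pad, 0), min(cj + pad + 1, spec.image_shape_px[1])))
    ii, jj = np.mgrid[sl]
    # pixel centres in um
    ypix = (ii + 0.5) * px
    xpix = (jj + 0.5) * px
    d = np.hypot(xpix - cx, ypix - cy)
    wall = (d >= r_in) & (d <= r_out)
    disk = d <= r_out
    phi = np.arctan2(ypix - cy, xpix - cx)
    modulation = 1.0 + amplitude * np.cos(phi - np.deg2rad(v.phase_deg))
    add = np.where(wall, modulation, 0.0)
    peak = add.max()
    if peak <= 0:
        raise ValueError(f"vessel at {v.center_um} um renders no wall pixels "
                         f"(diameter {v.diameter_um} um at {px} um/px)")
    add *= (v.pi_true - 1.0) * spec.background_median / peak
    return add, sl, wall, disk


def wedge_cv(values: np.ndarray, dx: np.ndarray, dy: np.ndarray,
             n_wedges: int = 8) -> float:
    """Population-SD/mean of per-wedge mean intensity.

    ``dx``/``dy`` are pixel offsets from the object centroid; pixels at
    the centroid fall in the angle-zero wedge by the atan2(0, 0) = 0
    convention.  Shared by the generator calibration and the radial-CV
    measurement so both speak the same wedge geometry.
    """
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    idx = np.minimum((phi / (2 * np.pi) * n_wedges).astype(int), n_wedges - 1)
    means = np.array([values[idx == k].mean() for k in range(n_wedges)
                      if np.any(idx == k)])
    mu = means.mean()
    return float(means.std() / mu) if mu != 0 else 0.0


def _solve_amplitude(v: VesselSpec, spec: MicrographSpec) -> float:
    """Amplitude of the angular mode reproducing radial_cv_true.

    Downstream measurement runs on the object's above-threshold (wall)
    pixels, and its wedge CV depends on the background baseline and the
    discrete pixel geometry -- so the amplitude is found by root-finding
    on the actual noiseless rendering measured the same way.
    """
    if v.radial_cv_true == 0:
        return 0.0

    def measured(a: float) -> float:
        add, sl, wall, _disk = _render_vessel(v, spec, a)
        vals = add[wall] + spec.background_median
        ii, jj = np.mgrid[sl]
        ci = ii[wall].mean()
        cj = jj[wall].mean()
        return wedge_cv(vals, jj[wall] - cj, ii[wall] - ci)

    f = lambda a: measured(a) - v.radial_cv_true
    hi = 0.999
    if f(hi) < 0:
        raise ValueError(
            f"radial_cv_true={v.radial_cv_true} unreachable for vessel at "
            f"{v.center_um} um (max achievable {measured(hi):.3f})")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))


def make_vessel_micrograph(spec: MicrographSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the micrograph and return it with the ground-truth table.

    The table lists, per vessel: centre, outer diameter, class under the
    10 um rule, and the prescribed polarization index and radial CV.
    Deterministic given ``spec.seed`` (only noise is stochastic).
    """
    _check_layout(spec)
    img = np.full(spec.image_shape_px, float(spec.background_median))
    rows = []
    for k, v in enumerate(spec.vessels):
        a = _solve_amplitude(v, spec)
        add, sl, wall, _disk = _render_vessel(v, spec, a)
        img[sl] = np.where(wall, spec.background_median + add, img[sl])
        rows.append({
            "vessel_id": k,
            "cx_um": v.center_um[0], "cy_um": v.center_um[1],
            "diameter_um": v.diameter_um,
            "wall_thickness_um": v.wall_thickness_um,
            "class": v.truth_class,
            "pi_true": v.pi_true,
            "radial_cv_true": v.radial_cv_true,
        })
    rng = np.random.default_rng(spec.seed)
    if spec.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img, pd.DataFrame(rows)
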