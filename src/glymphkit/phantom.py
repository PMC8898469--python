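"""Synthetic 3D brain phantoms and simulated MR image series.

The phantom emulates a post-contrast mouse-head acquisition after
cisterna-magna infusion of a gadolinium tracer: compartments with known
T1/M0, a smooth transmit (B1+) inhomogeneity field, a variable-flip-angle
spoiled gradient-echo (VFA-SPGR) series and a double-angle B1-mapping
pair, both optionally degraded with Rician magnitude noise.  Every
quantity carries its ground truth so downstream estimators can be
validated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "LABEL_CODES",
    "TIV_LABELS",
    "default_phantom_spec",
    "make_brain_phantom",
    "spgr_signal",
    "rician",
    "simulate_vfa_series",
    "simulate_dam_pair",
]

# Compartment label codes.  0 is background by convention.
LABEL_CODES: dict[str, int] = {
    "background": 0,
    "parenchyma_unreached": 1,
    "parenchyma_reached": 2,
    "ventricle": 3,
    "olfactory_bulb": 4,
    "nasal_cavity": 5,
    "dcln_left": 6,
    "dcln_right": 7,
}

#: Labels whose union constitutes the total intracranial volume (TIV).
TIV_LABELS: tuple[str, ...] = (
    "parenchyma_unreached",
    "parenchyma_reached",
    "ventricle",
    "olfactory_bulb",
)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional grid coordinates (0..1)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        acc = np.zeros(grid_shape, dtype=float)
        for ax in range(3):
            c = self.center[ax] * (grid_shape[ax] - 1)
            r = self.radii[ax] * grid_shape[ax]
            acc += ((idx[ax] - c) / r) ** 2
        return acc <= 1.0


# T1/M0 defaults (ms / arbitrary units) at 9.4 T-plausible post-contrast
# values: "reached" compartments fall inside the 1-1700 ms tracer window,
# "unreached" ones outside it.  Reached parenchyma draws per-voxel T1
# uniformly from a range to emulate graded tracer concentration.
_DEFAULT_T1: dict[str, float | tuple[float, float]] = {
    "background": 3000.0,
    "parenchyma_unreached": 2000.0,
    "parenchyma_reached": (900.0, 1500.0),
    "ventricle": 3200.0,
    "olfactory_bulb": 1000.0,
    "nasal_cavity": 1200.0,
    "dcln_left": 1400.0,
    "dcln_right": 1400.0,
}

_DEFAULT_M0: dict[str, float] = {
    "background": 0.0,
    "parenchyma_unreached": 0.90,
    "parenchyma_reached": 0.95,
    "ventricle": 1.0,
    "olfactory_bulb": 0.90,
    "nasal_cavity": 0.80,
    "dcln_left": 0.85,
    "dcln_right": 0.85,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and noise model of a brain phantom.

    ``unreached_core`` carves the deep parenchyma that the tracer has not
    penetrated; the shell between it and the intracranial ellipsoid is the
    "reached" compartment.  Extracranial compartments (nasal cavity and
    deep cervical lymph nodes) must not overlap the head or each other.
    """

    grid_shape: tuple[int, int, int] = (100, 100, 100)
    voxel_size_mm: float = 0.18
    intracranial: Ellipsoid = Ellipsoid((0.50, 0.55, 0.50), (0.30, 0.30, 0.26))
    unreached_core: Ellipsoid = Ellipsoid((0.50, 0.55, 0.50), (0.18, 0.18, 0.156))
    ventricle: Ellipsoid = Ellipsoid((0.50, 0.55, 0.52), (0.06, 0.08, 0.05))
    olfactory_bulb: Ellipsoid = Ellipsoid((0.50, 0.24, 0.50), (0.08, 0.06, 0.07))
    nasal_cavity: Ellipsoid = Ellipsoid((0.50, 0.08, 0.46), (0.09, 0.06, 0.07))
    dcln_left: Ellipsoid = Ellipsoid((0.30, 0.90, 0.24), (0.04, 0.05, 0.04))
    dcln_right: Ellipsoid = Ellipsoid((0.70, 0.90, 0.24), (0.04, 0.05, 0.04))
    t1_by_label: Mapping[str, float | tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_T1))
    m0_by_label: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_M0))
    b1_field_range: tuple[float, float] = (0.85, 1.15)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        lo, hi = self.b1_field_range
        if not (0.5 < lo <= hi < 1.5):
            raise ValueError(f"b1_field_range must lie within (0.5, 1.5), got {self.b1_field_range}")
        for name, t1 in self.t1_by_label.items():
            vals = t1 if isinstance(t1, (tuple, list)) else (t1,)
            if any(v <= 0 for v in vals):
                raise ValueError(f"T1 for {name!r} must be positive, got {t1}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        for key, val in raw.items():
            if isinstance(val, dict) and {"center", "radii"} <= set(val):
                raw[key] = Ellipsoid(tuple(val["center"]), tuple(val["radii"]))
            elif isinstance(val, list):
                raw[key] = tuple(val)
        if "t1_by_label" in raw:
            raw["t1_by_label"] = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in raw["t1_by_label"].items()
            }
        return cls(**raw)


def default_phantom_spec(grid_shape: tuple[int, int, int] = (100, 100, 100),
                         **overrides) -> PhantomSpec:
    """Spec with the default mouse-head geometry at the given grid size."""
    return PhantomSpec(grid_shape=tuple(grid_shape), **overrides)


@dataclass
class PhantomTruth:
    """Ground-truth fields of a generated phantom."""

    label_volume: np.ndarray          # integer compartment codes
    t1_volume: np.ndarray             # ms
    b1_volume: np.ndarray             # dimensionless multiplier
    m0_volume: np.ndarray             # arbitrary units
    voxel_size_mm: float
    label_names: dict[int, str]
    true_volumes_mm3: dict[str, float]

    def mask(self, name: str) -> np.ndarray:
        return self.label_volume == LABEL_CODES[name]

    @property
    def tiv_mask(self) -> np.ndarray:
        codes = [LABEL_CODES[n] for n in TIV_LABELS]
        return np.isin(self.label_volume, codes)

    @property
    def tiv_mm3(self) -> float:
        return float(sum(self.true_volumes_mm3[n] for n in TIV_LABELS))


def _smooth_b1_field(grid_shape: tuple[int, int, int],
                     b1_range: tuple[float, float]) -> np.ndarray:
    """Low-order polynomial transmit-field ramp, min-max scaled to range."""
    u, v, w = (np.linspace(0.0, 1.0, n).astype(float) for n in grid_shape)
    U, V, W = np.meshgrid(u, v, w, indexing="ij")
    poly = 0.55 * U + 0.25 * V + 0.45 * W**2 - 0.30 * U * W
    lo, hi = b1_range
    pmin, pmax = poly.min(), poly.max()
    if pmax == pmin:
        return np.full(grid_shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (poly - pmin) / (pmax - pmin)


def make_brain_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterise the compartment geometry and assign ground-truth fields.

    The label map is purely geometric (seed-independent); ``spec.seed``
    only drives the per-voxel T1 draw inside compartments whose T1 is
    given as a range.  Overlapping extracranial compartments or a
    ventricle escaping the skull are rejected.
    """
    shape = tuple(spec.grid_shape)
    intracranial = spec.intracranial.mask(shape)
    ventricle = spec.ventricle.mask(shape)
    bulb = spec.olfactory_bulb.mask(shape)
    core = spec.unreached_core.mask(shape)

    if not np.all(intracranial[ventricle]):
        raise ValueError("ventricle compartment extends outside the intracranial ellipsoid")

    head = intracranial | bulb
    extracranial = {
        "nasal_cavity": spec.nasal_cavity.mask(shape),
        "dcln_left": spec.dcln_left.mask(shape),
        "dcln_right": spec.dcln_right.mask(shape),
    }
    names = list(extracranial)
    for i, a in enumerate(names):
        if np.any(extracranial[a] & head):
            raise ValueError(f"compartment {a!r} overlaps the intracranial/olfactory region")
        for b in names[i + 1:]:
            if np.any(extracranial[a] & extracranial[b]):
                raise ValueError(f"compartments {a!r} and {b!r} overlap")

    labels = np.zeros(shape, dtype=np.uint8)
    parenchyma = intracranial & ~ventricle & ~bulb
    labels[parenchyma & core] = LABEL_CODES["parenchyma_unreached"]
    labels[parenchyma & ~core] = LABEL_CODES["parenchyma_reached"]
    labels[ventricle] = LABEL_CODES["ventricle"]
    labels[bulb] = LABEL_CODES["olfactory_bulb"]
    for name, m in extracranial.items():
        labels[m] = LABEL_CODES[name]

    rng = np.random.default_rng(spec.seed)
    t1 = np.zeros(shape, dtype=float)
    m0 = np.zeros(shape, dtype=float)
    for name, code in LABEL_CODES.items():
        sel = labels == code
        t1_spec = spec.t1_by_label.get(name, _DEFAULT_T1[name])
        if isinstance(t1_spec, (tuple, list)):
            lo, hi = t1_spec
            t1[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
        else:
            t1[sel] = float(t1_spec)
        m0[sel] = float(spec.m0_by_label.get(name, _DEFAULT_M0[name]))

    b1 = _smooth_b1_field(shape, spec.b1_field_range)

    vox3 = spec.voxel_size_mm ** 3
    volumes = {
        name: float(np.count_nonzero(labels == code)) * vox3
        for name, code in LABEL_CODES.items() if name != "background"
    }
    return PhantomTruth(
        label_volume=labels,
        t1_volume=t1,
        b1_volume=b1,
        m0_volume=m0,
        voxel_size_mm=spec.voxel_size_mm,
        label_names={c: n for n, c in LABEL_CODES.items()},
        true_volumes_mm3=volumes,
    )


def spgr_signal(t1_ms, m0, b1, flip_deg, tr_ms):
    """Steady-state spoiled gradient-echo magnitude signal.

    S = M0 sin(B1*theta) (1 - E1) / (1 - E1 cos(B1*theta)),
    E1 = exp(-TR/T1).  Inputs broadcast; angles in degrees.
    """
    theta = np.deg2rad(np.asarray(flip_deg, dtype=float)) * np.asarray(b1, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return np.asarray(m0, dtype=float) * np.sin(theta) * (1.0 - e1) / (1.0 - e1 * np.cos(theta))


def rician(signal: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-image noise: sqrt((S+n1)^2 + n2^2), n1,n2 ~ N(0, sd)."""
    if sd == 0:
        return np.asarray(signal, dtype=float).copy()
    n1 = rng.normal(0.0, sd, size=np.shape(signal))
    n2 = rng.normal(0.0, sd, size=np.shape(signal))
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def _check_truth_finite(truth: PhantomTruth) -> None:
    if not (np.all(np.isfinite(truth.t1_volume)) and np.all(np.isfinite(truth.m0_volume))):
        raise ValueError("phantom T1/M0 fields contain non-finite values")


def simulate_vfa_series(truth: PhantomTruth, protocol: AcquisitionProtocol,
                        noise_sd: float = 0.0, seed: int | None = None) -> np.ndarray:
    """Simulate one SPGR volume per nominal flip angle.

    Returns an array of shape ``(n_angles,) + grid``.  With
    ``noise_sd = 0`` the output is the exact noiseless signal model;
    otherwise Rician noise is applied per image from a single seeded
    generator.
    """
    _check_truth_finite(truth)
    rng = np.random.default_rng(seed)
    out = np.empty((len(protocol.flip_angles_deg),) + truth.t1_volume.shape, dtype=float)
    for i, ang in enumerate(protocol.flip_angles_deg):
        s = spgr_signal(truth.t1_volume, truth.m0_volume, truth.b1_volume,
                        ang, protocol.tr_ms)
        out[i] = rician(s, noise_sd, rng)
    return out


def simulate_dam_pair(truth: PhantomTruth, protocol: AcquisitionProtocol,
                      noise_sd: float = 0.0, seed: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the double-angle pair (alpha, 2*alpha).

    Long-TR regime: relaxation is complete between excitations, so the
    signal is proportional to the sine of the effective angle,
    S_a = M0 sin(B1*a) and S_2a = M0 sin(2*B1*a).
    """
    _check_truth_finite(truth)
    rng = np.random.default_rng(seed)
    a = np.deg2rad(protocol.dam_angle_deg)
    s1 = truth.m0_volume * np.sin(truth.b1_volume * a)
    s2 = truth.m0_volume * np.sin(2.0 * truth.b1_volume * a)
    return rician(s1, noise_sd, rng), rician(s2, noise_sd, rng)
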