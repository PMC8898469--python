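"""Acquisition metadata for the VFA-SPGR and double-angle series."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Pulse-sequence parameters needed by the signal model and the fits.

    Parameters
    ----------
    tr_ms : float
        Repetition time of the spoiled gradient-echo readout, in ms.
    te_ms : float
        Echo time in ms. Metadata only: with a single echo the T2*
        weighting is a constant factor absorbed into M0.
    flip_angles_deg : tuple of float
        Nominal flip angles of the variable-flip-angle series, strictly
        increasing, in degrees.
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    dam_angle_deg : float
        Base angle alpha of the double-angle (alpha, 2*alpha) B1-mapping
        pair, in degrees.
    """

    tr_ms: float = 16.0
    te_ms: float = 3.0
    flip_angles_deg: tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    voxel_size_mm: float = 0.18
    dam_angle_deg: float = 70.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if self.voxel_size_mm <= 0:
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        angles = tuple(float(a) for a in self.flip_angles_deg)
        if len(angles) < 2:
            raise ValueError("need at least two flip angles")
        if any(not (0.0 < a < 180.0) for a in angles):
            raise ValueError(f"flip angles must lie in (0, 180) deg: {angles}")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError(f"flip angles must be strictly increasing: {angles}")
        if not (0.0 < self.dam_angle_deg <= 90.0):
            raise ValueError(f"dam_angle_deg must lie in (0, 90], got {self.dam_angle_deg}")
        object.__setattr__(self, "flip_angles_deg", angles)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionProtocol":
        raw = json.loads(Path(path).read_text())
        raw["flip_angles_deg"] = tuple(raw["flip_angles_deg"])
        return cls(**raw)
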