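"""Tracer-window cluster volumetrics and brain morphometry.

After cisterna-magna infusion of a gadolinium tracer, tissue reached by
the tracer exhibits shortened T1; voxels with T1 inside a fixed window
(default [1, 1700] ms, both bounds inclusive) are classified as
tracer-reached and their summed physical volume is the transport or
drainage metric.  Morphometry (TIV, ventricles, olfactory bulb, lymph
nodes) is plain label-volume bookkeeping: count times voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import LABEL_CODES, TIV_LABELS, PhantomTruth
from .t1_mapping import T1Volume

__all__ = [
    "RoiSet",
    "ClusterResult",
    "threshold_t1_cluster",
    "compute_morphometry",
    "glymphatic_pct",
    "DrainageReport",
    "drainage_report",
]


@dataclass
class RoiSet:
    """Integer ROI label volume plus code-to-name mapping and voxel size."""

    label_volume: np.ndarray
    names: dict[int, str]
    voxel_size_mm: float
    tiv_codes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if np.any(self.label_volume < 0):
            raise ValueError("ROI codes must be non-negative")
        if not self.tiv_codes:
            self.tiv_codes = tuple(c for c in self.names if self.names[c] != "background" and c != 0)

    @classmethod
    def from_phantom(cls, truth: PhantomTruth) -> "RoiSet":
        return cls(
            label_volume=truth.label_volume,
            names=dict(truth.label_names),
            voxel_size_mm=truth.voxel_size_mm,
            tiv_codes=tuple(LABEL_CODES[n] for n in TIV_LABELS),
        )

    def code(self, name: str) -> int:
        for c, n in self.names.items():
            if n == name:
                return c
        raise KeyError(f"ROI {name!r} not present in this label set "
                       f"(available: {sorted(self.names.values())})")

    def mask(self, name: str) -> np.ndarray:
        return self.label_volume == self.code(name)

    @property
    def tiv_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, self.tiv_codes)

    def volume_mm3(self, name: str) -> float:
        return float(np.count_nonzero(self.mask(name))) * self.voxel_size_mm ** 3


@dataclass
class ClusterResult:
    """In-window voxel cluster inside one ROI."""

    roi: str
    voxel_count: int
    volume_mm3: float
    lo_ms: float
    hi_ms: float
    percent: float | None = None
    reference: str | None = None


def threshold_t1_cluster(t1: T1Volume, roi_mask: np.ndarray, roi_name: str = "roi",
                         voxel_size_mm: float = 0.18,
                         lo_ms: float = 1.0, hi_ms: float = 1700.0) -> ClusterResult:
    """Count valid ROI voxels with lo <= T1 <= hi (inclusive bounds).

    Invalid fit voxels are never counted.  An empty ROI yields a zero
    cluster, not an error.
    """
    if lo_ms > hi_ms:
        raise ValueError(f"lo_ms ({lo_ms}) must not exceed hi_ms ({hi_ms})")
    if t1.t1_ms.shape != roi_mask.shape:
        raise ValueError(f"T1 grid {t1.t1_ms.shape} != ROI grid {roi_mask.shape}")
    sel = roi_mask & t1.valid
    vals = t1.t1_ms[sel]
    n = int(np.count_nonzero((vals >= lo_ms) & (vals <= hi_ms)))
    return ClusterResult(
        roi=roi_name, voxel_count=n, volume_mm3=n * voxel_size_mm ** 3,
        lo_ms=lo_ms, hi_ms=hi_ms)


def glymphatic_pct(cluster: ClusterResult, reference_volume_mm3: float,
                   reference_name: str = "TIV") -> float:
    """Cluster volume as a percentage of a reference volume.

    The result (and which reference was used) is also recorded on the
    cluster itself.
    """
    if reference_volume_mm3 <= 0:
        raise ValueError(f"reference volume must be positive, got {reference_volume_mm3}")
    pct = 100.0 * cluster.volume_mm3 / reference_volume_mm3
    cluster.percent = pct
    cluster.reference = reference_name
    return pct


def compute_morphometry(rois: RoiSet) -> pd.DataFrame:
    """Per-ROI physical volumes plus derived metrics.

    Derived rows: TIV (union of intracranial codes), total dcLN
    (left + right when present), and the cerebral-ventricle volume
    fraction of TIV in percent (NaN-flagged when TIV is empty).
    """
    vox3 = rois.voxel_size_mm ** 3
    rows = []
    for code, name in sorted(rois.names.items()):
        if code == 0 or name == "background":
            continue
        n = int(np.count_nonzero(rois.label_volume == code))
        rows.append({"roi": name, "voxel_count": n, "volume_mm3": n * vox3})
    df = pd.DataFrame(rows)

    tiv_n = int(np.count_nonzero(rois.tiv_mask))
    derived = [{"roi": "TIV", "voxel_count": tiv_n, "volume_mm3": tiv_n * vox3}]

    present = set(df["roi"]) if len(df) else set()
    if {"dcln_left", "dcln_right"} <= present:
        n = int(df.loc[df["roi"].isin(["dcln_left", "dcln_right"]), "voxel_count"].sum())
        derived.append({"roi": "dcln_total", "voxel_count": n, "volume_mm3": n * vox3})
    if "ventricle" in present:
        vn = int(df.loc[df["roi"] == "ventricle", "voxel_count"].iloc[0])
        frac = 100.0 * vn / tiv_n if tiv_n > 0 else float("nan")
        derived.append({"roi": "cv_fraction_of_tiv_pct", "voxel_count": vn,
                        "volume_mm3": frac})
    return pd.concat([df, pd.DataFrame(derived)], ignore_index=True)


@dataclass
class DrainageReport:
    """Drained (in-window) volumes for the extracranial targets.

    ``dcln_roi_volume_mm3`` is the anatomical lymph-node ROI volume,
    attached as a lymphadenopathy check; it depends only on the labels,
    never on T1 content.
    """

    clusters: dict[str, ClusterResult]
    dcln_roi_volume_mm3: float


def drainage_report(t1: T1Volume, rois: RoiSet,
                    lo_ms: float = 1.0, hi_ms: float = 1700.0) -> DrainageReport:
    """Tracer-window cluster volumes for the nasal cavity and the deep
    cervical lymph nodes (per side and combined)."""
    clusters: dict[str, ClusterResult] = {}
    vox = rois.voxel_size_mm
    for name in ("nasal_cavity", "dcln_left", "dcln_right"):
        try:
            mask = rois.mask(name)
        except KeyError as err:
            raise KeyError(f"drainage ROI missing from label set: {name!r}") from err
        clusters[name] = threshold_t1_cluster(t1, mask, name, vox, lo_ms, hi_ms)

    n = clusters["dcln_left"].voxel_count + clusters["dcln_right"].voxel_count
    clusters["dcln_total"] = ClusterResult(
        roi="dcln_total", voxel_count=n, volume_mm3=n * vox ** 3,
        lo_ms=lo_ms, hi_ms=hi_ms)
    return DrainageReport(
        clusters=clusters,
        dcln_roi_volume_mm3=rois.volume_mm3("dcln_left") + rois.volume_mm3("dcln_right"))
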