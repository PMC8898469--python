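"""Readers/writers for the standard formats used across the pipeline.

Volumes travel as NIfTI with the voxel size encoded in a diagonal
affine; micrographs as single-channel TIFF with a JSON metadata sidecar
(pixel size, animal id, genotype); tables as CSV.  Every output
directory gets a provenance manifest recording parameters and seeds.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "save_nifti", "load_nifti",
    "save_tiff", "load_tiff",
    "write_manifest",
]


def save_nifti(data: np.ndarray, path: str | Path, voxel_size_mm: float) -> Path:
    """Write a volume with an isotropic diagonal affine (canonical RAS axes)."""
    path = Path(path)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Load a volume; returns the data array and the voxel edge in mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as err:
        raise IOError(f"failed to read NIfTI volume {path}: {err}") from err
    zooms = img.header.get_zooms()[:3]
    return data, float(zooms[0])


def save_tiff(image: np.ndarray, path: str | Path, pixel_size_um: float,
              meta: dict | None = None) -> Path:
    """Write a single-channel TIFF plus a JSON sidecar with the pixel size."""
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    sidecar = dict(meta or {})
    sidecar["pixel_size_um"] = pixel_size_um
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a micrograph and its JSON sidecar (empty dict when absent)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TIFF image not found: {path}")
    image = tifffile.imread(str(path)).astype(float)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return image, meta


def write_manifest(out_dir: str | Path, params: dict, name: str = "manifest.json") -> Path:
    """Provenance manifest: parameters, seeds, package version, timestamp."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "glymphkit",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "axis_order": "index (i, j, k) with isotropic diagonal affine",
        "parameters": params,
    }
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
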