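"""Perivascular AQP4 quantification on single-channel micrographs.

Pipeline: robust-background segmentation of AQP4+ vessels, rule-based
classification into capillaries (< 10 um equivalent diameter) and small
vessels, then two intensity metrics per object:

* polarization index (PI) -- maximum object intensity divided by the
  median intensity of a 32.5 um radially expanded background region
  (all segmented objects excluded from the background);
* radial CV -- coefficient of variation of mean intensity across equal
  angular wedges about the object centroid, a measure of circumferential
  uniformity of the endfoot labeling.

A stereological area-fraction estimator (counting-frame/point-grid
fractionator) and per-animal summarisation feed the statistics layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .micrograph import wedge_cv, CAPILLARY_DIAMETER_UM

__all__ = [
    "SegmentationParams",
    "AreaFractionResult",
    "segment_vessels",
    "classify_objects",
    "polarization_index",
    "radial_cv",
    "measure_vessels",
    "area_fraction",
    "summarize_by_animal",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the robust-background segmentation and the rule-based
    classifier standing in for a trained object classifier."""

    trim_frac: float = 0.05        # fraction trimmed per intensity tail
    k_sd: float = 2.0              # threshold = trimmed mean + k_sd * trimmed SD
    min_area_um2: float = 3.0      # objects below this are dropped
    aspect_ratio_limit: float = 3.0  # elongated objects (oblique sections) rejected
    expansion_um: float = 32.5     # background annulus radius
    n_wedges: int = 8


def robust_threshold(image: np.ndarray,
                     params: SegmentationParams = SegmentationParams()) -> float:
    """Robust-background threshold: trimmed mean + k * trimmed SD."""
    flat = np.sort(np.asarray(image, dtype=float).ravel())
    n = flat.size
    cut = int(np.floor(params.trim_frac * n))
    body = flat[cut:n - cut] if n - 2 * cut > 1 else flat
    return float(body.mean() + params.k_sd * body.std())


def segment_vessels(image: np.ndarray, pixel_size_um: float,
                    params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Label image of AQP4+ objects.

    Threshold = mean + k*SD of the intensities after discarding the
    dimmest and brightest ``trim_frac`` tails ("robust background");
    the mask is hole-filled, 8-connected components are labelled, and
    components below the minimum area are removed.  Invariant to adding
    a constant offset to the image.  A constant image yields zero
    objects with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {image.shape}")
    thr = robust_threshold(image, params)
    binary = image > thr
    if not binary.any():
        warnings.warn("no pixels above the robust-background threshold; "
                      "zero objects segmented")
        return np.zeros(image.shape, dtype=np.int32)
    filled = ndimage.binary_fill_holes(binary)
    labels = measure.label(filled, connectivity=2)
    min_px = params.min_area_um2 / pixel_size_um ** 2
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_px)
    labels[np.isin(labels, small[small > 0])] = 0
    return measure.label(labels > 0, connectivity=2).astype(np.int32)


def classify_objects(objects: pd.DataFrame, pixel_size_um: float | None = None,
                     params: SegmentationParams = SegmentationParams()) -> pd.Series:
    """Class per measured object: capillary, small_vessel, or reject.

    Pure function of geometry -- rejects elongated or sub-floor objects
    (oblique sections, thresholding debris), then splits on equivalent
    diameter at 10 um (exactly 10 um counts as a small vessel).
    Requires columns ``equiv_diameter_um``, ``area_um2``, ``aspect_ratio``.
    """
    cls = np.where(
        (objects["aspect_ratio"] > params.aspect_ratio_limit)
        | (objects["area_um2"] < params.min_area_um2),
        "reject",
        np.where(objects["equiv_diameter_um"] < CAPILLARY_DIAMETER_UM,
                 "capillary", "small_vessel"))
    return pd.Series(cls, index=objects.index, name="class")


def polarization_index(object_mask: np.ndarray, image: np.ndarray,
                       pixel_size_um: float, expansion_um: float = 32.5,
                       all_objects_mask: np.ndarray | None = None) -> float:
    """Max object intensity over the median of the expanded background.

    The background region is the object dilated radially by
    ``expansion_um`` (Euclidean boundary distance), minus the union of
    all segmented objects so neighbouring vessels never contaminate the
    background estimate.  Returns NaN (flagged) when the background is
    empty or has zero median.
    """
    if not object_mask.any():
        return float("nan")
    dist_px = ndimage.distance_transform_edt(~object_mask)
    ring = (dist_px > 0) & (dist_px * pixel_size_um <= expansion_um)
    if all_objects_mask is not None:
        ring &= ~all_objects_mask
    if not ring.any():
        return float("nan")
    bg = float(np.median(image[ring]))
    if bg == 0:
        return float("nan")
    return float(image[object_mask].max() / bg)


def radial_cv(object_mask: np.ndarray, image: np.ndarray, n_wedges: int = 8) -> float:
    """Wedge-based coefficient of variation of the object's intensity.

    Object pixels are partitioned into ``n_wedges`` equal angular
    sectors about the (unweighted) centroid; the CV is population-SD
    over mean of the per-wedge mean intensities.  Scale-invariant.
    """
    ii, jj = np.nonzero(object_mask)
    if ii.size < n_wedges:
        raise ValueError(
            f"object has {ii.size} pixels; need at least n_wedges={n_wedges}")
    ci, cj = ii.mean(), jj.mean()
    return wedge_cv(image[ii, jj].astype(float), jj - cj, ii - ci, n_wedges)


def measure_vessels(image: np.ndarray, pixel_size_um: float,
                    params: SegmentationParams = SegmentationParams()) -> pd.DataFrame:
    """Segment, measure and classify every object in a micrograph.

    Returns one row per object with geometry, PI, radial CV and class.
    Geometry and PI use the hole-filled object; the radial CV uses the
    object's above-threshold pixels (the labelled wall itself), so a
    circumferentially uniform wall reads CV = 0.  Objects whose PI is
    undefined are flagged (``pi_valid = False``) and excluded from
    downstream summaries.
    """
    labels = segment_vessels(image, pixel_size_um, params)
    all_mask = labels > 0
    bright = np.asarray(image, dtype=float) > robust_threshold(image, params)
    rows = []
    for rp in measure.regionprops(labels, intensity_image=image):
        area_um2 = rp.area * pixel_size_um ** 2
        minor = rp.axis_minor_length
        aspect = rp.axis_major_length / minor if minor > 0 else np.inf
        obj = labels == rp.label
        pi = polarization_index(obj, image, pixel_size_um,
                                params.expansion_um, all_mask)
        wall = obj & bright
        cv_mask = wall if np.count_nonzero(wall) >= params.n_wedges else obj
        cv = radial_cv(cv_mask, image, params.n_wedges) \
            if np.count_nonzero(cv_mask) >= params.n_wedges else np.nan
        rows.append({
            "object_id": rp.label,
            "centroid_row": rp.centroid[0],
            "centroid_col": rp.centroid[1],
            "area_um2": area_um2,
            "equiv_diameter_um": 2.0 * np.sqrt(area_um2 / np.pi),
            "aspect_ratio": aspect,
            "max_intensity": float(rp.intensity_max),
            "pi": pi,
            "radial_cv": cv,
            "pi_valid": bool(np.isfinite(pi)),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["class"] = classify_objects(df, pixel_size_um, params)
    else:
        df = pd.DataFrame(columns=[
            "object_id", "centroid_row", "centroid_col", "area_um2",
            "equiv_diameter_um", "aspect_ratio", "max_intensity", "pi",
            "radial_cv", "pi_valid", "class"])
    return df


@dataclass
class AreaFractionResult:
    fraction: float
    hits: int
    total_markers: int
    grid_origin_um: tuple[float, float]


def area_fraction(mask: np.ndarray, pixel_size_um: float,
                  roi_mask: np.ndarray | None = None,
                  frame_um: float = 100.0, grid_um: float = 200.0,
                  marker_um: float = 10.0, seed: int | None = None
                  ) -> AreaFractionResult:
    """Stereological area-fraction fractionator estimate.

    A ``frame_um``-square counting frame sits at each node of a
    ``grid_um``-square grid whose origin is drawn uniformly from the
    grid period (the only stochastic step, reproducible by ``seed``);
    with the defaults this is an area sampling fraction of 1/4.  Probe
    markers are spaced every ``marker_um`` within each frame, and the
    estimate is (markers hitting the mask) / (markers inside the ROI).
    Falls back to a full-ROI marker lattice with a warning when the ROI
    cannot hold a single frame.
    """
    mask = np.asarray(mask, dtype=bool)
    if roi_mask is None:
        roi_mask = np.ones(mask.shape, dtype=bool)
    h_um = mask.shape[0] * pixel_size_um
    w_um = mask.shape[1] * pixel_size_um
    rng = np.random.default_rng(seed)
    ox, oy = rng.uniform(0.0, grid_um, size=2)

    rows = np.flatnonzero(roi_mask.any(axis=1))
    cols = np.flatnonzero(roi_mask.any(axis=0))
    roi_h = (rows[-1] - rows[0] + 1) * pixel_size_um if rows.size else 0.0
    roi_w = (cols[-1] - cols[0] + 1) * pixel_size_um if cols.size else 0.0

    offsets = (np.arange(int(round(frame_um / marker_um))) + 0.5) * marker_um
    xs_list, ys_list = [], []
    if roi_h < frame_um or roi_w < frame_um:
        warnings.warn("ROI smaller than one counting frame; using a "
                      "full-ROI marker lattice")
        xs = np.arange(ox % marker_um, w_um, marker_um)
        ys = np.arange(oy % marker_um, h_um, marker_um)
        X, Y = np.meshgrid(xs, ys)
        xs_list.append(X.ravel())
        ys_list.append(Y.ravel())
    else:
        gx = np.arange(ox - grid_um, w_um, grid_um)
        gy = np.arange(oy - grid_um, h_um, grid_um)
        for fy in gy:
            for fx in gx:
                X, Y = np.meshgrid(fx + offsets, fy + offsets)
                xs_list.append(X.ravel())
                ys_list.append(Y.ravel())
    x = np.concatenate(xs_list)
    y = np.concatenate(ys_list)
    inside = (x >= 0) & (x < w_um) & (y >= 0) & (y < h_um)
    x, y = x[inside], y[inside]
    px = np.floor(x / pixel_size_um).astype(int)
    py = np.floor(y / pixel_size_um).astype(int)
    in_roi = roi_mask[py, px]
    px, py = px[in_roi], py[in_roi]
    total = int(px.size)
    hits = int(np.count_nonzero(mask[py, px]))
    frac = hits / total if total else float("nan")
    return AreaFractionResult(fraction=frac, hits=hits, total_markers=total,
                              grid_origin_um=(float(ox), float(oy)))


def summarize_by_animal(objects: pd.DataFrame,
                        hippocampus_area_um2: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """Per-animal, per-class object counts and mean PI / radial CV.

    ``objects`` needs columns animal, genotype, class, pi, radial_cv,
    pi_valid.  Rejected and PI-flagged objects are excluded; animals
    with zero valid objects in a class get NaN means with n = 0.
    """
    valid = objects[(objects["class"] != "reject") & objects["pi_valid"]]
    animals = objects[["animal", "genotype"]].drop_duplicates()
    rows = []
    for _, a in animals.iterrows():
        for cls in ("capillary", "small_vessel"):
            sub = valid[(valid["animal"] == a["animal"]) & (valid["class"] == cls)]
            rows.append({
                "animal": a["animal"],
                "genotype": a["genotype"],
                "vessel_class": cls,
                "n_objects": len(sub),
                "mean_pi": sub["pi"].mean() if len(sub) else float("nan"),
                "mean_radial_cv": sub["radial_cv"].mean() if len(sub) else float("nan"),
                "hippocampus_area_um2": (hippocampus_area_um2 or {}).get(
                    a["animal"], float("nan")),
            })
    return pd.DataFrame(rows)
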