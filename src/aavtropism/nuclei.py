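"""DAPI nucleus segmentation and per-nucleus channel quantification.

Every nucleus visible in the DAPI channel gets its own region of interest,
and the mean intensity of each of the four channels over that region is the
measurement unit for all downstream positivity calls. Segmentation is the
standard deterministic pipeline: Gaussian smoothing, Otsu thresholding,
hole filling, distance-transform watershed to split touching nuclei, and an
area filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .image import ROLE_WAVELENGTH, ROLES, ImageStack

#: Stable measurement-table columns (wavelength naming used on disk).
NUCLEUS_COLUMNS = ["nucleus_id", "row", "col", "area_px",
                   "mean_dapi", "mean_633", "mean_488", "mean_546"]

#: Role-based aliases used throughout the in-memory API.
ROLE_COLUMNS = {role: f"mean_{ROLE_WAVELENGTH[role]}" for role in ROLES}


def segment_nuclei(image: ImageStack, min_area_px: int = 12,
                   max_area_px: int = 2000, smooth_sigma: float = 2.0,
                   peak_min_distance: int = 5,
                   exclude_border: bool = False) -> np.ndarray:
    """Segment DAPI nuclei; returns an int32 label map (0 = background).

    Touching nuclei are split by a watershed on the distance transform of
    the thresholded DAPI mask, seeded at distance-transform peaks. Regions
    outside [min_area_px, max_area_px] are dropped and labels relabelled
    consecutively from 1. Fully deterministic.
    """
    dapi = np.asarray(image.channel("dapi"), dtype=np.float64)
    if dapi.size == 0:
        raise ValueError("empty image")
    smoothed = gaussian(dapi, sigma=smooth_sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndimage.distance_transform_edt(mask)
    # local maxima of the distance transform seed the watershed; plateau
    # maxima are merged into one marker by connected-component labelling
    size = 2 * peak_min_distance + 1
    local_max = (distance == ndimage.maximum_filter(distance, size=size)) & mask
    markers, _ = ndimage.label(local_max)
    labels = watershed(-distance, markers.astype(np.int32), mask=mask)

    if exclude_border:
        border = np.zeros(dapi.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        for lab in np.unique(labels[border]):
            if lab:
                labels[labels == lab] = 0

    # area filter + consecutive relabelling
    ids, counts = np.unique(labels, return_counts=True)
    keep = ids[(ids > 0) & (counts >= min_area_px) & (counts <= max_area_px)]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return lut[labels]


def measure_nuclei(image: ImageStack, labels: np.ndarray,
                   roi_id: str = "whole_slice") -> pd.DataFrame:
    """Mean intensity of every channel within each nucleus label.

    Returns one row per label with columns ``nucleus_id, row, col, area_px``
    plus ``mean_dapi, mean_633, mean_488, mean_546`` (the 633/488/546
    channels carry the marker_a / gfp / marker_b roles respectively), and
    provenance columns ``image_id`` and ``roi_id``.
    """
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ValueError(f"label map shape {labels.shape} != image shape {image.shape}")
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(columns=NUCLEUS_COLUMNS + ["image_id", "roi_id"])
    flat = labels.ravel()
    nbins = n + 1
    areas = np.bincount(flat, minlength=nbins)[1:]
    rows_grid = np.repeat(np.arange(labels.shape[0], dtype=np.float64), labels.shape[1])
    cols_grid = np.tile(np.arange(labels.shape[1], dtype=np.float64), labels.shape[0])
    out = pd.DataFrame({
        "nucleus_id": np.arange(1, n + 1),
        "row": np.bincount(flat, weights=rows_grid, minlength=nbins)[1:] / areas,
        "col": np.bincount(flat, weights=cols_grid, minlength=nbins)[1:] / areas,
        "area_px": areas.astype(np.int64),
    })
    for role in ROLES:
        ch = np.asarray(image.channel(role), dtype=np.float64).ravel()
        out[ROLE_COLUMNS[role]] = np.bincount(flat, weights=ch, minlength=nbins)[1:] / areas
    out["image_id"] = image.image_id
    out["roi_id"] = roi_id
    return out


def quantify_image(image: ImageStack, roi=None, **segment_kwargs) -> pd.DataFrame:
    """Convenience: optionally crop to a circular ROI, segment and measure."""
    from .roi import crop_to_circle

    roi_id = "whole_slice"
    if roi is not None:
        image = crop_to_circle(image, roi)
        roi_id = "degenerate" if roi.degenerate else f"circle@{roi.center}"
    labels = segment_nuclei(image, **segment_kwargs)
    return measure_nuclei(image, labels, roi_id=roi_id)


def match_nuclei(truth: pd.DataFrame, table: pd.DataFrame,
                 max_dist_px: float = 5.0) -> dict[str, float]:
    """Greedy centroid matching of detected nuclei to ground truth.

    Each truth nucleus is matched to the nearest unmatched detection within
    ``max_dist_px``; returns precision, recall and F1 of detection.
    """
    from scipy.spatial import cKDTree

    t = truth[["row", "col"]].to_numpy(dtype=float)
    if len(table) == 0 or len(truth) == 0:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0,
                "n_truth": len(truth), "n_detected": len(table), "n_matched": 0}
    d = table[["row", "col"]].to_numpy(dtype=float)
    tree = cKDTree(d)
    dist, idx = tree.query(t, k=1)
    order = np.argsort(dist)
    used: set[int] = set()
    matched = 0
    for i in order:
        if dist[i] <= max_dist_px and idx[i] not in used:
            used.add(int(idx[i]))
            matched += 1
    precision = matched / len(d)
    recall = matched / len(t)
    f1 = 0.0 if matched == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_truth": len(truth), "n_detected": len(table), "n_matched": matched}
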