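"""Nuclear segmentation from the DAPI channel.

Nuclei are first detected in 2D on a maximum-intensity projection of the
DAPI stack with a single global threshold (Otsu by default, manual override
supported), size-filtered, and labelled. Each nucleus is then re-segmented
in 3D with its own cell-specific threshold set to background plus 50% of
the range between the brightest DAPI voxel in its column and the background
level, which absorbs cell-to-cell differences in DNA content and staining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "NucleusMap3D",
    "max_project",
    "detect_nuclei",
    "estimate_background",
    "per_nucleus_threshold",
    "segment_nuclei_3d",
    "nuclei_centroid_image",
]


@dataclass
class NucleusMap3D:
    """3D nucleus label volume with the per-nucleus thresholds that produced it.

    ``labels[z, y, x] == k`` marks a voxel of the nucleus of cell ``k``;
    0 is background.
    """

    labels: np.ndarray
    per_label_threshold: dict[int, float] = field(default_factory=dict)
    background_level: float = 0.0

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def footprint_2d(self) -> np.ndarray:
        """Project the 3D labels down to a 2D footprint (max over z)."""
        return self.labels.max(axis=0)


def max_project(volume: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over z: ``out[y, x] = max_z volume[z, y, x]``."""
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.size == 0:
        raise ValueError("expected a non-empty 3D (z, y, x) volume")
    return volume.max(axis=0)


def detect_nuclei(
    dapi_projection: np.ndarray,
    global_threshold: float | None = None,
    min_area: int = 20,
    max_area: int = 2000,
) -> np.ndarray:
    """Detect nuclei on a DAPI projection with one global threshold.

    The projection is binarised at ``global_threshold`` (Otsu's threshold on
    the projection when None), connected regions are labelled, regions whose
    area falls outside ``[min_area, max_area]`` are removed, and survivors
    are renumbered 1..K. A threshold above the image maximum yields an empty
    label image, not an error.
    """
    proj = np.asarray(dapi_projection)
    if proj.ndim != 2:
        raise ValueError("projection must be 2D")
    if min_area < 0 or max_area < 0:
        raise ValueError("area bounds must be non-negative")
    if min_area >= max_area:
        raise ValueError("min_area must be smaller than max_area")
    if global_threshold is None:
        if np.ptp(proj) == 0:
            return np.zeros(proj.shape, dtype=np.int32)
        global_threshold = threshold_otsu(proj)
    mask = proj > global_threshold
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero((areas >= min_area) & (areas <= max_area))
    keep = keep[keep > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[labels]


def estimate_background(dapi_projection: np.ndarray, nuclei_2d: np.ndarray) -> float:
    """Background DAPI level: median projection intensity outside all nuclei."""
    outside = np.asarray(dapi_projection)[np.asarray(nuclei_2d) == 0]
    if outside.size == 0:
        return 0.0
    return float(np.median(outside))


def per_nucleus_threshold(dapi_region_max: float, background: float) -> float:
    """Cell-specific DAPI cutoff: background + 50% of (region max - background)."""
    if background < 0:
        raise ValueError("background must be non-negative")
    if dapi_region_max < background:
        raise ValueError("region maximum below background level")
    return background + 0.5 * (dapi_region_max - background)


def segment_nuclei_3d(
    dapi_volume: np.ndarray,
    nuclei_2d: np.ndarray,
    background: float | None = None,
) -> NucleusMap3D:
    """Grow each 2D nucleus into 3D with its own 50%-of-range threshold.

    For every 2D label k the threshold is computed from the brightest DAPI
    voxel inside the 3D column over k's footprint. Voxels in that column at
    or above the threshold that are 26-connected to the brightest voxel
    receive label k. Labels whose column never reaches the threshold are
    skipped with a warning.
    """
    vol = np.asarray(dapi_volume)
    nuclei_2d = np.asarray(nuclei_2d)
    if vol.ndim != 3 or vol.shape[1:] != nuclei_2d.shape:
        raise ValueError("volume (z, y, x) and 2D labels (y, x) shapes disagree")
    if background is None:
        background = estimate_background(max_project(vol), nuclei_2d)
    out = np.zeros(vol.shape, dtype=np.int32)
    thresholds: dict[int, float] = {}
    structure = np.ones((3, 3, 3), bool)  # 26-connectivity
    for sl, k in _label_slices(nuclei_2d):
        footprint = nuclei_2d[sl] == k
        column = vol[(slice(None),) + sl]
        masked = np.where(footprint[None, :, :], column, -np.inf)
        peak = float(masked.max())
        if not np.isfinite(peak) or peak <= background:
            warnings.warn(f"nucleus {k}: no DAPI signal above background; skipped")
            continue
        thr = per_nucleus_threshold(peak, background)
        thresholds[k] = thr
        binary = masked >= thr
        comps, _ = ndimage.label(binary, structure=structure)
        seed = np.unravel_index(int(np.argmax(masked)), masked.shape)
        seed_comp = comps[seed]
        if seed_comp == 0:
            warnings.warn(f"nucleus {k}: empty 3D region; skipped")
            continue
        region = comps == seed_comp
        target = out[(slice(None),) + sl]
        target[region] = k
    return NucleusMap3D(
        labels=out, per_label_threshold=thresholds, background_level=float(background)
    )


def nuclei_centroid_image(nuclei: NucleusMap3D) -> np.ndarray:
    """2D image marking each nucleus footprint centroid with its label."""
    footprint = nuclei.footprint_2d()
    out = np.zeros(footprint.shape, dtype=np.int32)
    for k in nuclei.label_ids:
        ys, xs = np.nonzero(footprint == int(k))
        if ys.size:
            out[int(round(ys.mean())), int(round(xs.mean()))] = int(k)
    return out


def _label_slices(labels: np.ndarray):
    """Yield (bounding-box slice, label id) for every positive label."""
    for k, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is not None:
            yield sl, k
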