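"""Whole-cell segmentation from the widefield (transmitted-light) channel.

The last few planes of the widefield stack are max-projected to get cell
outlines, a smoothed background image (disk mean filter) is subtracted to
enhance contrast, nucleus seeds are imposed as minima on the inverted
contrast image by morphological reconstruction, and a seeded watershed
assigns each catchment basin to its nucleus. Cells that are too small, too
large, or too close to the image border are removed, survivors renumbered
with their nuclei in lockstep, and measured (centroid, moment-ellipse axes,
area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, reconstruction
from skimage.segmentation import watershed

from .nuclei_seg import NucleusMap3D, max_project

__all__ = [
    "CellMap2D",
    "CellRecord",
    "widefield_projection",
    "subtract_background",
    "segment_cells",
    "filter_cells",
    "measure_cells",
]


@dataclass
class CellMap2D:
    """2D cell label image; label k is the cell around nucleus k."""

    labels: np.ndarray
    border_margin: int = 0
    area_bounds: tuple[int, int] | None = None

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.label_ids.size)


@dataclass
class CellRecord:
    """Per-cell morphology plus per-channel (nuclear, cytoplasmic, total) counts."""

    label: int
    centroid: tuple[float, float]  # (x, y), 0-based pixels
    major_axis: float
    minor_axis: float
    area: int
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def set_counts(self, channel: str, nuclear: int, cytoplasmic: int) -> None:
        self.counts[channel] = (int(nuclear), int(cytoplasmic), int(nuclear + cytoplasmic))


def widefield_projection(widefield_volume: np.ndarray, n_last: int = 5) -> np.ndarray:
    """Maximum projection over the final ``n_last`` z-planes of the widefield stack."""
    vol = np.asarray(widefield_volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    if not 1 <= n_last <= vol.shape[0]:
        raise ValueError(f"n_last={n_last} outside [1, {vol.shape[0]}]")
    return max_project(vol[-n_last:])


def subtract_background(image: np.ndarray, disk_radius: int = 15) -> np.ndarray:
    """Contrast enhancement: subtract a disk-mean-smoothed background, clip at 0."""
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    kernel = disk(disk_radius).astype(np.float64)
    # normalize by the in-bounds kernel mass so the local mean is unbiased
    # at the image borders (a constant image subtracts to exactly zero)
    num = fftconvolve(img, kernel, mode="same")
    den = fftconvolve(np.ones_like(img), kernel, mode="same")
    return np.clip(img - num / den, 0.0, None)


def segment_cells(
    contrast_image: np.ndarray,
    nuclei_2d: np.ndarray,
    foreground_quantile: float = 0.5,
) -> CellMap2D:
    """Watershed cells from a contrast image using nucleus labels as seeds.

    The inverted contrast image is the relief; nucleus seeds are imposed as
    its only regional minima via morphological reconstruction by erosion, and
    the watershed floods each basin from its seed. Pixels below the
    foreground cutoff (Otsu of the contrast image, falling back to the given
    quantile on degenerate histograms) and basins without a seed stay
    background. Nucleus pixels are always foreground.
    """
    contrast = np.asarray(contrast_image, dtype=np.float64)
    seeds = np.asarray(nuclei_2d)
    if contrast.shape != seeds.shape:
        raise ValueError("contrast image and nucleus labels must share a shape")
    if seeds.max() == 0:
        warnings.warn("no nucleus seeds; returning empty cell map")
        return CellMap2D(labels=np.zeros(contrast.shape, dtype=np.int32))
    if np.ptp(contrast) == 0:
        foreground = np.ones(contrast.shape, dtype=bool)
    else:
        try:
            cutoff = threshold_otsu(contrast)
        except ValueError:
            cutoff = float(np.quantile(contrast, foreground_quantile))
        foreground = contrast > cutoff
    foreground |= seeds > 0
    relief = _impose_minima(-contrast, seeds > 0)
    labels = watershed(relief, markers=seeds, mask=foreground)
    return CellMap2D(labels=labels.astype(np.int32))


def _impose_minima(relief: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Force the seed pixels to be the only regional minima of the relief."""
    span = float(np.ptp(relief)) or 1.0
    lo = float(relief.min()) - 2.0 * span
    hi = float(relief.max()) + 2.0 * span
    marker = np.where(seed_mask, lo, hi)
    mask = np.minimum(relief + 1e-9 * span, marker)
    return reconstruction(marker, mask, method="erosion")


def filter_cells(
    cells: CellMap2D,
    area_bounds: tuple[int, int] = (50, 5000),
    border_margin: int = 20,
    nuclei: NucleusMap3D | None = None,
) -> tuple[CellMap2D, NucleusMap3D | None]:
    """Remove badly segmented and border cells; renumber survivors.

    A cell is dropped when its area is outside ``area_bounds`` or any of its
    pixels lies within ``border_margin`` pixels of the image border.
    Survivors are renumbered 1..K consecutively; when a nucleus map is
    given its labels are remapped in lockstep so the cell/nucleus bijection
    is preserved. Filtering is idempotent.
    """
    labels = cells.labels
    if labels.max() == 0:
        return (
            CellMap2D(labels.copy(), border_margin=border_margin, area_bounds=area_bounds),
            nuclei,
        )
    areas = np.bincount(labels.ravel())
    h, w = labels.shape
    m = int(border_margin)
    border = np.zeros(labels.shape, dtype=bool)
    if m > 0:
        border[:m, :] = border[h - m :, :] = True
        border[:, :m] = border[:, w - m :] = True
    touching = np.unique(labels[border])
    lo, hi = area_bounds
    keep = []
    for k in range(1, labels.max() + 1):
        if k >= areas.size or areas[k] == 0:
            continue
        if areas[k] < lo or areas[k] > hi or k in touching:
            continue
        keep.append(k)
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    new_cells = CellMap2D(
        labels=remap[labels], border_margin=m, area_bounds=(lo, hi)
    )
    new_nuclei = nuclei
    if nuclei is not None:
        nuc_labels = nuclei.labels
        nuc_remap = np.zeros(max(nuc_labels.max(), labels.max()) + 1, dtype=np.int32)
        nuc_remap[: remap.size] = remap
        new_nuclei = NucleusMap3D(
            labels=nuc_remap[nuc_labels],
            per_label_threshold={
                int(remap[k]): v
                for k, v in nuclei.per_label_threshold.items()
                if k < remap.size and remap[k] > 0
            },
            background_level=nuclei.background_level,
        )
    return new_cells, new_nuclei


def measure_cells(cells: CellMap2D) -> list[CellRecord]:
    """Measure every labelled cell: area, centroid and moment-ellipse axes.

    The major/minor axes are those of the ellipse with the same normalized
    second central moments as the region. Centroids are (x, y) with x the
    column index.
    """
    records = []
    for props in regionprops(cells.labels):
        cy, cx = props.centroid
        records.append(
            CellRecord(
                label=int(props.label),
                centroid=(float(cx), float(cy)),
                major_axis=float(props.axis_major_length),
                minor_axis=float(props.axis_minor_length),
                area=int(props.area),
            )
        )
    records.sort(key=lambda r: r.label)
    return records
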