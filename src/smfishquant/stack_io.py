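"""Reading and writing interleaved multi-channel FISH z-stacks and tabular exports.

A field of view is stored on disk as a single multi-page TIFF in which the
four channels of each z-position are interleaved: page ``i`` belongs to
channel ``channel_order[i % n_channels]`` at z-index ``i // n_channels``.
The default acquisition order is TMR, CY5, DAPI, widefield, one set per
focal plane, so a 25-z stack has 100 pages and a 26-z stack has 104.

Tabular exports use the deposited-file schemas: a five-column cell-morphology
table (centroid x, centroid y, major axis, minor axis, area) and a
three-column per-cell count table (total, cytoplasmic, nuclear) per dye.
All pixel coordinates are 0-based with x = column, y = row, z = plane index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DEFAULT_CHANNEL_ORDER",
    "DYE_CHANNELS",
    "ImageStack",
    "ProbeSet",
    "ExperimentManifest",
    "StackLayoutError",
    "StackFormatError",
    "read_stack",
    "write_stack",
    "read_probe_table",
    "packaged_probe_table",
    "read_manifest",
    "packaged_manifest",
    "write_cell_info",
    "read_cell_info",
    "write_counts",
    "read_counts",
]

#: Acquisition order at each z-position: image 1 = TMR, 2 = CY5, 3 = DAPI,
#: 4 = widefield (transmitted light).
DEFAULT_CHANNEL_ORDER: tuple[str, ...] = ("TMR", "CY5", "DAPI", "WIDEFIELD")

#: The two single-molecule dye channels (STL1 is TMR-labelled, CTT1 Cy5-labelled).
DYE_CHANNELS: tuple[str, ...] = ("TMR", "CY5")

#: Default gene -> dye assignment used when parsing probe tables.
DEFAULT_GENE_DYES: dict[str, str] = {"STL1": "TMR", "CTT1": "CY5"}

CELL_INFO_COLUMNS = ["centroid_x", "centroid_y", "major_axis", "minor_axis", "area"]
COUNT_COLUMNS = ["total", "cytoplasmic", "nuclear"]


class StackLayoutError(ValueError):
    """Page count incompatible with the declared channel interleaving."""


class StackFormatError(ValueError):
    """Pages of a stack do not share a single pixel shape."""


@dataclass
class ImageStack:
    """One field of view: per-channel 3D voxel arrays plus acquisition metadata.

    Parameters
    ----------
    channels
        Map from channel role (e.g. ``"TMR"``) to a ``(n_z, height, width)``
        intensity array. All channels must share one shape.
    z_step_nm
        Spacing between consecutive focal planes in nanometres.
    channel_order
        On-disk interleaving order; defaults to the acquisition order.
    source_id
        Free-form experiment/replicate/timepoint/field identifier.
    """

    channels: dict[str, np.ndarray]
    z_step_nm: float = 200.0
    channel_order: tuple[str, ...] = DEFAULT_CHANNEL_ORDER
    source_id: str = ""

    def __post_init__(self) -> None:
        self.channel_order = tuple(self.channel_order)
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        ref = next(iter(shapes.values()))
        if len(ref) != 3:
            raise ValueError(f"channel arrays must be 3D (z, y, x), got {ref}")
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.z_step_nm <= 0:
            raise ValueError("z_step_nm must be positive")
        for ch, arr in self.channels.items():
            if np.min(arr) < 0:
                raise ValueError(f"negative intensities in channel {ch}")
        missing = set(self.channels) - set(self.channel_order)
        if missing:
            raise ValueError(f"channels {missing} absent from channel_order")

    @property
    def n_z(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def pixel_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class ProbeSet:
    """A tiling set of short DNA oligos against one transcript."""

    gene: str
    probes: list[str]
    dye: str = ""

    def __post_init__(self) -> None:
        lengths = {len(p) for p in self.probes}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: ragged probe lengths {sorted(lengths)}")
        bad = [p for p in self.probes if set(p) - set("ACGT")]
        if bad:
            raise ValueError(f"{self.gene}: non-ACGT characters in {bad[:3]}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_length(self) -> int:
        return len(self.probes[0]) if self.probes else 0


@dataclass
class ExperimentManifest:
    """One experimental design row: condition, replicate and imaging schedule."""

    experiment: str
    condition: str
    replicate: int
    timepoints_min: list[float]
    fields_per_timepoint: int = 4
    n_stacks: int | None = None

    def __post_init__(self) -> None:
        tp = list(self.timepoints_min)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.fields_per_timepoint < 1:
            raise ValueError("fields_per_timepoint must be positive")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_min)


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(
    path: str | Path,
    n_channels: int = 4,
    channel_order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
    source_id: str | None = None,
) -> ImageStack:
    """Read an interleaved multi-page TIFF into per-channel volumes.

    Page ``i`` on disk maps to channel ``channel_order[i % n_channels]`` at
    z-index ``i // n_channels``.

    Raises
    ------
    StackLayoutError
        If the page count is not divisible by ``n_channels``.
    StackFormatError
        If pages do not share one pixel shape.
    """
    channel_order = tuple(channel_order)
    if len(channel_order) != n_channels:
        raise ValueError("channel_order length must equal n_channels")
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise StackFormatError(f"{path.name}: inconsistent page shapes {shapes}")
        n_pages = len(tif.pages)
        if n_pages == 0 or n_pages % n_channels:
            raise StackLayoutError(
                f"{path.name}: {n_pages} pages not divisible by {n_channels} channels"
            )
        pages = tif.asarray()
        meta = _parse_description(tif.pages[0].description)
    pages = pages.reshape(n_pages, *pages.shape[-2:])
    n_z = n_pages // n_channels
    channels = {
        role: pages[c::n_channels].copy() for c, role in enumerate(channel_order)
    }
    return ImageStack(
        channels=channels,
        z_step_nm=float(meta.get("z_step_nm", 200.0)),
        channel_order=channel_order,
        source_id=source_id if source_id is not None else meta.get("source_id", path.stem),
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as an interleaved multi-page TIFF.

    The metadata (z-step, channel order, source id) is stored in the TIFF
    image description as JSON so ``read_stack(write_stack(s))`` reproduces
    the stack voxel-for-voxel with its metadata.
    """
    stack.validate()
    path = Path(path)
    order = [ch for ch in stack.channel_order if ch in stack.channels]
    if set(order) != set(stack.channels):
        raise ValueError("channel_order does not cover all channels")
    planes = np.stack([stack.channels[ch] for ch in order], axis=1)
    n_z, n_c, h, w = planes.shape
    desc = json.dumps(
        {
            "z_step_nm": stack.z_step_nm,
            "channel_order": list(order),
            "source_id": stack.source_id,
        }
    )
    tifffile.imwrite(path, planes.reshape(n_z * n_c, h, w), description=desc)
    return path


def _parse_description(description: str) -> dict:
    if not description:
        return {}
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, TypeError):
        return {}
    return meta if isinstance(meta, dict) else {}


# ---------------------------------------------------------------------------
# Probe tables and experiment manifests


def read_probe_table(
    path: str | Path,
    gene_dyes: Mapping[str, str] | None = None,
) -> list[ProbeSet]:
    """Parse a delimited probe table with one column of sequences per gene.

    Each column header is a gene name; each cell a DNA sequence over ACGT.
    All sequences within a gene must share one length.
    """
    gene_dyes = dict(DEFAULT_GENE_DYES if gene_dyes is None else gene_dyes)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty probe table")
    out = []
    for gene in df.columns:
        probes = [str(s).strip().upper() for s in df[gene].dropna()]
        out.append(ProbeSet(gene=gene, probes=probes, dye=gene_dyes.get(gene, "")))
    return out


def packaged_probe_table() -> list[ProbeSet]:
    """The STL1/CTT1 probe sets shipped with the package (48 oligos of 20 nt each)."""
    with resources.as_file(
        resources.files("smfishquant.data") / "probes_stl1_ctt1.csv"
    ) as p:
        return read_probe_table(p)


def read_manifest(path: str | Path) -> list[ExperimentManifest]:
    """Parse an experiment manifest CSV (one row per condition x replicate).

    The ``timepoints_min`` column holds space-separated minutes. The declared
    ``n_stacks`` per experiment is recorded as-is and not reconciled with
    ``fields_per_timepoint x n_timepoints``.
    """
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExperimentManifest(
                experiment=str(row.experiment),
                condition=str(row.condition),
                replicate=int(row.replicate),
                timepoints_min=[float(t) for t in str(row.timepoints_min).split()],
                fields_per_timepoint=int(getattr(row, "fields_per_timepoint", 4)),
                n_stacks=int(row.n_stacks) if hasattr(row, "n_stacks") else None,
            )
        )
    return out


def packaged_manifest() -> list[ExperimentManifest]:
    """The NaCl-step experiment designs shipped with the package."""
    with resources.as_file(
        resources.files("smfishquant.data") / "experiments_nacl_step.csv"
    ) as p:
        return read_manifest(p)


# ---------------------------------------------------------------------------
# Tabular exports


def write_cell_info(records: Sequence, path: str | Path) -> Path:
    """Write the five-column per-cell morphology table.

    Columns: centroid x, centroid y, major axis, minor axis, area — one row
    per cell, ordered by cell label. Coordinates are 0-based pixels.
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.label):
        for attr in ("centroid", "major_axis", "minor_axis", "area"):
            if getattr(rec, attr, None) is None:
                raise ValueError(f"cell {rec.label}: missing morphology field {attr}")
        rows.append(
            [rec.centroid[0], rec.centroid[1], rec.major_axis, rec.minor_axis, rec.area]
        )
    df = pd.DataFrame(rows, columns=CELL_INFO_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f")
    return Path(path)


def read_cell_info(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != CELL_INFO_COLUMNS:
        raise ValueError(f"{path}: unexpected cell-info columns {list(df.columns)}")
    return df


def write_counts(records: Sequence, channel: str, path: str | Path) -> Path:
    """Write the three-column per-cell count table for one dye channel.

    Columns: total, cytoplasmic, nuclear. Every row satisfies
    ``total == cytoplasmic + nuclear``; a violation aborts the export.
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.label):
        try:
            nuclear, cytoplasmic, total = rec.counts[channel]
        except KeyError as exc:
            raise ValueError(f"cell {rec.label}: no counts for channel {channel}") from exc
        if total != nuclear + cytoplasmic:
            raise ValueError(
                f"cell {rec.label}: total {total} != nuclear {nuclear} + "
                f"cytoplasmic {cytoplasmic}"
            )
        rows.append([total, cytoplasmic, nuclear])
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS, dtype=int)
    df.to_csv(path, index=False)
    return Path(path)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != COUNT_COLUMNS:
        raise ValueError(f"{path}: unexpected count columns {list(df.columns)}")
    return df
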