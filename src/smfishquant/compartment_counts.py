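"""Assignment of detected spots to cells and compartments.

A spot is nuclear when its voxel lies inside a 3D nucleus label, otherwise
cytoplasmic when its (y, x) position lies inside a cell footprint, otherwise
unassigned (background) and excluded from all counts. Nuclear membership is
evaluated in 3D, cytoplasmic membership on the 2D cell map, mirroring the
dimensionality of the segmentation products. Nuclear assignment takes
precedence, so no spot is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .cell_seg import CellMap2D
from .nuclei_seg import NucleusMap3D
from .spot_detect import Spot

__all__ = ["NUCLEAR", "CYTOPLASMIC", "CountTable", "assign_spot", "count_cells"]

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"


@dataclass
class CountTable:
    """Per-cell, per-channel nuclear/cytoplasmic/total spot counts for one stack."""

    rows: pd.DataFrame  # columns: cell, channel, nuclear, cytoplasmic, total
    unassigned: dict[str, int] = field(default_factory=dict)
    provenance: str = ""

    COLUMNS = ["cell", "channel", "nuclear", "cytoplasmic", "total"]

    def __post_init__(self) -> None:
        df = self.rows
        if list(df.columns) != self.COLUMNS:
            raise ValueError(f"count table needs columns {self.COLUMNS}")
        if ((df["nuclear"] + df["cytoplasmic"]) != df["total"]).any():
            raise ValueError("total != nuclear + cytoplasmic in count table")
        if (df[["nuclear", "cytoplasmic", "total"]] < 0).any().any():
            raise ValueError("negative counts")

    def channel_counts(self, channel: str) -> pd.DataFrame:
        sub = self.rows[self.rows["channel"] == channel]
        return sub.set_index("cell")[["nuclear", "cytoplasmic", "total"]]

    @classmethod
    def concat(cls, tables: Sequence["CountTable"]) -> "CountTable":
        """Merge tables from disjoint fields by concatenation."""
        rows = pd.concat([t.rows for t in tables], ignore_index=True)
        unassigned: dict[str, int] = {}
        for t in tables:
            for ch, n in t.unassigned.items():
                unassigned[ch] = unassigned.get(ch, 0) + n
        return cls(
            rows=rows,
            unassigned=unassigned,
            provenance=";".join(t.provenance for t in tables if t.provenance),
        )


def assign_spot(
    spot: Spot, cells: CellMap2D, nuclei: NucleusMap3D
) -> tuple[int | None, str | None]:
    """Assign one spot to (cell label, compartment), or (None, None) if background."""
    nz, ny, nx = nuclei.labels.shape
    if not (0 <= spot.z < nz and 0 <= spot.y < ny and 0 <= spot.x < nx):
        raise ValueError(f"spot {spot} outside volume bounds {(nz, ny, nx)}")
    k = int(nuclei.labels[spot.z, spot.y, spot.x])
    if k > 0:
        return k, NUCLEAR
    k = int(cells.labels[spot.y, spot.x])
    if k > 0:
        return k, CYTOPLASMIC
    return None, None


def count_cells(
    spots: Iterable[Spot],
    cells: CellMap2D,
    nuclei: NucleusMap3D,
    channels: Sequence[str] = ("TMR", "CY5"),
    provenance: str = "",
) -> CountTable:
    """Aggregate spot assignments into a per-cell count table.

    Every surviving cell gets an explicit row per channel, including zero
    rows, so the table row count is ``n_cells x n_channels``. Spots outside
    all cell footprints are tallied per channel in ``unassigned``.
    """
    labels = [int(k) for k in cells.label_ids]
    counts = {
        (k, ch): [0, 0] for k in labels for ch in channels
    }  # [nuclear, cytoplasmic]
    unassigned = {ch: 0 for ch in channels}
    for spot in spots:
        if spot.channel not in unassigned:
            unassigned[spot.channel] = 0
        cell, compartment = assign_spot(spot, cells, nuclei)
        if cell is None:
            unassigned[spot.channel] += 1
            continue
        key = (cell, spot.channel)
        if key not in counts:
            # spot inside a nucleus whose cell was filtered out: discard
            unassigned[spot.channel] += 1
            continue
        counts[key][0 if compartment == NUCLEAR else 1] += 1
    rows = [
        {
            "cell": k,
            "channel": ch,
            "nuclear": nuc,
            "cytoplasmic": cyt,
            "total": nuc + cyt,
        }
        for (k, ch), (nuc, cyt) in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=CountTable.COLUMNS)
    return CountTable(rows=df, unassigned=unassigned, provenance=provenance)
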