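"""Run configuration: every threshold and filter parameter, serializable to YAML.

A run's effective configuration is written next to its outputs so any run
can be reproduced byte-identically from the snapshot.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # acquisition layout
    channel_order: tuple[str, ...] = ("TMR", "CY5", "DAPI", "WIDEFIELD")
    z_step_nm: float = 200.0

    # nuclear segmentation
    dapi_threshold: float | str = "auto"  # "auto" = Otsu on the projection
    nucleus_min_area: int = 20
    nucleus_max_area: int = 2000

    # cell segmentation
    widefield_n_last: int = 5
    disk_radius: int = 15
    cell_min_area: int = 50
    cell_max_area: int = 5000
    border_margin: int = 20

    # spot detection (sigmas are (lateral, axial) voxels)
    sigma_smooth: float = 1.0
    sigma_log: tuple[float, float] = (1.4, 1.2)
    spot_threshold: dict = field(
        default_factory=lambda: {"TMR": "auto", "CY5": "auto"}
    )
    threshold_plane: str = "max_projection"  # representative image for auto thresholds

    # statistics
    on_coverage: float = 0.95
    fano_ddof: int = 0
    replicate_sd_ddof: int = 1

    # export naming (``{exp}`` = experiment_replicate, ``{stem}`` = stack stem)
    cell_info_template: str = "M_Lab_{stem}_CellInfo.csv"
    counts_template: str = "SD_mRNA_{stem}_CELLmaxRNA{dye}_mid.csv"
    combined_template: str = "Results_{exp}_RNA_{dye}_{kind}.csv"

    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.channel_order = tuple(cfg.channel_order)
        if not isinstance(cfg.sigma_log, (int, float)):
            cfg.sigma_log = tuple(cfg.sigma_log)
        return cfg

    def dye_channels(self) -> list[str]:
        return [ch for ch in self.channel_order if ch in self.spot_threshold]
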