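"""End-to-end orchestration: segmentation -> spot detection -> counts -> stats.

The unit of work is one :class:`~smfishquant.stack_io.ImageStack` (a field
of view). Batch helpers run directories of stacks with one configuration,
write the deposited-layout exports, and snapshot the effective config next
to the outputs so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell_seg, compartment_counts, nuclei_seg, spot_detect, stack_io
from .config import RunConfig

logger = logging.getLogger("smfishquant")

__all__ = [
    "StackResult",
    "segment_stack",
    "filtered_dye_volume",
    "stack_threshold",
    "sample_thresholds",
    "count_stack",
    "process_stacks",
    "combine_counts",
    "write_combined_counts",
]


@dataclass
class StackResult:
    """Everything derived from one field of view."""

    source_id: str
    cells: cell_seg.CellMap2D
    nuclei: nuclei_seg.NucleusMap3D
    records: list[cell_seg.CellRecord]
    spots: dict[str, list[spot_detect.Spot]] = field(default_factory=dict)
    counts: compartment_counts.CountTable | None = None
    thresholds: dict[str, float] = field(default_factory=dict)


def segment_stack(stack: stack_io.ImageStack, config: RunConfig) -> StackResult:
    """Segment nuclei (DAPI, 3D) and cells (widefield, watershed) for one stack."""
    dapi = stack["DAPI"]
    projection = nuclei_seg.max_project(dapi)
    thr = None if config.dapi_threshold == "auto" else float(config.dapi_threshold)
    nuclei_2d = nuclei_seg.detect_nuclei(
        projection,
        global_threshold=thr,
        min_area=config.nucleus_min_area,
        max_area=config.nucleus_max_area,
    )
    n_detected = int(nuclei_2d.max())
    background = nuclei_seg.estimate_background(projection, nuclei_2d)
    nuclei = nuclei_seg.segment_nuclei_3d(dapi, nuclei_2d, background)

    contrast = cell_seg.subtract_background(
        cell_seg.widefield_projection(stack["WIDEFIELD"], config.widefield_n_last),
        config.disk_radius,
    )
    cells = cell_seg.segment_cells(contrast, nuclei_2d)
    cells, nuclei = cell_seg.filter_cells(
        cells,
        area_bounds=(config.cell_min_area, config.cell_max_area),
        border_margin=config.border_margin,
        nuclei=nuclei,
    )
    records = cell_seg.measure_cells(cells)
    logger.info(
        "%s: %d nuclei detected, %d cells kept after filtering",
        stack.source_id,
        n_detected,
        cells.n_cells,
    )
    return StackResult(
        source_id=stack.source_id, cells=cells, nuclei=nuclei, records=records
    )


def filtered_dye_volume(
    stack: stack_io.ImageStack, channel: str, config: RunConfig
) -> np.ndarray:
    return spot_detect.log_filter(
        stack[channel], sigma_smooth=config.sigma_smooth, sigma_log=config.sigma_log
    )


def _representative_plane(filtered: np.ndarray, which: str) -> np.ndarray:
    if which == "max_projection":
        # every spot is visible and the noise ceiling matches the 3D volume's
        return filtered.max(axis=0)
    if which == "middle":
        return filtered[filtered.shape[0] // 2]
    if which == "brightest":
        return filtered[int(np.argmax(filtered.max(axis=(1, 2))))]
    return filtered[int(which)]


def stack_threshold(
    stack: stack_io.ImageStack, channel: str, config: RunConfig
) -> float:
    """Per-image detection threshold for one dye, from one representative plane."""
    filtered = filtered_dye_volume(stack, channel, config)
    return spot_detect.auto_threshold(
        _representative_plane(filtered, config.threshold_plane), require_spots=True
    )


def sample_thresholds(
    stacks: list[stack_io.ImageStack], config: RunConfig
) -> dict[str, spot_detect.DetectionThreshold]:
    """One mean threshold per dye across all stacks of a sample.

    Manual thresholds in the config win outright; automatic thresholds are
    determined per image and averaged. Images where no spot population is
    separable contribute nothing to the mean.
    """
    out: dict[str, spot_detect.DetectionThreshold] = {}
    for channel, setting in config.spot_threshold.items():
        if setting != "auto":
            value = float(setting)
            out[channel] = spot_detect.DetectionThreshold(
                channel=channel, per_image_values=[value], mean_value=value
            )
            logger.info("%s: manual threshold %.4g", channel, value)
            continue
        values = []
        for stack in stacks:
            try:
                values.append(stack_threshold(stack, channel, config))
            except ValueError as exc:
                logger.warning("%s/%s: auto-threshold failed (%s)", stack.source_id, channel, exc)
        out[channel] = spot_detect.aggregate_threshold(values, channel=channel)
        logger.info(
            "%s: mean auto threshold %.4g over %d images",
            channel,
            out[channel].mean_value,
            len(values),
        )
    return out


def count_stack(
    stack: stack_io.ImageStack,
    result: StackResult,
    thresholds: dict[str, spot_detect.DetectionThreshold],
    config: RunConfig,
    filtered_volumes: dict[str, np.ndarray] | None = None,
) -> StackResult:
    """Detect spots per dye with the sample thresholds and count per cell."""
    all_spots: list[spot_detect.Spot] = []
    for channel, threshold in thresholds.items():
        if filtered_volumes is not None and channel in filtered_volumes:
            filtered = filtered_volumes[channel]
        else:
            filtered = filtered_dye_volume(stack, channel, config)
        spots = spot_detect.detect_spots(filtered, threshold.mean_value, channel=channel)
        result.spots[channel] = spots
        result.thresholds[channel] = threshold.mean_value
        all_spots.extend(spots)
    result.counts = compartment_counts.count_cells(
        all_spots,
        result.cells,
        result.nuclei,
        channels=tuple(thresholds),
        provenance=result.source_id,
    )
    for rec in result.records:
        per_cell = result.counts.rows[result.counts.rows["cell"] == rec.label]
        for row in per_cell.itertuples(index=False):
            rec.set_counts(row.channel, row.nuclear, row.cytoplasmic)
    return result


def process_stacks(
    stacks: list[stack_io.ImageStack], config: RunConfig
) -> list[StackResult]:
    """Segment, auto-threshold and count a whole sample of stacks.

    The LoG-filtered volume of each stack and dye is computed once and
    shared between threshold determination and spot detection.
    """
    results = [segment_stack(s, config) for s in stacks]
    dyes = list(config.spot_threshold)
    filtered_all = [
        {ch: filtered_dye_volume(s, ch, config) for ch in dyes} for s in stacks
    ]
    thresholds: dict[str, spot_detect.DetectionThreshold] = {}
    for channel in dyes:
        setting = config.spot_threshold[channel]
        if setting != "auto":
            value = float(setting)
            thresholds[channel] = spot_detect.DetectionThreshold(
                channel=channel, per_image_values=[value], mean_value=value
            )
            continue
        values = []
        for stack, filtered in zip(stacks, filtered_all):
            try:
                values.append(
                    spot_detect.auto_threshold(
                        _representative_plane(
                            filtered[channel], config.threshold_plane
                        ),
                        require_spots=True,
                    )
                )
            except ValueError as exc:
                logger.warning(
                    "%s/%s: auto-threshold failed (%s)", stack.source_id, channel, exc
                )
        thresholds[channel] = spot_detect.aggregate_threshold(values, channel=channel)
    for stack, result, filtered in zip(stacks, results, filtered_all):
        count_stack(stack, result, thresholds, config, filtered_volumes=filtered)
    return results


def quantify_synthetic_experiment(
    spec_per_timepoint: dict,
    n_fields: int,
    config: RunConfig,
    base_seed: int = 0,
    replicate: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and fully quantify one synthetic replicate experiment.

    For each timepoint, ``n_fields`` fields are generated with seeds derived
    from ``(base_seed, replicate, timepoint index, field index)``. All images
    of the replicate form one sample per dye: per-image auto thresholds are
    collected across every timepoint and averaged into one mean detection
    threshold per dye, which applies to every stack.

    Each field is processed once. Because the regional maxima of a filtered
    volume do not depend on the threshold (raising it only removes whole
    maxima), candidate spots are detected above a conservative per-image
    noise floor, assigned to their cell and compartment immediately, and
    the sample-wide mean threshold is applied at the end as an intensity
    cut — exactly equivalent to re-detecting at the final threshold, without
    holding or regenerating any volume. Segmented cells are matched back to
    planted cells by centroid.

    Returns ``(detected, truth)`` tidy frames: ``detected`` has one row per
    surviving segmented cell and channel with its counts and, where matched,
    the planted cell's true counts; ``truth`` has one row per planted valid
    cell and channel.
    """
    from dataclasses import replace

    from . import synthetic
    from .compartment_counts import NUCLEAR, assign_spot

    dyes = list(config.spot_threshold)
    timepoints = sorted(spec_per_timepoint.items())

    fields = []  # (tp, fi, labels, mapping, truth, candidates per dye)
    per_image: dict[str, list[float]] = {ch: [] for ch in dyes}
    for ti, (tp, spec) in enumerate(timepoints):
        for fi in range(n_fields):
            seed = int(
                np.random.SeedSequence([base_seed, replicate, ti, fi]).generate_state(1)[0]
                % (2**31 - 1)
            )
            stack, truth = synthetic.generate_field(
                replace(spec, seed=seed),
                source_id=f"rep{replicate}_{tp:g}min_im{fi}",
            )
            result = segment_stack(stack, config)
            candidates: dict[str, list] = {}
            for ch in dyes:
                filtered = filtered_dye_volume(stack, ch, config)
                plane = _representative_plane(filtered, config.threshold_plane)
                if config.spot_threshold[ch] == "auto":
                    try:
                        per_image[ch].append(
                            spot_detect.auto_threshold(plane, require_spots=True)
                        )
                    except ValueError:
                        pass
                # conservative floor: 3x the regional-maxima noise spread,
                # safely below any auto threshold of this sample (those sit
                # at >= 5x the same spread; all images share one noise model)
                from skimage.morphology import local_maxima

                peaks = plane[local_maxima(plane, connectivity=2)]
                med = float(np.median(peaks))
                floor = med + 3.0 * max(float(np.quantile(peaks, 0.9)) - med, 1e-12)
                rows = []
                for s in spot_detect.detect_spots(filtered, floor, channel=ch):
                    cell, comp = assign_spot(s, result.cells, result.nuclei)
                    rows.append((cell, comp == NUCLEAR, s.intensity))
                candidates[ch] = rows
            fields.append(
                (
                    tp,
                    fi,
                    [int(k) for k in result.cells.label_ids],
                    synthetic.match_cells(truth, result.records),
                    truth,
                    candidates,
                )
            )

    thresholds = {}
    for ch in dyes:
        setting = config.spot_threshold[ch]
        if setting != "auto":
            thresholds[ch] = float(setting)
        else:
            thresholds[ch] = spot_detect.aggregate_threshold(
                per_image[ch], channel=ch
            ).mean_value

    det_rows = []
    truth_rows = []
    for tp, fi, labels, mapping, truth, candidates in fields:
        truth_counts = truth.counts.set_index(["cell", "channel"])
        for ch in dyes:
            counts = {k: [0, 0] for k in labels}  # [nuclear, cytoplasmic]
            for cell, nuclear, intensity in candidates[ch]:
                if intensity < thresholds[ch] or cell not in counts:
                    continue
                counts[cell][0 if nuclear else 1] += 1
            for cell, (nuc, cyt) in sorted(counts.items()):
                true_cell = mapping.get(cell)
                base = dict(
                    replicate=replicate,
                    timepoint=tp,
                    field=fi,
                    channel=ch,
                    det_label=cell,
                    truth_cell=true_cell,
                    det_total=nuc + cyt,
                    det_nuclear=nuc,
                    det_cytoplasmic=cyt,
                )
                if true_cell is not None:
                    t = truth_counts.loc[(true_cell, ch)]
                    base.update(
                        truth_total=int(t.total),
                        truth_nuclear=int(t.nuclear),
                        truth_cytoplasmic=int(t.cytoplasmic),
                    )
                det_rows.append(base)
        valid = set(truth.cells.loc[truth.cells["valid"], "cell"])
        for row in truth.counts.itertuples(index=False):
            if row.cell in valid:
                truth_rows.append(
                    dict(
                        replicate=replicate,
                        timepoint=tp,
                        field=fi,
                        channel=row.channel,
                        cell=row.cell,
                        total=row.total,
                        nuclear=row.nuclear,
                        cytoplasmic=row.cytoplasmic,
                    )
                )
    return pd.DataFrame(det_rows), pd.DataFrame(truth_rows)


def combine_counts(results: list[StackResult]) -> compartment_counts.CountTable:
    """Concatenate the per-stack count tables of one experiment."""
    tables = [r.counts for r in results if r.counts is not None]
    if not tables:
        raise ValueError("no counted stacks to combine")
    return compartment_counts.CountTable.concat(tables)


def write_combined_counts(
    combined: compartment_counts.CountTable,
    out_dir: str | Path,
    experiment: str,
    config: RunConfig,
) -> list[Path]:
    """Write the per-experiment combined count files (dye x total/nuclear/cytoplasm)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for dye in combined.rows["channel"].unique():
        sub = combined.rows[combined.rows["channel"] == dye]
        for kind in ("total", "nuclear", "cytoplasm"):
            col = "cytoplasmic" if kind == "cytoplasm" else kind
            path = out_dir / config.combined_template.format(
                exp=experiment, dye=dye, kind=kind
            )
            pd.DataFrame({kind: sub[col].to_numpy()}).to_csv(path, index=False)
            paths.append(path)
    return paths
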