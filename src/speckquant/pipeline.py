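"""End-to-end orchestration: segment -> tessellate -> detect -> summarize.

`process_field` runs the full measurement chain on one stack and returns all
intermediate products; `run_pipeline` maps it over fields, attaches group
labels and writes byte-stable CSV tables plus 16-bit label TIFFs. All
coordinates are 0-based (z, y, x).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import nuclei as nuc_mod
from . import speckles as spk_mod
from . import stats as stats_mod
from . import territories as terr_mod
from .nuclei import NucleusRecord, SegmentationParams
from .simulate import FieldParams, generate_field
from .speckles import SpeckleRecord
from .stack import ImageStack, read_stack

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Speckle-detection knobs (shared across FISH channels)."""

    tophat_radius_px: int = 8
    min_voxels: int = 3
    per_slice_threshold: bool = False


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, YAML round-trippable."""

    inputs: list[str] = field(default_factory=list)
    channel_map: dict[str, int] | None = None
    dapi_channel: str = "dapi"
    fish_channels: list[str] | None = None  # default: every non-DAPI channel
    voxel_size: tuple[float, float, float] | None = None
    projection_method: str = "max"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    max_reach_um: float | None = None
    output_dir: str = "speckquant_out"
    seed: int = 0  # simulation only
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        det = DetectionParams(**raw.pop("detection", {}))
        if raw.get("voxel_size") is not None:
            raw["voxel_size"] = tuple(raw["voxel_size"])
        return cls(segmentation=seg, detection=det, **raw)


@dataclass
class FieldResult:
    """All products of one field's analysis."""

    stack: ImageStack
    projection: np.ndarray
    nucleus_labels: np.ndarray
    nucleus_records: list[NucleusRecord]
    micronuclei_table: pd.DataFrame
    cell_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    speckle_records: list[SpeckleRecord]
    cell_summary: pd.DataFrame
    excluded_cells: frozenset[int]


def process_field(stack: ImageStack, config: PipelineConfig | None = None) -> FieldResult:
    """Run the full measurement chain on one multi-channel stack.

    Degenerate fields (no nuclei, constant channels) produce empty tables,
    not exceptions.
    """
    config = config or PipelineConfig()
    projection = nuc_mod.project_dapi(
        stack, method=config.projection_method, channel=config.dapi_channel
    )
    labels, records = nuc_mod.segment_nuclei(projection, config.segmentation)
    records = nuc_mod.classify_phase(records, config.segmentation)
    records, micro_table = nuc_mod.detect_micronuclei(labels, records, config.segmentation)

    excluded = frozenset(
        r.nucleus_id
        for r in records
        if not r.is_candidate and r.touches_border and config.segmentation.exclude_border
    )
    log.info(
        "field: %d nuclei (%d border-excluded), %d micronuclei",
        sum(1 for r in records if not r.is_candidate),
        len(excluded),
        sum(1 for r in records if r.is_micronucleus),
    )

    if labels.max() > 0:
        reach_px = None
        if config.max_reach_um is not None:
            reach_px = config.max_reach_um / stack.voxel_size[1]
        cells = terr_mod.tessellate_cells(labels, max_reach_px=reach_px)
        cytoplasm = terr_mod.derive_cytoplasm(cells, labels)
    else:
        cells = np.zeros_like(labels)
        cytoplasm = np.zeros_like(labels)

    fish = config.fish_channels or [c for c in stack.channel_names if c != config.dapi_channel]
    all_speckles: list[SpeckleRecord] = []
    for ch in fish:
        recs = spk_mod.detect_speckles(
            stack.require(ch),
            channel=ch,
            tophat_radius_px=config.detection.tophat_radius_px,
            min_voxels=config.detection.min_voxels,
            per_slice_threshold=config.detection.per_slice_threshold,
        )
        recs = spk_mod.assign_compartments(recs, cells, cytoplasm, labels, excluded)
        log.info("field[%s]: %d speckles detected", ch, len(recs))
        all_speckles.extend(recs)

    summary = stats_mod.summarize_cells(all_speckles, records, micro_table)
    return FieldResult(
        stack=stack,
        projection=projection,
        nucleus_labels=labels,
        nucleus_records=records,
        micronuclei_table=micro_table,
        cell_labels=cells,
        cytoplasm_labels=cytoplasm,
        speckle_records=all_speckles,
        cell_summary=summary,
        excluded_cells=excluded,
    )


def _write_field_outputs(result: FieldResult, out: Path, tag: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{tag}_nucleus_labels.tif", result.nucleus_labels.astype(np.uint16))
    tifffile.imwrite(out / f"{tag}_cell_labels.tif", result.cell_labels.astype(np.uint16))
    tifffile.imwrite(
        out / f"{tag}_cytoplasm_labels.tif", result.cytoplasm_labels.astype(np.uint16)
    )
    nuc_mod.records_to_frame(result.nucleus_records).to_csv(
        out / f"{tag}_nuclei.csv", index=False
    )
    spk_frame = spk_mod.speckles_to_frame(result.speckle_records, result.stack.voxel_size)
    spk_frame.sort_values(["cell_id", "channel", "speckle_id"]).to_csv(
        out / f"{tag}_speckles.csv", index=False
    )
    result.cell_summary.sort_values(["cell_id", "channel"]).to_csv(
        out / f"{tag}_cells.csv", index=False
    )


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Analyze every input stack in the config; write tables and labels.

    Returns the concatenated per-cell summary across fields, sorted by
    (field, cell_id, channel) for byte-stable output.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    summaries = []
    if not config.inputs:
        raise ValueError("config.inputs is empty; nothing to analyze")
    for i, path in enumerate(config.inputs):
        stack = read_stack(path, channel_map=None if config.channel_map is None else config.channel_map,
                           voxel_size=config.voxel_size)
        if config.dapi_channel not in stack.channels:
            raise ValueError(
                f"{path}: configured DAPI channel {config.dapi_channel!r} absent; "
                f"available: {stack.channel_names}"
            )
        result = process_field(stack, config)
        tag = f"field{i:03d}"
        _write_field_outputs(result, out, tag)
        s = result.cell_summary.copy()
        s.insert(0, "field", tag)
        summaries.append(s)
    combined = pd.concat(summaries, ignore_index=True).sort_values(
        ["field", "cell_id", "channel"], ignore_index=True
    )
    out.mkdir(parents=True, exist_ok=True)
    combined.to_csv(out / "cells_all.csv", index=False)
    return combined


def simulate_and_process(
    params: FieldParams, seed: int, config: PipelineConfig | None = None
) -> tuple[FieldResult, "object"]:
    """Convenience: generate one synthetic field and analyze it."""
    stack, truth = generate_field(params, seed)
    return process_field(stack, config), truth
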