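"""End-to-end orchestration: image -> per-cell and per-FA tables -> stats.

The stage order is fixed: read -> pillar-background subtraction -> median
denoise -> three-class classification of vinculin -> cell segmentation from
actin -> cell morphometrics -> FA candidate extraction and filtering ->
edge distances and normalisation -> group statistics.  A run manifest
records the software version, a config hash and per-stage counts (images,
cells, FA candidates, accepted/rejected) so every run is auditable and
count conservation can be asserted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    DEFAULT_CHANNELS,
    read_ome_tiff,
    read_samplesheet,
    write_json,
    write_mask_tiff,
)
from .localisation import (
    FAFilterParams,
    build_distance_frame,
    fa_edge_distance,
    filter_fa_candidates,
    find_fa_candidates,
    normalise_distance,
)
from .morphometrics import describe_region
from .segmentation import (
    ImageRecord,
    SegmentationParams,
    classify_vinculin,
    median_denoise,
    segment_cells,
    subtract_pillar_background,
)
from .stats import GroupSample, compare_all_groups

__all__ = [
    "RunConfig",
    "ConfigError",
    "validate_config",
    "analyse_image",
    "run_pipeline",
]

CELL_COLUMNS = [
    "image", "surface", "time", "cell_id", "area_um2", "perimeter_um",
    "circularity", "roundness", "aspect_ratio", "n_fa",
    "fa_area_total_um2", "fa_area_fraction",
]
FA_COLUMNS = [
    "image", "surface", "time", "cell_id", "fa_id", "area_um2",
    "aspect_ratio", "d_um", "d_norm_maxr", "d_norm_area", "flags",
]


class ConfigError(ValueError):
    """Aggregated, human-readable config violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    """Validated pipeline configuration with the published defaults:
    34 nm pixels, 10 px-scale median window (odd realisation 9), three Otsu
    classes, aspect-ratio window (1.5, 8.5), 0.05 um^2 minimum FA area."""

    inputs: list[str] = field(default_factory=list)
    samplesheet: str | None = None
    channels: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    pixel_size: float | None = 34.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    fa_filter: FAFilterParams = field(default_factory=FAFilterParams)
    distance_interpolation: str = "bilinear"
    stats_metric: str = "d_norm_maxr"
    pool_fas: bool = True
    holm: bool = False
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"


def validate_config(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain dict (e.g. parsed YAML),
    reporting every violation with its field path at once."""
    errors: list[str] = []
    known = {
        "inputs", "samplesheet", "channels", "pixel_size", "segmentation",
        "fa_filter", "distance_interpolation", "stats_metric", "pool_fas",
        "holm", "out_dir", "seed", "log_level",
    }
    for key in raw:
        if key not in known:
            errors.append(f"{key}: unknown field")

    seg_raw = dict(raw.get("segmentation", {}))
    filt_raw = dict(raw.get("fa_filter", {}))
    try:
        seg = SegmentationParams(**seg_raw)
    except (TypeError, ValueError) as e:
        errors.append(f"segmentation: {e}")
        seg = SegmentationParams()
    try:
        filt = FAFilterParams(**filt_raw)
    except (TypeError, ValueError) as e:
        errors.append(f"fa_filter: {e}")
        filt = FAFilterParams()

    px = raw.get("pixel_size", 34.0)
    if px is not None and (not isinstance(px, (int, float)) or px <= 0):
        errors.append(f"pixel_size: must be a positive number, got {px!r}")
    interp = raw.get("distance_interpolation", "bilinear")
    if interp not in ("bilinear", "nearest"):
        errors.append(
            f"distance_interpolation: must be bilinear or nearest, got {interp!r}"
        )
    inputs = list(raw.get("inputs", []))
    for p in inputs:
        if not Path(p).exists():
            errors.append(f"inputs: file not found: {p}")
    sheet = raw.get("samplesheet")
    if sheet is not None and not Path(sheet).exists():
        errors.append(f"samplesheet: file not found: {sheet}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        inputs=inputs,
        samplesheet=sheet,
        channels=dict(raw.get("channels", DEFAULT_CHANNELS)),
        pixel_size=px,
        segmentation=seg,
        fa_filter=filt,
        distance_interpolation=interp,
        stats_metric=raw.get("stats_metric", "d_norm_maxr"),
        pool_fas=bool(raw.get("pool_fas", True)),
        holm=bool(raw.get("holm", False)),
        out_dir=str(raw.get("out_dir", "results")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def analyse_image(
    record: ImageRecord,
    seg_params: SegmentationParams | None = None,
    filter_params: FAFilterParams | None = None,
    distance_interpolation: str = "bilinear",
    image_name: str = "image",
) -> dict:
    """Run the full single-image chain.

    Returns a dict with ``cells`` and ``fas`` DataFrames, the per-cell
    masks, the vinculin :class:`ClassMap` and the stage ``counts`` used for
    the manifest's count-conservation check.
    """
    seg_params = seg_params or SegmentationParams()
    filter_params = filter_params or FAFilterParams()

    corrected = subtract_pillar_background(record.vinculin, record.pillar)
    denoised = median_denoise(corrected, seg_params.median_size)
    fa_class = (
        seg_params.fa_class_index
        if seg_params.fa_class_index is not None
        else seg_params.n_otsu_classes - 1
    )
    try:
        class_map = classify_vinculin(denoised, seg_params)
        fa_mask = class_map.labels == fa_class
    except ValueError:
        # degenerate vinculin channel (fewer distinct intensities than
        # classes): no FA candidates, but the cells are still measurable
        from .segmentation import ClassMap

        class_map = ClassMap(
            labels=np.zeros(denoised.shape, dtype=np.uint8), thresholds=()
        )
        fa_mask = np.zeros(denoised.shape, dtype=bool)

    cell_masks = segment_cells(record.actin, record.pixel_size, seg_params)
    candidates = find_fa_candidates(
        fa_mask, cell_masks, record.pixel_size, seg_params.connectivity
    )
    accepted, rejection_log = filter_fa_candidates(candidates, filter_params)

    frames = {}
    cell_stats = {}
    for cid, mask in enumerate(cell_masks):
        frames[cid] = build_distance_frame(mask, record.pixel_size, cid)
        cell_stats[cid] = describe_region(mask, record.pixel_size)

    fa_rows = []
    per_cell_fa_area: dict[int, float] = {cid: 0.0 for cid in frames}
    per_cell_fa_n: dict[int, int] = {cid: 0 for cid in frames}
    for fa in accepted:
        flags = []
        if fa.cell_id in frames:
            frame = frames[fa.cell_id]
            d, outside = fa_edge_distance(
                fa.centroid, frame, distance_interpolation
            )
            if outside:
                flags.append("centroid_outside_mask")
                nmr, nar = 0.0, 0.0
            else:
                nmr, nar = normalise_distance(
                    d, frame, cell_stats[fa.cell_id].area_um2
                )
            fa.edge_distance_um = d
            fa.norm_distance_maxr = nmr
            fa.norm_distance_area = nar
            fa.outside_mask = outside
            per_cell_fa_area[fa.cell_id] += fa.area_um2
            per_cell_fa_n[fa.cell_id] += 1
        else:
            flags.append("unassigned_cell")
        fa_rows.append(
            {
                "image": image_name,
                "surface": record.surface_label,
                "time": record.time_label,
                "cell_id": fa.cell_id,
                "fa_id": fa.fa_id,
                "area_um2": fa.area_um2,
                "aspect_ratio": fa.aspect_ratio,
                "d_um": fa.edge_distance_um,
                "d_norm_maxr": fa.norm_distance_maxr,
                "d_norm_area": fa.norm_distance_area,
                "flags": "|".join(flags),
            }
        )

    cell_rows = []
    for cid, desc in cell_stats.items():
        cell_rows.append(
            {
                "image": image_name,
                "surface": record.surface_label,
                "time": record.time_label,
                "cell_id": cid,
                "area_um2": desc.area_um2,
                "perimeter_um": desc.perimeter_um,
                "circularity": desc.circularity,
                "roundness": desc.roundness,
                "aspect_ratio": desc.aspect_ratio,
                "n_fa": per_cell_fa_n[cid],
                "fa_area_total_um2": per_cell_fa_area[cid],
                "fa_area_fraction": per_cell_fa_area[cid] / desc.area_um2,
            }
        )

    n_rej_ar = sum(1 for _, r in rejection_log if "round" in r or "elongated" in r)
    n_rej_area_only = sum(1 for _, r in rejection_log if r == "too_small")
    counts = {
        "n_cells": len(cell_masks),
        "n_fa_candidates": len(candidates),
        "n_fa_accepted": len(accepted),
        "n_fa_rejected_ar": n_rej_ar,
        "n_fa_rejected_area": n_rej_area_only,
    }
    assert counts["n_fa_candidates"] == (
        counts["n_fa_accepted"] + len(rejection_log)
    ), "FA count conservation violated"

    return {
        "cells": pd.DataFrame(cell_rows, columns=CELL_COLUMNS),
        "fas": pd.DataFrame(fa_rows, columns=FA_COLUMNS),
        "cell_masks": cell_masks,
        "class_map": class_map,
        "rejection_log": rejection_log,
        "counts": counts,
    }


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole pipeline over the configured inputs.

    Writes ``cells.csv``, ``fas.csv``, ``comparisons.csv``/``.json``, label
    masks and ``manifest.json`` into ``config.out_dir`` and returns the
    tables in memory.  Unreadable images are skipped with a warning counted
    in the manifest; reruns with identical config and inputs produce
    byte-identical CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    entries: list[tuple[str, str, str]] = []
    if config.samplesheet:
        sheet = read_samplesheet(config.samplesheet)
        entries += [
            (str(r.path), str(r.surface), str(r.time))
            for r in sheet.itertuples()
        ]
    entries += [(p, "custom", "custom") for p in config.inputs]

    all_cells, all_fas = [], []
    per_image_counts = {}
    n_skipped = 0
    for path, surface, time in entries:
        name = Path(path).name
        try:
            record = read_ome_tiff(
                path,
                channels=config.channels,
                pixel_size=config.pixel_size,
                surface_label=surface,
                time_label=time,
            )
        except Exception as e:  # unreadable image: skip, keep going
            import logging

            logging.getLogger(__name__).warning("skipping %s: %s", path, e)
            n_skipped += 1
            continue
        result = analyse_image(
            record,
            config.segmentation,
            config.fa_filter,
            config.distance_interpolation,
            image_name=name,
        )
        all_cells.append(result["cells"])
        all_fas.append(result["fas"])
        per_image_counts[name] = result["counts"]
        write_mask_tiff(out / f"{Path(name).stem}_cells.tif", result["cell_masks"])

    cells = (
        pd.concat(all_cells, ignore_index=True)
        if all_cells
        else pd.DataFrame(columns=CELL_COLUMNS)
    )
    fas = (
        pd.concat(all_fas, ignore_index=True)
        if all_fas
        else pd.DataFrame(columns=FA_COLUMNS)
    )
    cells.to_csv(out / "cells.csv", index=False)
    fas.to_csv(out / "fas.csv", index=False)

    comparisons = pd.DataFrame()
    metric = config.stats_metric
    source = fas if metric in fas.columns else cells
    if not source.empty and metric in source.columns:
        groups = []
        for (surface, time), sub in source.groupby(["surface", "time"], sort=True):
            vals = sub[metric].dropna().to_numpy()
            if vals.size:
                groups.append(GroupSample(label=(surface, time), values=vals))
        if len(groups) >= 2:
            comparisons = compare_all_groups(groups, holm=config.holm)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    write_json(out / "comparisons.json", comparisons.to_dict(orient="records"))

    manifest = {
        "nanofa_version": __version__,
        "config_hash": _config_hash(config),
        "n_images": len(per_image_counts),
        "n_images_skipped": n_skipped,
        "per_image_counts": per_image_counts,
        "totals": {
            "n_cells": int(cells.shape[0]),
            "n_fa_accepted": int(fas.shape[0]),
        },
    }
    write_json(out / "manifest.json", manifest)
    return {
        "cells": cells,
        "fas": fas,
        "comparisons": comparisons,
        "manifest": manifest,
    }
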