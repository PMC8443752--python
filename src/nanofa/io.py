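"""Reading and writing multichannel images and tidy result tables.

The canonical interchange format is multichannel OME-TIFF with channel
order (actin, vinculin, pillar) and the in-plane pixel size recorded in the
OME physical-size metadata, so no proprietary reader is ever needed.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import ImageRecord

__all__ = [
    "write_ome_tiff",
    "read_ome_tiff",
    "write_mask_tiff",
    "read_samplesheet",
]

DEFAULT_CHANNELS = {"actin": 0, "vinculin": 1, "pillar": 2}


def write_ome_tiff(path: str | Path, record: ImageRecord) -> None:
    """Write the three channels as CYX OME-TIFF with pixel size in um."""
    stack = np.stack([record.actin, record.vinculin, record.pillar]).astype(
        np.float32
    )
    px_um = record.pixel_size / 1000.0
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": px_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": px_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": ["actin", "vinculin", "pillar"]},
        },
    )


def _pixel_size_from_ome(ome_xml: str | None) -> float | None:
    if not ome_xml:
        return None
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', ome_xml)
    if not m:
        return None
    size = float(m.group(1))
    unit = re.search(r'PhysicalSizeXUnit="([^"]+)"', ome_xml)
    # OME default unit is um; convert to nm
    if unit and unit.group(1) in ("nm",):
        return size
    return size * 1000.0


def read_ome_tiff(
    path: str | Path,
    channels: dict[str, int] | None = None,
    pixel_size: float | None = None,
    surface_label: str = "custom",
    time_label: str = "custom",
) -> ImageRecord:
    """Read a multichannel TIFF into an :class:`ImageRecord`.

    ``channels`` maps role -> channel index (default actin 0, vinculin 1,
    pillar 2).  The pixel size (nm/px) is taken from the OME metadata when
    present; an explicit ``pixel_size`` overrides it and is required when
    the file carries none.
    """
    channels = channels or DEFAULT_CHANNELS
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_ome(tif.ome_metadata)
    if data.ndim == 2:
        raise ValueError(f"{path}: expected a multichannel image, got a single plane")
    if data.ndim != 3:
        data = np.squeeze(data)
    if data.shape[0] > data.shape[-1]:  # tolerate YXC layouts
        data = np.moveaxis(data, -1, 0)
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in metadata and none supplied in config"
        )
    return ImageRecord(
        actin=data[channels["actin"]].astype(float),
        vinculin=data[channels["vinculin"]].astype(float),
        pillar=data[channels["pillar"]].astype(float),
        pixel_size=px,
        surface_label=surface_label,
        time_label=time_label,
    )


def write_mask_tiff(path: str | Path, masks: list[np.ndarray]) -> None:
    """Write per-cell masks as one 16-bit label image (0 = background)."""
    if masks:
        label = np.zeros(masks[0].shape, dtype=np.uint16)
        for i, m in enumerate(masks, start=1):
            label[m] = i
    else:
        label = np.zeros((1, 1), dtype=np.uint16)
    tifffile.imwrite(str(path), label)


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Samplesheet CSV with columns ``path, surface, time`` (labels come
    from this file, never from filename parsing)."""
    sheet = pd.read_csv(path)
    missing = {"path", "surface", "time"} - set(sheet.columns)
    if missing:
        raise ValueError(f"samplesheet lacks columns: {sorted(missing)}")
    return sheet


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
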