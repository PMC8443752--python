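"""Focal-adhesion acceptance filtering and edge-distance analysis.

Candidate vinculin-rich regions are filtered on shape: regions that are too
round (aspect ratio <= 1.5, typically cytosolic blobs or pillar remnants) or
too elongated (aspect ratio >= 8.5, typically stress-fibre bleed-through)
are rejected, as are regions smaller than 0.05 um^2.  Accepted adhesions are
localised relative to the cell edge via the Euclidean distance transform of
the cell mask, and the distance is normalised two ways so cells of different
sizes are comparable:

* by the cell's maximum edge distance (the radius for a circular cell), and
* by the equivalent-circle radius sqrt(Area/pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphometrics import EllipseFit

__all__ = [
    "FAFilterParams",
    "FARecord",
    "CellDistanceFrame",
    "filter_fa_candidates",
    "build_distance_frame",
    "fa_edge_distance",
    "normalise_distance",
    "find_fa_candidates",
]


@dataclass(frozen=True)
class FAFilterParams:
    """Acceptance window for vinculin regions.  Both aspect-ratio bounds are
    rejection-inclusive: AR equal to a bound is rejected."""

    ar_min_exclusive: float = 1.5
    ar_max_exclusive: float = 8.5
    min_area: float = 0.05  # um^2

    def __post_init__(self) -> None:
        if not self.ar_min_exclusive < self.ar_max_exclusive:
            raise ValueError("ar_min must be below ar_max")
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")


@dataclass
class FARecord:
    """One vinculin-rich region, before or after filtering."""

    cell_id: int
    fa_id: int
    mask: np.ndarray | None
    area_um2: float
    ellipse: EllipseFit | None
    aspect_ratio: float
    centroid: tuple[float, float]  # (row, col), px
    edge_distance_um: float = np.nan
    norm_distance_maxr: float = np.nan
    norm_distance_area: float = np.nan
    outside_mask: bool = False


@dataclass
class CellDistanceFrame:
    """Per-pixel Euclidean distance to the cell edge (um, 0 outside the
    mask), its maximum (the normalising radius) and the mask centroid."""

    cell_id: int
    distance_map: np.ndarray
    normalising_radius: float
    geometric_centre: tuple[float, float]
    mask: np.ndarray = field(repr=False, default=None)


def filter_fa_candidates(
    regions: list[FARecord], params: FAFilterParams | None = None
) -> tuple[list[FARecord], list[tuple[int, str]]]:
    """Apply the shape filters; returns (accepted, rejection log).

    A region is kept iff ``ar_min < AR < ar_max`` and ``area >= min_area``.
    The log holds one ``(index, reason)`` entry per rejected region with
    every failing rule named, so candidate counts are conserved:
    ``len(regions) == len(accepted) + len(log)``.
    """
    params = params or FAFilterParams()
    accepted: list[FARecord] = []
    log: list[tuple[int, str]] = []
    for i, reg in enumerate(regions):
        reasons = []
        if reg.aspect_ratio <= params.ar_min_exclusive:
            reasons.append("too_round")
        elif reg.aspect_ratio >= params.ar_max_exclusive:
            reasons.append("too_elongated")
        if reg.area_um2 < params.min_area:
            reasons.append("too_small")
        if reasons:
            log.append((i, "+".join(reasons)))
        else:
            accepted.append(reg)
    return accepted, log


def build_distance_frame(
    cell_mask: np.ndarray, pixel_size: float, cell_id: int = 0
) -> CellDistanceFrame:
    """Exact Euclidean distance transform of the cell interior, in um."""
    if not np.any(cell_mask):
        raise ValueError("empty cell mask")
    dmap = ndimage.distance_transform_edt(cell_mask) * (pixel_size / 1000.0)
    rows, cols = np.nonzero(cell_mask)
    return CellDistanceFrame(
        cell_id=cell_id,
        distance_map=dmap,
        normalising_radius=float(dmap.max()),
        geometric_centre=(float(rows.mean()), float(cols.mean())),
        mask=cell_mask,
    )


def fa_edge_distance(
    centroid: tuple[float, float],
    frame: CellDistanceFrame,
    interpolation: str = "bilinear",
) -> tuple[float, bool]:
    """Shortest distance (um) from an FA centroid to the cell edge.

    The distance map is sampled at the (sub-pixel) centroid, bilinearly by
    default.  A centroid falling outside the mask — possible for adhesions
    at the very periphery — yields ``(0.0, True)`` rather than an error, so
    record counts are conserved downstream.
    """
    r, c = centroid
    ri, ci = int(round(r)), int(round(c))
    inside = (
        0 <= ri < frame.mask.shape[0]
        and 0 <= ci < frame.mask.shape[1]
        and bool(frame.mask[ri, ci])
    )
    if not inside:
        return 0.0, True
    if interpolation == "bilinear":
        d = float(ndimage.map_coordinates(frame.distance_map, [[r], [c]], order=1)[0])
    elif interpolation == "nearest":
        d = float(frame.distance_map[ri, ci])
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return d, False


def normalise_distance(
    d: float, frame: CellDistanceFrame, cell_area_um2: float
) -> tuple[float, float]:
    """Both normalisations of an edge distance.

    ``norm_maxr = d / normalising_radius`` lies in [0, 1]; ``norm_area``
    divides by the equivalent-circle radius ``sqrt(area/pi)`` (for a disk
    the two coincide).
    """
    if frame.normalising_radius <= 0:
        raise ValueError("normalising radius must be positive")
    if cell_area_um2 <= 0:
        raise ValueError("cell area must be positive")
    r_eq = float(np.sqrt(cell_area_um2 / np.pi))
    return d / frame.normalising_radius, d / r_eq


def find_fa_candidates(
    fa_mask: np.ndarray,
    cell_masks: list[np.ndarray],
    pixel_size: float,
    connectivity: int = 8,
) -> list[FARecord]:
    """Connected components of the FA-rich class restricted to the cells.

    Each component becomes an unfiltered :class:`FARecord`; it is assigned
    to the cell whose mask contains its centroid (components whose centroid
    lands outside every cell keep ``cell_id = -1``).  Components below the
    5 px ellipse-fit minimum are described with a degenerate single-pixel
    ellipse so they can still be (and invariably are) rejected on area.
    """
    from .morphometrics import fit_ellipse, region_area

    if not cell_masks:
        return []
    union = np.zeros_like(fa_mask, dtype=bool)
    for m in cell_masks:
        union |= m
    candidates = fa_mask & union
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labelled, n = ndimage.label(candidates, structure=structure)
    records: list[FARecord] = []
    for lab in range(1, n + 1):
        m = labelled == lab
        area = region_area(m, pixel_size)
        try:
            ell = fit_ellipse(m)
            ar = ell.aspect_ratio
            centroid = ell.centroid
        except ValueError:  # < 5 px
            rows, cols = np.nonzero(m)
            centroid = (float(rows.mean()), float(cols.mean()))
            ell, ar = None, 1.0
        cell_id = -1
        ri, ci = int(round(centroid[0])), int(round(centroid[1]))
        for k, cm in enumerate(cell_masks):
            if cm[ri, ci]:
                cell_id = k
                break
        records.append(
            FARecord(
                cell_id=cell_id,
                fa_id=lab - 1,
                mask=m,
                area_um2=area,
                ellipse=ell,
                aspect_ratio=ar,
                centroid=centroid,
            )
        )
    return records
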