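"""Synthetic fluorescence scenes with exact ground truth.

Generates the three-channel imaging situation the analysis pipeline expects:
an actin-reporter channel showing a bright, fibre-textured cell on a dark
background; a vinculin-reporter channel with three intensity populations
(background, cytosolic vinculin, bright elliptical focal-adhesion patches)
plus optional pillar-lattice cross-talk; and a pillar channel of Gaussian
spots on a regular nanopillar lattice.  Every scene carries a
:class:`GroundTruth` recording the planted cell mask, focal-adhesion table
and edge distances, so each downstream stage can be tested against known
answers.

All randomness flows through a single :class:`numpy.random.Generator`
constructed from the scene seed; identical specs yield bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import ImageRecord

__all__ = [
    "LatticeSpec",
    "PlantedFA",
    "CellShapeParams",
    "SceneSpec",
    "GroundTruth",
    "lattice_density",
    "lattice_sites",
    "make_cell_mask",
    "render_scene",
    "sample_distance_cohort",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Regular nanopillar array.

    Parameters
    ----------
    kind:
        ``"hexagonal"`` (triangular packing, the default array geometry) or
        ``"square"``.
    pitch:
        Centre-to-centre pillar distance in nm.
    spot_sigma:
        Gaussian radius of one rendered pillar spot, nm.
    spot_amplitude:
        Peak intensity of one pillar spot, arbitrary units.
    """

    kind: Literal["hexagonal", "square"] = "hexagonal"
    pitch: float = 1000.0
    spot_sigma: float = 120.0
    spot_amplitude: float = 80.0

    def __post_init__(self) -> None:
        if self.kind not in ("hexagonal", "square"):
            raise ValueError(f"unknown lattice kind {self.kind!r}")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")


def lattice_density(lattice: LatticeSpec) -> float:
    """Areal pillar density in pillars per 100 um^2 (closed form).

    Hexagonal packing has 2 sites per ``sqrt(3) * pitch**2`` rhombic cell,
    square packing 1 site per ``pitch**2``.  Callers round to the nearest
    integer for reporting.
    """
    if lattice.pitch <= 0:
        raise ValueError("pitch must be positive")
    pitch_um = lattice.pitch / 1000.0
    if lattice.kind == "hexagonal":
        per_um2 = 2.0 / (math.sqrt(3.0) * pitch_um**2)
    else:
        per_um2 = 1.0 / pitch_um**2
    return per_um2 * 100.0


def lattice_sites(
    lattice: LatticeSpec,
    image_shape: tuple[int, int],
    pixel_size: float,
) -> np.ndarray:
    """Pillar centre positions (row, col) in px that fall inside the image.

    A hexagonal lattice is built from rows spaced ``pitch * sqrt(3)/2`` with
    every other row offset by half a pitch; a square lattice is a plain grid.
    The lattice origin is offset by half a pitch so no site sits exactly on
    the image border.
    """
    pitch_px = lattice.pitch / pixel_size
    nrows, ncols = image_shape
    sites = []
    if lattice.kind == "hexagonal":
        row_step = pitch_px * math.sqrt(3.0) / 2.0
        n_r = int(nrows / row_step) + 2
        for i in range(n_r):
            r = (i + 0.5) * row_step
            if r >= nrows:
                break
            offset = 0.5 * pitch_px if i % 2 else 0.0
            c = 0.5 * pitch_px + offset
            while c < ncols:
                sites.append((r, c))
                c += pitch_px
    else:
        r = 0.5 * pitch_px
        while r < nrows:
            c = 0.5 * pitch_px
            while c < ncols:
                sites.append((r, c))
                c += pitch_px
            r += pitch_px
    return np.asarray(sites, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class PlantedFA:
    """One ground-truth focal adhesion: an ellipse planted in the vinculin
    channel.  Axes are full lengths in px; ``major_axis >= minor_axis``."""

    centre: tuple[float, float]  # (row, col), px
    major_axis: float
    minor_axis: float
    orientation: float = 0.0  # rad, from the column axis, y up
    intensity: float | None = None  # None -> scene fa_level

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis / self.minor_axis


@dataclass(frozen=True)
class CellShapeParams:
    """Star-convex cell outline: a disk of ``base_radius`` px whose radius is
    modulated by low-order Fourier terms with random phases,
    ``r(theta) = R * (1 + sum_k a_k cos((k+2) theta + phi_k))``.

    Modes start at 2 so the perturbation never reduces to a pure translation.
    """

    base_radius: float = 100.0
    perturb_amplitudes: tuple[float, ...] = ()
    seed: int = 0
    centre: tuple[float, float] | None = None  # default: image centre


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic field of view."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 34.0  # nm/px
    cell_shape: CellShapeParams = field(default_factory=CellShapeParams)
    fa_list: tuple[PlantedFA, ...] = ()
    background_level: float = 10.0
    cytosol_level: float = 60.0
    fa_level: float = 160.0
    actin_level: float = 120.0
    fibre_count: int = 0
    fibre_amplitude: float = 25.0
    lattice: LatticeSpec | None = None
    crosstalk_fraction: float = 0.0
    gaussian_sd: float = 0.0
    poisson_scaling: float = 0.0
    seed: int = 0
    surface_label: str = "custom"
    time_label: str = "custom"

    def __post_init__(self) -> None:
        if not (self.background_level < self.cytosol_level < self.fa_level):
            raise ValueError(
                "intensity levels must satisfy background < cytosol < fa"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.crosstalk_fraction <= 1.0:
            raise ValueError("crosstalk_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-scene truth: planted cell mask, focal-adhesion table (areas in
    um^2, aspect ratios, edge distances in um), the cell's normalising
    radius (max edge distance, um) and the seed used."""

    cell_mask: np.ndarray
    fa_table: pd.DataFrame
    normalising_radius: float
    cell_area_um2: float
    seed: int


def make_cell_mask(
    shape_params: CellShapeParams,
    image_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise the star-convex cell outline.

    Returns ``(mask, polygon)`` where ``polygon`` is an (N, 2) array of
    (row, col) boundary vertices.  The region is connected and hole-free by
    construction (star convexity).  Deterministic given ``shape_params.seed``.
    """
    nrows, ncols = image_shape
    centre = shape_params.centre or ((nrows - 1) / 2.0, (ncols - 1) / 2.0)
    rng = np.random.default_rng(shape_params.seed)
    amps = np.asarray(shape_params.perturb_amplitudes, dtype=float)
    phases = rng.uniform(0, 2 * np.pi, size=amps.size)

    r_max = shape_params.base_radius * (1.0 + np.abs(amps).sum())
    margin = min(centre[0], centre[1], nrows - 1 - centre[0], ncols - 1 - centre[1])
    if r_max + 10 > margin:
        raise ValueError(
            f"cell radius {r_max:.1f} px + 10 px margin exceeds the "
            f"{margin:.1f} px available around the centre; use a larger "
            "image or a smaller base radius"
        )

    rr, cc = np.mgrid[0:nrows, 0:ncols]
    dy = rr - centre[0]
    dx = cc - centre[1]
    theta = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    r_theta = np.full_like(theta, shape_params.base_radius)
    for k, (a, phi) in enumerate(zip(amps, phases)):
        r_theta += shape_params.base_radius * a * np.cos((k + 2) * theta + phi)
    mask = radius <= r_theta

    t = np.linspace(0, 2 * np.pi, 721)
    r_t = np.full_like(t, shape_params.base_radius)
    for k, (a, phi) in enumerate(zip(amps, phases)):
        r_t += shape_params.base_radius * a * np.cos((k + 2) * t + phi)
    polygon = np.column_stack([centre[0] + r_t * np.sin(t), centre[1] + r_t * np.cos(t)])
    return mask, polygon


def _ellipse_mask(fa: PlantedFA, image_shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centres lie inside the planted ellipse."""
    a = fa.major_axis / 2.0
    b = fa.minor_axis / 2.0
    r0, c0 = fa.centre
    half = int(math.ceil(a)) + 1
    rlo = max(0, int(r0) - half)
    rhi = min(image_shape[0], int(r0) + half + 1)
    clo = max(0, int(c0) - half)
    chi = min(image_shape[1], int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dy = -(rr - r0)  # y up
    dx = cc - c0
    ct, st = math.cos(fa.orientation), math.sin(fa.orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(image_shape, dtype=bool)
    out[rlo:rhi, clo:chi] = local
    return out


def _render_pillars(scene: SceneSpec) -> np.ndarray:
    img = np.zeros(scene.image_shape, dtype=float)
    if scene.lattice is None:
        return img
    lat = scene.lattice
    sigma_px = lat.spot_sigma / scene.pixel_size
    half = int(math.ceil(4 * sigma_px))
    win = np.arange(-half, half + 1)
    for r0, c0 in lattice_sites(lat, scene.image_shape, scene.pixel_size):
        ri = int(round(r0))
        ci = int(round(c0))
        rows = win + ri
        cols = win + ci
        rsel = (rows >= 0) & (rows < scene.image_shape[0])
        csel = (cols >= 0) & (cols < scene.image_shape[1])
        gr = np.exp(-((rows[rsel] - r0) ** 2) / (2 * sigma_px**2))
        gc = np.exp(-((cols[csel] - c0) ** 2) / (2 * sigma_px**2))
        img[np.ix_(rows[rsel], cols[csel])] += lat.spot_amplitude * np.outer(gr, gc)
    return img


def _render_fibres(
    mask: np.ndarray, scene: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """Additive oriented line segments inside the cell — cosmetic actin
    texture for segmentation robustness, not a cytoskeleton model."""
    from skimage.draw import line

    tex = np.zeros(scene.image_shape, dtype=float)
    if scene.fibre_count == 0:
        return tex
    inside = np.argwhere(mask)
    length = int(scene.cell_shape.base_radius)
    for _ in range(scene.fibre_count):
        r0, c0 = inside[rng.integers(len(inside))]
        ang = rng.uniform(0, np.pi)
        r1 = int(np.clip(r0 + length * math.sin(ang), 0, scene.image_shape[0] - 1))
        c1 = int(np.clip(c0 + length * math.cos(ang), 0, scene.image_shape[1] - 1))
        rr, cc = line(int(r0), int(c0), r1, c1)
        tex[rr, cc] += scene.fibre_amplitude
    tex[~mask] = 0.0
    return tex


def render_scene(scene: SceneSpec) -> tuple[ImageRecord, GroundTruth]:
    """Render the three channels and the matching ground truth.

    The vinculin channel is ``background_level`` outside the cell,
    ``cytosol_level`` inside, ``fa_level`` (or the per-FA intensity) on
    planted ellipse pixels, plus ``crosstalk_fraction`` times the pillar
    channel, plus noise.  True edge distances are read off the Euclidean
    distance transform of the planted mask at each FA centre (bilinear).

    Raises
    ------
    ValueError
        If any planted FA centre falls outside the cell mask (the offending
        indices are listed).
    """
    rng = np.random.default_rng(scene.seed)
    mask, _ = make_cell_mask(scene.cell_shape, scene.image_shape)

    bad = [
        i
        for i, fa in enumerate(scene.fa_list)
        if not mask[int(round(fa.centre[0])), int(round(fa.centre[1]))]
    ]
    if bad:
        raise ValueError(f"FA centres outside the cell mask at indices {bad}")

    px_um = scene.pixel_size / 1000.0
    edt_um = ndimage.distance_transform_edt(mask) * px_um
    normalising_radius = float(edt_um.max())

    vinculin = np.where(mask, scene.cytosol_level, scene.background_level).astype(float)
    rows = []
    for i, fa in enumerate(scene.fa_list):
        emask = _ellipse_mask(fa, scene.image_shape) & mask
        vinculin[emask] = fa.intensity if fa.intensity is not None else scene.fa_level
        d = float(
            ndimage.map_coordinates(
                edt_um, [[fa.centre[0]], [fa.centre[1]]], order=1
            )[0]
        )
        rows.append(
            {
                "fa_id": i,
                "centre_row": fa.centre[0],
                "centre_col": fa.centre[1],
                "major_px": fa.major_axis,
                "minor_px": fa.minor_axis,
                "orientation": fa.orientation,
                "aspect_ratio": fa.aspect_ratio,
                "area_px": int(emask.sum()),
                "area_um2": float(emask.sum()) * px_um**2,
                "true_edge_distance_um": d,
                "norm_distance_maxr": d / normalising_radius,
            }
        )
    fa_table = pd.DataFrame(
        rows,
        columns=[
            "fa_id", "centre_row", "centre_col", "major_px", "minor_px",
            "orientation", "aspect_ratio", "area_px", "area_um2",
            "true_edge_distance_um", "norm_distance_maxr",
        ],
    )

    pillar = _render_pillars(scene)
    actin = np.where(mask, scene.actin_level, scene.background_level).astype(float)
    actin += _render_fibres(mask, scene, rng)
    vinculin = vinculin + scene.crosstalk_fraction * pillar

    for img in (actin, vinculin, pillar):
        if scene.poisson_scaling > 0:
            img[:] = rng.poisson(img * scene.poisson_scaling) / scene.poisson_scaling
        if scene.gaussian_sd > 0:
            img += rng.normal(0.0, scene.gaussian_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)

    record = ImageRecord(
        actin=actin,
        vinculin=vinculin,
        pillar=pillar,
        pixel_size=scene.pixel_size,
        surface_label=scene.surface_label,
        time_label=scene.time_label,
    )
    truth = GroundTruth(
        cell_mask=mask,
        fa_table=fa_table,
        normalising_radius=normalising_radius,
        cell_area_um2=float(mask.sum()) * px_um**2,
        seed=scene.seed,
    )
    return record, truth


def sample_distance_cohort(
    median: float,
    q1: float,
    q3: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a synthetic focal-adhesion edge-distance cohort (um).

    A log-normal is fit to the requested quartiles: the median fixes mu and
    the interquartile ratio fixes sigma via ``Q3/Q1 = exp(2 * z_.75 * sigma)``
    with ``z_.75 = 0.67449``.  Edge distances are positive and right-skewed,
    which this family matches.
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError("require 0 < q1 <= median <= q3")
    z75 = 0.6744897501960817
    sigma = math.log(q3 / q1) / (2 * z75) if q3 > q1 else 0.0
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
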