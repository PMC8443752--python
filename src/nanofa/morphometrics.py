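"""Shape descriptors for cells and vinculin-rich regions.

Areas come from pixel counts corrected for pixel size; shape geometry comes
from fitting each region with the ellipse sharing its second central
moments.  Three dimensionless descriptors are computed:

* aspect ratio  AR = major axis / minor axis  (>= 1),
* circularity   C  = 4 pi Area / Perimeter^2  (1 for a circle),
* roundness     R  = 4 Area / (pi MajorAxis^2)  (= minor/major = 1/AR for an
  exact ellipse).

C is reported as-is, without clamping at 1: the marching-squares perimeter
slightly underestimates the boundary length of rasterised shapes, so values
marginally above 1 can occur for near-circular regions and are meaningful as
a discretisation bias, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "EllipseFit",
    "ShapeDescriptors",
    "region_area",
    "fit_ellipse",
    "circularity",
    "roundness",
    "perimeter_estimate",
    "describe_region",
]


@dataclass(frozen=True)
class EllipseFit:
    """Second-moment ellipse of a binary region.

    Axes are full lengths in px under the 4*sqrt(eigenvalue) convention, so
    the fitted axes of an exact ellipse equal its geometric axes.
    ``orientation`` is the major-axis angle from the column (x) axis with y
    pointing up, in (-pi/2, pi/2].  ``degenerate`` flags collinear regions
    whose minor axis was floored at one pixel.
    """

    centroid: tuple[float, float]  # (row, col)
    major_axis: float
    minor_axis: float
    orientation: float
    degenerate: bool = False

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis / self.minor_axis


@dataclass(frozen=True)
class ShapeDescriptors:
    area_um2: float
    perimeter_um: float
    aspect_ratio: float
    circularity: float
    roundness: float
    ellipse: EllipseFit


def region_area(mask: np.ndarray, pixel_size: float) -> float:
    """Pixel-count area corrected to um^2 (``pixel_size`` in nm)."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty mask")
    return n * (pixel_size / 1000.0) ** 2


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Ellipse with the same second central moments as the region.

    With lam1 >= lam2 the eigenvalues of the normalised second-moment
    matrix, the full axes are 4*sqrt(lam1) and 4*sqrt(lam2).  Degenerate
    (collinear) regions get a one-pixel minor-axis floor and are flagged.
    """
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n < 5:
        raise ValueError(f"region has {n} px; ellipse fit needs at least 5")
    r0, c0 = rows.mean(), cols.mean()
    y = -(rows - r0)  # y up so orientation is a conventional CCW angle
    x = cols - c0
    sxx = float(x @ x) / n
    syy = float(y @ y) / n
    sxy = float(x @ y) / n
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = math.sqrt(max(tr**2 / 4 - det, 0.0))
    lam1 = tr / 2 + disc
    lam2 = max(tr / 2 - disc, 0.0)
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    degenerate = minor < 1.0
    if degenerate:
        minor = 1.0
        major = max(major, minor)
    theta = 0.5 * math.atan2(2 * sxy, sxx - syy)
    if theta <= -math.pi / 2:
        theta += math.pi
    return EllipseFit(
        centroid=(float(r0), float(c0)),
        major_axis=major,
        minor_axis=minor,
        orientation=theta,
        degenerate=degenerate,
    )


def circularity(area: float, perimeter: float) -> float:
    """C = 4 pi Area / Perimeter^2 (any consistent units)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def roundness(area: float, major_axis: float) -> float:
    """R = 4 Area / (pi MajorAxis^2) (any consistent units)."""
    if major_axis <= 0:
        raise ValueError("major_axis must be positive")
    return 4.0 * area / (math.pi * major_axis**2)


def perimeter_estimate(
    mask: np.ndarray, pixel_size: float = 1000.0, tolerance: float = 1.0
) -> float:
    """Boundary length of the simplified 0.5-level contour, in um.

    The raw marching-squares contour overestimates smooth boundaries by
    ~6% (staircase effect), so each closed contour is simplified to a
    near-minimum-length polygon (Douglas-Peucker, ``tolerance`` px) before
    measuring.  The contour is first rolled to start at its vertex farthest
    from the contour centroid so genuine corners anchor the simplification
    and are not cut.  Digital disks and squares are then recovered within
    ~0.5%.  Tiny contours (< 9 vertices) are measured raw.  With the
    default ``pixel_size`` of 1000 nm the value is numerically in px.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        closed = bool(np.allclose(contour[0], contour[-1]))
        if tolerance > 0 and closed and len(contour) > 8:
            pts = contour[:-1]
            far = int(np.argmax(((pts - pts.mean(axis=0)) ** 2).sum(axis=1)))
            pts = np.roll(pts, -far, axis=0)
            contour = measure.approximate_polygon(
                np.vstack([pts, pts[:1]]), tolerance
            )
        total += float(np.hypot(*np.diff(contour, axis=0).T).sum())
    return total * pixel_size / 1000.0


def describe_region(mask: np.ndarray, pixel_size: float) -> ShapeDescriptors:
    """All descriptors of one region (``pixel_size`` in nm)."""
    area = region_area(mask, pixel_size)
    perim = perimeter_estimate(mask, pixel_size)
    ell = fit_ellipse(mask)
    major_um = ell.major_axis * pixel_size / 1000.0
    return ShapeDescriptors(
        area_um2=area,
        perimeter_um=perim,
        aspect_ratio=ell.aspect_ratio,
        circularity=circularity(area, perim),
        roundness=roundness(area, major_um),
        ellipse=ell,
    )
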