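"""FA filtering and edge-distance analysis against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nanofa import (
    FAFilterParams,
    FARecord,
    build_distance_frame,
    fa_edge_distance,
    filter_fa_candidates,
    normalise_distance,
)
from conftest import raster_disk


def make_record(ar: float, area: float) -> FARecord:
    return FARecord(
        cell_id=0,
        fa_id=0,
        mask=None,
        area_um2=area,
        ellipse=None,
        aspect_ratio=ar,
        centroid=(0.0, 0.0),
    )


def bruteforce_edge_distance(mask: np.ndarray, pixel: tuple[int, int]) -> float:
    """Min distance from a mask pixel to any background pixel, px."""
    bg = np.argwhere(~mask)
    return float(np.sqrt(((bg - np.array(pixel)) ** 2).sum(axis=1)).min())


# ------------------------------------------------------------------ filtering

@pytest.mark.parametrize(
    "ar,area,kept,reason",
    [
        (1.5, 0.2, False, "too_round"),  # boundary AR rejected (inclusive)
        (8.5, 0.2, False, "too_elongated"),
        (3.0, 0.04, False, "too_small"),
        (3.0, 0.05, True, None),  # boundary area accepted
        (1.51, 0.2, True, None),
        (9.0, 0.01, False, "too_elongated+too_small"),
    ],
)
def test_filter_rules(ar, area, kept, reason):
    accepted, log = filter_fa_candidates([make_record(ar, area)])
    assert (len(accepted) == 1) is kept
    if not kept:
        assert log == [(0, reason)]


def test_filter_count_conservation(rng):
    regions = [
        make_record(float(rng.uniform(0.5, 10)), float(rng.uniform(0.01, 0.5)))
        for _ in range(100)
    ]
    accepted, log = filter_fa_candidates(regions)
    assert len(accepted) + len(log) == len(regions)


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FAFilterParams(ar_min_exclusive=9.0, ar_max_exclusive=1.5)
    with pytest.raises(ValueError):
        FAFilterParams(min_area=0.0)


# -------------------------------------------------------------- distance maps

def test_distance_frame_disk():
    frame = build_distance_frame(raster_disk(100), pixel_size=34.0)
    assert frame.normalising_radius == pytest.approx(3.40, abs=0.034)


def test_distance_frame_rectangle_half_short_side():
    mask = np.zeros((120, 60), dtype=bool)
    mask[10:110, 10:50] = True  # 100 x 40
    frame = build_distance_frame(mask, pixel_size=1000.0)
    assert frame.normalising_radius == pytest.approx(20.0, abs=1.0)


def test_distance_frame_empty_errors():
    with pytest.raises(ValueError):
        build_distance_frame(np.zeros((4, 4), bool), 34.0)


def test_distance_map_equals_bruteforce(rng):
    """EDT values match the brute-force nearest-background search on
    random blob masks."""
    from scipy import ndimage

    for _ in range(10):
        blob = rng.random((48, 48)) > 0.6
        mask = ndimage.binary_dilation(blob, iterations=2)
        mask[0], mask[-1], mask[:, 0], mask[:, -1] = False, False, False, False
        if not mask.any():
            continue
        frame = build_distance_frame(mask, pixel_size=1000.0)
        inside = np.argwhere(mask)
        bg = np.argwhere(~mask)
        d_brute = cdist(inside, bg).min(axis=1)
        np.testing.assert_allclose(
            frame.distance_map[tuple(inside.T)], d_brute, rtol=1e-12
        )


# ------------------------------------------------------------- FA distances

def test_fa_distance_disk_centre_and_boundary():
    mask = raster_disk(100)
    frame = build_distance_frame(mask, pixel_size=34.0)
    c = (mask.shape[0] - 1) / 2
    d, outside = fa_edge_distance((c, c), frame)
    assert not outside
    assert d == pytest.approx(3.40, abs=0.05)
    d_edge, outside = fa_edge_distance((c, c + 99), frame)
    assert not outside
    assert d_edge <= 2 * 0.034  # within two pixels of zero


def test_fa_distance_outside_mask_flagged():
    frame = build_distance_frame(raster_disk(30), pixel_size=34.0)
    d, outside = fa_edge_distance((0.0, 0.0), frame)
    assert d == 0.0 and outside


def test_fa_distance_matches_bruteforce(rng):
    mask = raster_disk(25)
    frame = build_distance_frame(mask, pixel_size=1000.0)
    inside = np.argwhere(mask)
    for idx in rng.choice(len(inside), 20, replace=False):
        r, c = inside[idx]
        d, _ = fa_edge_distance((float(r), float(c)), frame)
        assert d == pytest.approx(
            bruteforce_edge_distance(mask, (r, c)), rel=1e-12
        )


# -------------------------------------------------------------- normalisation

def test_normalisation_disk_identities():
    mask = raster_disk(100)
    frame = build_distance_frame(mask, pixel_size=34.0)
    area = mask.sum() * 0.034**2
    c = (mask.shape[0] - 1) / 2
    d, _ = fa_edge_distance((c, c), frame)
    nmr, nar = normalise_distance(d, frame, area)
    assert nmr == pytest.approx(1.0, abs=0.02)
    # for a disk the equivalent radius equals the radius
    assert nar == pytest.approx(nmr, rel=0.02)
    nmr_edge, _ = normalise_distance(0.0, frame, area)[0], None
    assert nmr_edge == 0.0


def test_normalisation_zero_denominator_errors():
    frame = build_distance_frame(raster_disk(10), pixel_size=34.0)
    with pytest.raises(ValueError):
        normalise_distance(1.0, frame, 0.0)


def test_norm_maxr_bounded_by_one(rng):
    """The map maximum bounds every (bilinearly interpolated) value."""
    from scipy import ndimage

    blob = rng.random((40, 40)) > 0.55
    mask = ndimage.binary_dilation(blob, iterations=2)
    mask[0], mask[-1], mask[:, 0], mask[:, -1] = False, False, False, False
    frame = build_distance_frame(mask, pixel_size=34.0)
    inside = np.argwhere(mask)
    for idx in rng.choice(len(inside), 50, replace=True):
        r, c = inside[idx] + rng.uniform(-0.49, 0.49, 2)
        d, outside = fa_edge_distance((float(r), float(c)), frame)
        if not outside:
            nmr, _ = normalise_distance(d, frame, 1.0)
            assert nmr <= 1.0 + 1e-12


def test_scale_invariance_of_normalised_distances():
    """Doubling resolution while halving pixel size leaves the normalised
    distances unchanged within 2%."""
    m1 = raster_disk(50)
    m2 = raster_disk(100)
    f1 = build_distance_frame(m1, pixel_size=68.0)
    f2 = build_distance_frame(m2, pixel_size=34.0)
    c1 = (m1.shape[0] - 1) / 2
    c2 = (m2.shape[0] - 1) / 2
    area1 = m1.sum() * 0.068**2
    area2 = m2.sum() * 0.034**2
    for frac in (0.0, 0.3, 0.6, 0.9):
        d1, _ = fa_edge_distance((c1, c1 + frac * 50), f1)
        d2, _ = fa_edge_distance((c2, c2 + frac * 100), f2)
        n1 = normalise_distance(d1, f1, area1)
        n2 = normalise_distance(d2, f2, area2)
        assert n1[0] == pytest.approx(n2[0], abs=0.02)
        assert n1[1] == pytest.approx(n2[1], abs=0.02)
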