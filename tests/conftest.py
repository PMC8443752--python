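import numpy as np
import pytest

from nanofa import CellShapeParams, PlantedFA, SceneSpec


def raster_disk(radius: int, pad: int = 5) -> np.ndarray:
    """Binary disk: pixel centres within `radius` of the centre."""
    n = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def raster_ellipse(a: float, b: float, angle: float = 0.0, pad: int = 5) -> np.ndarray:
    """Binary ellipse with semi-axes (a, b), rotated by `angle` rad."""
    half = int(np.ceil(max(a, b))) + pad
    n = 2 * half + 1
    rr, cc = np.mgrid[0:n, 0:n]
    y = -(rr - half).astype(float)
    x = (cc - half).astype(float)
    u = x * np.cos(angle) + y * np.sin(angle)
    v = -x * np.sin(angle) + y * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def standard_scene(
    seed: int = 0,
    fa_list: tuple = (),
    perturb: tuple = (),
    **overrides,
) -> SceneSpec:
    """A noiseless 512x512 scene with a cell large enough to pass the
    default 100 um^2 minimum (radius 220 px at 34 nm/px ~ 176 um^2)."""
    kwargs = dict(
        image_shape=(512, 512),
        cell_shape=CellShapeParams(
            base_radius=220, perturb_amplitudes=perturb, seed=seed
        ),
        fa_list=fa_list,
        seed=seed,
    )
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


def default_fas() -> tuple:
    """Four planted adhesions: two filter-passing, one too round, one too
    small (the tiny one is also erased by the median filter — rejected
    either way)."""
    return (
        PlantedFA(centre=(256, 256), major_axis=30, minor_axis=10),
        PlantedFA(centre=(180, 200), major_axis=40, minor_axis=12, orientation=0.7),
        PlantedFA(centre=(330, 300), major_axis=12, minor_axis=10),
        PlantedFA(centre=(200, 330), major_axis=6, minor_axis=3),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
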