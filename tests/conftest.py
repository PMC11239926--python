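import numpy as np
import pytest

from aneumorph import (
    extract_isosurface,
    make_sphere_mesh,
    make_vessel_phantom,
    smooth_non_shrinking,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Sphere-on-tube phantom: dome radius 3 mm, isotropic 0.3 mm spacing."""
    return make_vessel_phantom(dome_radius_mm=3.0, spacing=0.3, case_id="phantom")


@pytest.fixture(scope="session")
def long_phantom():
    """Phantom with a 50 mm vessel so the surface exceeds 5000 vertices."""
    return make_vessel_phantom(
        dome_radius_mm=3.0, spacing=0.3, tube_length_mm=50.0, case_id="long"
    )


@pytest.fixture(scope="session")
def long_phantom_smoothed(long_phantom):
    volume, truth = long_phantom
    return smooth_non_shrinking(extract_isosurface(volume)), truth


@pytest.fixture(scope="session")
def ball_volume():
    """Digitized ball, radius 5 mm at 0.25 mm spacing, analytic geometry known."""
    from aneumorph.io_formats import BinaryVolume

    spacing = 0.25
    r = 5.0
    n = int(2 * (r + 2 * spacing) / spacing)
    coords = (np.arange(n) - (n - 1) / 2) * spacing
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    mask = (x**2 + y**2 + z**2 <= r**2).astype(np.uint8)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = coords[0]
    return BinaryVolume(voxels=mask, affine=affine), r


@pytest.fixture(scope="session")
def icosphere5():
    return make_sphere_mesh(5.0, subdivisions=3)


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test stream."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()) % 2**31)
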