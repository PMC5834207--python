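import numpy as np
import pytest

from cmtsim.geometry import (CellSurface, ShapeSpec, build_shape,
                             standard_shape_spec)


@pytest.fixture(scope="session")
def cube_surface():
    """Sharp cube at default resolution (the standard study shape)."""
    return CellSurface(build_shape(standard_shape_spec("cube", "sharp")))


@pytest.fixture(scope="session")
def coarse_sphere_surface():
    """Sphere-like rounded box (radius = half side), coarse mesh."""
    spec = ShapeSpec("rounded_box", (6.0, 6.0, 6.0), corner_radius=3.0,
                     mesh_resolution=0.5)
    return CellSurface(build_shape(spec))


@pytest.fixture(scope="session")
def ellipsoid_surface():
    return CellSurface(build_shape(standard_shape_spec("ellipsoid")))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
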