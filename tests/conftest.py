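import numpy as np
import pytest

from reefmetrics import fixture_table1, sample_surface
from reefmetrics.synth_meshes import ShapeSpec, generate


@pytest.fixture(scope="session")
def cube():
    return generate(ShapeSpec("cube"))


@pytest.fixture(scope="session")
def menger1():
    return generate(ShapeSpec("menger", {"level": 1}))


@pytest.fixture(scope="session")
def menger2():
    return generate(ShapeSpec("menger", {"level": 2}))


@pytest.fixture(scope="session")
def table1():
    return fixture_table1()


@pytest.fixture(scope="session")
def cube_sample(cube):
    # 600 points on the unit cube: exactly 50 per triangle, 100 per square face
    return sample_surface(cube, resolution=100, seed=0)


def planar_grid_sample(n_side=64):
    """A flat n x n grid in the z=0 plane with +z normals."""
    from reefmetrics import PointSample

    g = np.linspace(0.0, 1.0, n_side)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n_side * n_side)])
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return PointSample(points=pts, normals=normals, resolution=None, seed=0)
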