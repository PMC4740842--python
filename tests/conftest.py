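"""Shared synthetic fixtures; everything is generated, nothing is loaded."""

import numpy as np
import pytest

from guideforge import fixtures as fx


@pytest.fixture(scope="session")
def sphere():
    """Unit icosphere, subdivision 3 (1280 faces)."""
    return fx.make_sphere(1.0, 3)


@pytest.fixture(scope="session")
def sphere_coarse():
    return fx.make_sphere(1.0, 2)


@pytest.fixture(scope="session")
def ridge():
    """40 mm sinusoidal ridge patch, 41x41 grid."""
    return fx.make_ridge(40.0, 4.0, 41)


@pytest.fixture(scope="session")
def ridge_small():
    return fx.make_ridge(40.0, 4.0, 25)


@pytest.fixture(scope="session")
def hemisphere():
    return fx.make_hemisphere(1.0, 2)


@pytest.fixture(scope="session")
def equator_control_points():
    """Four control points on the unit sphere's equator."""
    return np.array(
        [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, -1.0, 0.0]]
    )


TETRA_ASCII = """solid tetra
facet normal 0 0 -1
  outer loop
    vertex 0 0 0
    vertex 0 1 0
    vertex 1 0 0
  endloop
endfacet
facet normal 0 -1 0
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 0 1
  endloop
endfacet
facet normal -1 0 0
  outer loop
    vertex 0 0 0
    vertex 0 0 1
    vertex 0 1 0
  endloop
endfacet
facet normal 0.577 0.577 0.577
  outer loop
    vertex 1 0 0
    vertex 0 1 0
    vertex 0 0 1
  endloop
endfacet
endsolid tetra
"""


@pytest.fixture()
def tetra_stl(tmp_path):
    path = tmp_path / "tetra.stl"
    path.write_text(TETRA_ASCII)
    return path
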