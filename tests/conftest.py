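"""Shared fixtures: the seeded reference world and hand-built two-box oceans."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from docpump import synthetic_ocean as so


@pytest.fixture(scope="session")
def scenario() -> so.Scenario:
    """The default 36-lat x 3-basin x 24-layer reference world."""
    return so.make_scenario(seed=0)


@pytest.fixture(scope="session")
def mapping_scenario() -> so.Scenario:
    """A finer world (64 x 6 x 24, ~9200 boxes) for gap-filling benchmarks.

    The milder nitrate uptake keeps the finer-resolved gyres positive; the
    DOC field and predictor structure are otherwise the same physics.
    """
    return so.make_scenario(seed=0, n_lat=64, n_lon=6, uptake_scale=3.5)


def make_two_box_grid() -> so.Grid:
    """One column, two layers (36 m / 74 m interfaces), densities chosen so
    both boxes have exactly equal mass."""
    rho1 = 1025.0
    rho2 = rho1 * 36.0 / 38.0
    return so.Grid(
        lat_edges=np.array([-10.0, 10.0]),
        basins=("Atlantic",),
        layer_bottoms=np.array([36.0, 74.0]),
        density=np.array([rho1, rho2]),
        euphotic_depth=np.array([36.0]),
    )


def make_two_box_transport(a: float) -> so.TransportMatrix:
    """Symmetric exchange at rate ``a`` yr⁻¹ between two equal-mass boxes."""
    grid = make_two_box_grid()
    T = sp.csr_matrix(np.array([[-a, a], [a, -a]]))
    return so.TransportMatrix(T=T, grid=grid, params={"exchange": a})


@pytest.fixture
def two_box():
    return make_two_box_grid(), make_two_box_transport(2.0)
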