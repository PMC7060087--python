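import numpy as np
import pytest

from oxchip.geometry import DeviceSpec, Material, MaterialGrid, build_cross_section
from oxchip.transport import BoundarySet, solve_steady


@pytest.fixture(scope="session")
def default_spec():
    return DeviceSpec()


@pytest.fixture(scope="session")
def coarse_grid(default_spec):
    """50 um cross-section grid, shared to keep the suite fast."""
    return build_cross_section(default_spec, 50e-6)


@pytest.fixture(scope="session")
def steady_h0(coarse_grid):
    return solve_steady(coarse_grid, BoundarySet(0.0, 0.0))


@pytest.fixture(scope="session")
def steady_gradient(coarse_grid):
    return solve_steady(coarse_grid, BoundarySet(0.0, 21.0))


def make_slab_strip(slabs, res=25e-6, gas_pad=0.2e-3, height=50e-6):
    """1-D horizontal strip [gas | slab_1 | ... | slab_n | gas] centered at
    x = 0 so the two gas blocks take the left/right supply values.

    ``slabs``: list of (Material, thickness_m).  Returns (grid, x_centers,
    interface_positions) with interfaces including both gas faces.
    """
    widths = [gas_pad] + [t for _, t in slabs] + [gas_pad]
    breaks = np.concatenate([[0.0], np.cumsum(widths)])
    breaks -= breaks[-1] / 2  # center so gas blocks straddle x = 0
    edges = [breaks[0]]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((hi - lo) / res - 1e-9)))
        edges.extend(np.linspace(lo, hi, n + 1)[1:])
    x_edges = np.asarray(edges)
    z_edges = np.array([0.0, height])
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    mat = np.full((1, len(xc)), int(Material.GAS), dtype=np.int8)
    for (m, _), lo, hi in zip(slabs, breaks[1:-2], breaks[2:-1]):
        mat[0, (xc >= lo) & (xc < hi)] = int(m)
    grid = MaterialGrid(
        spec=DeviceSpec(), x_edges=x_edges, z_edges=z_edges, material=mat
    )
    return grid, xc, breaks[1:-1]
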