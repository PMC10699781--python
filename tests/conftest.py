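"""Shared fixtures: reference simulation runs reused across tests.

The 2D reference runs are the expensive part of the suite; they are
computed once per session at the study resolutions (wild type at
64 x 128, the perturbation modes at 48 x 96) and shared by every test
that inspects them.
"""

import numpy as np
import pytest

from gastruflow import DiskGrid, default_params, run_2d


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def wild_fine(params):
    """Wild-type run at the full study resolution (64 x 128)."""
    return run_2d("wild_type", params, grid=DiskGrid(64, 128), output_every=0.5)


@pytest.fixture(scope="session")
def wild_mid(params):
    return run_2d("wild_type", params, grid=DiskGrid(48, 96), output_every=0.5)


@pytest.fixture(scope="session")
def reptilian_mid(params):
    return run_2d("reptilian", params, grid=DiskGrid(48, 96), output_every=0.5)


@pytest.fixture(scope="session")
def teleost_mid(params):
    return run_2d("teleost", params, grid=DiskGrid(48, 96), output_every=0.5)


def axis_distance(grid):
    """Distance of every node from the AP axis line."""
    x, y = grid.mesh_xy()
    ax, ay = grid.ap_unit()
    return np.abs(x * ay - y * ax)
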