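"""Shared fixtures: houses and full kerma-grid sets (computed once)."""

import numpy as np
import pytest

from isomap import build_house, compute_kerma_grids, occupancy_from_hours
from isomap.isodose import STANDARD_HOURS
from isomap.transport import TransportConfig


@pytest.fixture(scope="session")
def wooden_house():
    return build_house("wooden")


@pytest.fixture(scope="session")
def brick_house():
    return build_house("brick")


@pytest.fixture(scope="session")
def wooden_grids(wooden_house):
    """All 33 kerma grids (11 points x 3 depths) at default quadrature."""
    return compute_kerma_grids(wooden_house, config=TransportConfig())


@pytest.fixture(scope="session")
def brick_grids(brick_house):
    return compute_kerma_grids(brick_house, config=TransportConfig())


@pytest.fixture()
def standard_occupancy(wooden_house):
    return occupancy_from_hours(STANDARD_HOURS, wooden_house)


def synthetic_kerma_grid(point, depth, values, far_field, variant="synthetic"):
    """Helper for unit tests: a KermaGrid with prescribed values."""
    from isomap.transport import KermaGrid
    return KermaGrid(observation_point=point, source_depth_cm=depth,
                     values=np.asarray(values, dtype=float),
                     far_field=far_field, house_variant=variant)
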