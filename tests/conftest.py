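"""Shared fixtures: small grids and phantoms sized for fast solves."""

from __future__ import annotations

import numpy as np
import pytest

from b1eval import (
    EPMap,
    PhantomSpec,
    VoxelGrid,
    build_mask,
    build_phantom,
)


@pytest.fixture(scope="session")
def cube_grid() -> VoxelGrid:
    """Small full-cube grid (24^3, 2 mm) for solver unit tests."""
    return VoxelGrid(shape=(24, 24, 24), spacing_h=2e-3)


@pytest.fixture(scope="session")
def cube_mask(cube_grid):
    return build_mask(np.ones(cube_grid.shape, bool))


@pytest.fixture(scope="session")
def homogeneous_ep(cube_grid) -> EPMap:
    """Saline-like homogeneous medium: sigma 0.5 S/m, eps_r 78."""
    return EPMap(
        sigma=np.full(cube_grid.shape, 0.5),
        eps_r=np.full(cube_grid.shape, 78.0),
    )


@pytest.fixture(scope="session")
def sphere_grid() -> VoxelGrid:
    """32^3 grid at 5 mm spacing; fits a 75 mm-radius phantom."""
    return VoxelGrid(shape=(32, 32, 32), spacing_h=5e-3)


@pytest.fixture(scope="session")
def two_compartment(sphere_grid):
    """Scaled two-compartment sphere (radius 75 mm, inner 37.5 mm)."""
    spec = PhantomSpec(
        kind="two_compartment_sphere",
        radius_mm=75.0,
        inner_radius_mm=37.5,
        inner_offset_mm=18.75,
    )
    ep, mask = build_phantom(spec, sphere_grid)
    return ep, mask
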