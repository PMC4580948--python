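"""Shared fixtures: reduced-scale cytoskeletons and field libraries.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive pieces (polymer growth, Stokes factorization) shared.
"""

import numpy as np
import pytest

from oostream.fields import CoarseGrid, coarse_grain
from oostream.geometry import geometry_preset
from oostream.nucleation import SeedingDensityParams, sample_seeds
from oostream.polymer import PolymerParams, grow_cytoskeleton
from oostream.transport import build_field_library, scenario_presets


@pytest.fixture(scope="session")
def geom1():
    return geometry_preset("geometry1")


@pytest.fixture(scope="session")
def geom2():
    return geometry_preset("geometry2")


@pytest.fixture(scope="session")
def small_seeds(geom1):
    """Reduced wild-type seed set (N_A = 800)."""
    return sample_seeds(geom1, SeedingDensityParams(N_A=800), rng=11)


@pytest.fixture(scope="session")
def small_realization(geom1, small_seeds):
    """Reduced wild-type cytoskeleton (~1800 polymers)."""
    return grow_cytoskeleton(small_seeds, PolymerParams(), rng=12)


@pytest.fixture(scope="session")
def small_motor(geom1, small_realization):
    """Motor-velocity field of the reduced realization on a coarse grid."""
    return coarse_grain(small_realization, CoarseGrid(geom1, dG=0.1))


@pytest.fixture(scope="session")
def fixture_library(geom1):
    """Tiny (v_m, u) pair library for transport smoke tests.

    Coarse everything: dG = 0.1 transport and motor grids, N_A = 500,
    two pairs, flows solved on the same coarse mesh.
    """
    grid = CoarseGrid(geom1, dG=0.1)
    return build_field_library(
        geom1,
        scenario_presets()["oskar-wt"],
        n_pairs=2,
        rng=21,
        grid=grid,
        N_A=500,
        motor_dG=0.1,
    )
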