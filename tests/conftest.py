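"""Shared fixtures: phantoms and lead fields at two problem sizes.

The small 24^3 phantom keeps unit/integration tests fast; the 40^3 desk-scale
phantom (the package default) backs the end-to-end acceptance checks.  Both
are built once per session.
"""

import numpy as np
import pytest

from ecgloc.leadfield import build_lfm, select_source_points
from ecgloc.phantom import PhantomSpec, default_electrodes, make_block_torso
from ecgloc.spfd import ForwardSolver, SolverConfig

SMALL_SPEC = PhantomSpec(
    dims=(24, 24, 24), body_margin=3, heart_center=(12, 12, 12),
    heart_half=5, blood_half=2, lung_halfwidth=5, lung_thickness=3,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_model(small_spec):
    return make_block_torso(small_spec)


@pytest.fixture(scope="session")
def small_electrodes(small_spec):
    return default_electrodes(small_spec)


@pytest.fixture(scope="session")
def small_solver(small_model):
    return ForwardSolver(small_model, SolverConfig())


@pytest.fixture(scope="session")
def small_lfm(small_model, small_electrodes, small_solver):
    grid = select_source_points(small_model)
    return build_lfm(small_model, small_electrodes, grid, solver=small_solver)


@pytest.fixture(scope="session")
def desk_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def desk_model(desk_spec):
    return make_block_torso(desk_spec)


@pytest.fixture(scope="session")
def desk_solver(desk_model):
    return ForwardSolver(desk_model, SolverConfig())


@pytest.fixture(scope="session")
def desk_lfm(desk_model, desk_spec, desk_solver):
    grid = select_source_points(desk_model)
    return build_lfm(desk_model, default_electrodes(desk_spec), grid,
                     solver=desk_solver)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
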