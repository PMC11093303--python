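"""Shared fixtures: the bundled baseline configuration, its geometry and
mesh, and the solved quasistatic case (session-scoped; the solves are
cheap but reused by many tests)."""

import pytest

import plexusfem as pf
from plexusfem.study import solve_case


@pytest.fixture(scope="session")
def config():
    return pf.load_config()


@pytest.fixture(scope="session")
def geometry(config):
    return config.build_geometry()


@pytest.fixture(scope="session")
def mesh(config, geometry):
    return pf.generate_mesh(geometry, config.mesh.h_max, config.mesh.h_min)


@pytest.fixture(scope="session")
def case1_solution(config, geometry, mesh):
    sol, stress = solve_case(geometry, mesh, config.load_cases["case1"],
                             config.integration_scheme,
                             config.guided_edge_fraction)
    return sol, stress
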