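"""Shared fixtures; the expensive CFD solutions are session-scoped so the
Poiseuille benchmark, the symmetric bifurcation and the stented reference
sample are each solved once and reused across test modules."""

import pytest

from bifurcbench.examples import kio_example
from bifurcbench.flow import compute_shear_rate_field, solve_steady_flow
from bifurcbench.geometry import BifurcationParams, build_bifurcation, make_channel
from bifurcbench.meshing import MeshConfig, generate_mesh

CHANNEL_WIDTH = 5.5  # mm
CHANNEL_LENGTH = 15.0  # mm
U_MEAN = 0.14  # m/s


@pytest.fixture(scope="session")
def poiseuille_solution():
    """Plane-Poiseuille channel solved at h_max = width/20."""
    geom = make_channel(CHANNEL_WIDTH, CHANNEL_LENGTH)
    mesh = generate_mesh(geom, None, MeshConfig(h_max=CHANNEL_WIDTH / 20,
                                                near_wall_factor=0.5))
    field = solve_steady_flow(mesh)
    return geom, mesh, field


@pytest.fixture(scope="session")
def symmetric_bifurcation_solution():
    """Strut-free symmetric bifurcation (equal branches, equal angles)."""
    geom = build_bifurcation(BifurcationParams(L_prox=8.0, L_mb=6.0, L_sb=6.0))
    mesh = generate_mesh(geom, None, MeshConfig(h_max=0.34, near_wall_factor=0.6))
    field = solve_steady_flow(mesh)
    return geom, mesh, field


@pytest.fixture(scope="session")
def kio_solution():
    """The shipped stented KIO reference sample, meshed and solved."""
    geom, layout, cfg = kio_example()
    mesh = generate_mesh(geom, layout, cfg)
    field = solve_steady_flow(mesh)
    shear = compute_shear_rate_field(field)
    return geom, layout, mesh, field, shear
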