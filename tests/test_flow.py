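"""Navier-Stokes solver oracles: Poiseuille, symmetry, Stokes limit,
conservation, and the shear-rate recovery."""

import numpy as np
import pytest

from bifurcbench.fem import P2Space
from bifurcbench.flow import (
    FlowConditions,
    FlowField,
    FluidProperties,
    SolverError,
    SolverOptions,
    compute_shear_rate_field,
    solve_steady_flow,
)
from bifurcbench.geometry import make_channel
from bifurcbench.meshing import MeshConfig, generate_mesh

U = 0.14
H_MM = 5.5


def _small_channel_mesh():
    return generate_mesh(make_channel(H_MM, 10.0), None,
                         MeshConfig(h_max=0.45, near_wall_factor=0.6))


class TestPoiseuille:
    def test_centerline_velocity_is_three_halves_mean(self, poiseuille_solution):
        _, _, field = poiseuille_solution
        u = field.velocity_at(np.array([[7.5, 0.0]]))[0]
        assert u[0] == pytest.approx(1.5 * U, rel=0.01)
        assert abs(u[1]) < 1e-6

    def test_wall_shear_rate_matches_6u_over_h(self, poiseuille_solution):
        _, _, field = poiseuille_solution
        shear = compute_shear_rate_field(field)
        c = shear.centroids_mm
        near_wall = (np.abs(np.abs(c[:, 1]) - H_MM / 2) < 0.15) & \
                    (c[:, 0] > 4) & (c[:, 0] < 11)
        gamma_wall = shear.shear_rate[near_wall].max()
        assert gamma_wall == pytest.approx(6 * U / (H_MM * 1e-3), rel=0.05)

    def test_no_slip_on_walls(self, poiseuille_solution):
        _, mesh, field = poiseuille_solution
        space = field.space
        wall_nodes = set()
        for i, j, t in mesh.boundary_edges:
            if t == "wall":
                wall_nodes |= {i, j, space.edge_midpoint_index(i, j)}
        vel = field.velocity[sorted(wall_nodes)]
        assert np.abs(vel).max() < 1e-12


class TestConservationAndLimits:
    def test_mass_conserved_to_solver_precision(self, poiseuille_solution):
        *_, field = poiseuille_solution
        assert field.net_flux_imbalance() < 1e-10

    def test_vanishing_inlet_velocity_gives_vanishing_field(self):
        mesh = _small_channel_mesh()
        field = solve_steady_flow(
            mesh, conds=FlowConditions(inlet_mean_velocity=1e-9)
        )
        assert np.abs(field.velocity).max() < 2e-9
        assert np.abs(field.pressure).max() < 1e-5

    def test_stokes_limit_matches_creeping_flow(self):
        # at U * 1e-3 the nonlinear solution coincides with a creeping-flow
        # (negligible-inertia) solve to 0.1%
        mesh = _small_channel_mesh()
        conds = FlowConditions(inlet_mean_velocity=U * 1e-3)
        full = solve_steady_flow(mesh, conds=conds)
        creeping = solve_steady_flow(
            mesh, FluidProperties(density=1e-9), conds
        )
        scale = np.abs(full.velocity).max()
        assert np.abs(full.velocity - creeping.velocity).max() < 1e-3 * scale

    def test_reynolds_precondition_enforced(self):
        mesh = _small_channel_mesh()
        with pytest.raises(SolverError, match="Reynolds"):
            solve_steady_flow(mesh, conds=FlowConditions(inlet_mean_velocity=5.0))

    def test_nonconvergence_raises_with_residual_history(self):
        mesh = _small_channel_mesh()
        with pytest.raises(SolverError) as err:
            solve_steady_flow(
                mesh,
                opts=SolverOptions(tol=0.0, max_iter=2, use_newton=False),
            )
        assert len(err.value.residuals) == 2


class TestSymmetricBifurcation:
    def test_outlet_flux_split_is_even(self, symmetric_bifurcation_solution):
        *_, field = symmetric_bifurcation_solution
        q_mb = field.boundary_flux("outlet_mb")
        q_sb = field.boundary_flux("outlet_sb")
        assert q_mb / (q_mb + q_sb) == pytest.approx(0.5, abs=0.005)

    def test_mass_conserved_on_bifurcation(self, symmetric_bifurcation_solution):
        *_, field = symmetric_bifurcation_solution
        assert field.net_flux_imbalance() < 1e-10


class TestShearRecovery:
    def _manual_field(self, velocity_fn):
        mesh = generate_mesh(make_channel(2.0, 4.0), None,
                             MeshConfig(h_max=0.19, near_wall_factor=1.0))
        space = P2Space.build(mesh.points, mesh.triangles)
        coords = space.p2_coords() * 1e-3  # m
        vel = velocity_fn(coords)
        return FlowField(mesh, space, vel, np.zeros(space.n_vertices), [0.0],
                         True, FluidProperties(), FlowConditions())

    def test_uniform_translation_has_zero_shear(self):
        field = self._manual_field(
            lambda c: np.tile([0.3, 0.1], (len(c), 1))
        )
        shear = compute_shear_rate_field(field)
        assert np.abs(shear.shear_rate).max() < 1e-10

    def test_pure_linear_shear_recovered_exactly(self):
        k = 123.0  # 1/s
        field = self._manual_field(
            lambda c: np.column_stack([k * c[:, 1], np.zeros(len(c))])
        )
        shear = compute_shear_rate_field(field)
        assert shear.shear_rate == pytest.approx(k, rel=1e-10)

    def test_unconverged_field_rejected(self):
        field = self._manual_field(lambda c: np.zeros((len(c), 2)))
        field.converged = False
        with pytest.raises(SolverError):
            compute_shear_rate_field(field)


class TestNodeReordering:
    def test_solution_invariant_under_node_permutation(self):
        mesh = _small_channel_mesh()
        base = solve_steady_flow(mesh)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mesh.points))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        from bifurcbench.meshing import Mesh

        mesh2 = Mesh(
            mesh.points[perm],
            inv[mesh.triangles],
            [(int(inv[i]), int(inv[j]), t) for i, j, t in mesh.boundary_edges],
            mesh.config,
        )
        other = solve_steady_flow(mesh2)
        # mesh2 vertex m is mesh vertex perm[m]; compare at vertex nodes
        nv = len(mesh.points)
        diff = base.velocity[:nv][perm] - other.velocity[:nv]
        assert np.abs(diff).max() < 1e-6
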