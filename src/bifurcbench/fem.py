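"""Taylor-Hood (P2 velocity / P1 pressure) finite elements on triangles.

Vectorized assembly of the operators needed for steady incompressible
Navier-Stokes: scalar P2 stiffness and mass, the Picard convection operator
C(w), the Newton reaction blocks weighted by the current velocity gradient,
and the P1-P2 divergence coupling.  Geometry enters in metres; the mesh module
stores millimetres, conversion happens in the flow solver.

DOF layout used throughout: velocity x-components at P2 nodes [0, n2),
y-components [n2, 2*n2), pressure at vertices [2*n2, 2*n2 + nv).  P2 node k is
vertex k for k < nv and edge (k - nv) midpoint otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["P2Space", "Quadrature", "assemble_stokes_blocks", "assemble_convection",
           "assemble_newton_blocks", "velocity_gradient_at_centroids"]


# Dunavant 7-point rule, degree 5, barycentric points and weights (sum 1)
_A1, _B1 = 0.059715871789770, 0.470142064105115
_A2, _B2 = 0.797426985353087, 0.101286507323456
QPOINTS = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [_A1, _B1, _B1],
        [_B1, _A1, _B1],
        [_B1, _B1, _A1],
        [_A2, _B2, _B2],
        [_B2, _A2, _B2],
        [_B2, _B2, _A2],
    ]
)
QWEIGHTS = np.array(
    [0.225, 0.132394152788506, 0.132394152788506, 0.132394152788506,
     0.125939180544827, 0.125939180544827, 0.125939180544827]
)


def _p2_shape(lam: np.ndarray):
    """P2 shape values and barycentric gradients at barycentric points.

    Returns (N, dN) with N of shape (q, 6) and dN of shape (q, 6, 3) where the
    last axis is d/dlambda_i.
    """
    l1, l2, l3 = lam[:, 0], lam[:, 1], lam[:, 2]
    N = np.stack(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ],
        axis=1,
    )
    z = np.zeros_like(l1)
    dN = np.stack(
        [
            np.stack([4 * l1 - 1, z, z], axis=1),
            np.stack([z, 4 * l2 - 1, z], axis=1),
            np.stack([z, z, 4 * l3 - 1], axis=1),
            np.stack([4 * l2, 4 * l1, z], axis=1),
            np.stack([z, 4 * l3, 4 * l2], axis=1),
            np.stack([4 * l3, z, 4 * l1], axis=1),
        ],
        axis=1,
    )
    return N, dN


N_Q, DN_Q = _p2_shape(QPOINTS)  # (7,6), (7,6,3)
P1_Q = QPOINTS.copy()  # P1 shape values are the barycentric coordinates
N_C, DN_C = _p2_shape(np.array([[1 / 3, 1 / 3, 1 / 3]]))  # centroid


@dataclass
class P2Space:
    """P2 connectivity for a triangle mesh: vertices + unique edge midpoints."""

    points: np.ndarray  # (nv, 2) vertex coords (any unit)
    triangles: np.ndarray  # (m, 3)
    edges: np.ndarray  # (ne, 2) sorted vertex pairs
    tri_edges: np.ndarray  # (m, 3) edge index of local edges (0-1, 1-2, 2-0)

    @classmethod
    def build(cls, points: np.ndarray, triangles: np.ndarray) -> "P2Space":
        tri = np.asarray(triangles, dtype=np.int64)
        pairs = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        pairs.sort(axis=1)
        edges, inv = np.unique(pairs, axis=0, return_inverse=True)
        tri_edges = inv.reshape(3, -1).T
        return cls(np.asarray(points, float), tri, edges, tri_edges)

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def n_p2(self) -> int:
        return len(self.points) + len(self.edges)

    def p2_dofs(self) -> np.ndarray:
        """(m, 6) P2 node index per element (3 vertices, 3 edge midpoints)."""
        return np.concatenate(
            [self.triangles, self.tri_edges + self.n_vertices], axis=1
        )

    def p2_coords(self) -> np.ndarray:
        """(n_p2, 2) coordinates of all P2 nodes."""
        mids = 0.5 * (self.points[self.edges[:, 0]] + self.points[self.edges[:, 1]])
        return np.concatenate([self.points, mids], axis=0)

    def edge_midpoint_index(self, a: int, b: int) -> int:
        """P2 node index of the midpoint of vertex pair (a, b)."""
        key = (min(a, b), max(a, b))
        idx = np.searchsorted(self.edges[:, 0], key[0])
        while idx < len(self.edges) and self.edges[idx, 0] == key[0]:
            if self.edges[idx, 1] == key[1]:
                return self.n_vertices + idx
            idx += 1
        raise KeyError(f"edge {key} not in mesh")


def _geometry(space: P2Space, scale: float):
    """Per-element Jacobian data; ``scale`` converts stored coords to metres."""
    pts = space.points * scale
    tri = space.triangles
    p1, p2, p3 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    J = np.stack([p2 - p1, p3 - p1], axis=1)  # (m,2,2) rows are edge vectors
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    if np.any(detJ <= 0):
        raise ValueError("mesh contains inverted or degenerate elements")
    area = 0.5 * detJ
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1]
    invJ[:, 0, 1] = -J[:, 0, 1]
    invJ[:, 1, 0] = -J[:, 1, 0]
    invJ[:, 1, 1] = J[:, 0, 0]
    invJ /= detJ[:, None, None]
    return area, invJ


def _phys_grads(invJ: np.ndarray, dN: np.ndarray) -> np.ndarray:
    """Physical P2 gradients, shape (m, q, 6, 2).

    Barycentric gradients are mapped through dlambda/dx: with lambda_1 =
    1 - xi - eta, d/dxi = d/dl2 - d/dl1, d/deta = d/dl3 - d/dl1, then
    d/dx = invJ^T d/dxi.
    """
    dref = np.stack([dN[..., 1] - dN[..., 0], dN[..., 2] - dN[..., 0]], axis=-1)
    # (q,6,2) x (m,2,2) -> (m,q,6,2): grad_x f = J^{-1} grad_ref f
    return np.einsum("qia,mba->mqib", dref, invJ)


def _scatter(space: P2Space, Ke: np.ndarray, rows_dofs: np.ndarray,
             cols_dofs: np.ndarray, shape: tuple[int, int]) -> sp.csr_matrix:
    m, nr, nc = Ke.shape
    rows = np.repeat(rows_dofs, nc, axis=1).ravel()
    cols = np.tile(cols_dofs, (1, nr)).ravel()
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=shape).tocsr()


class Assembler:
    """Caches geometry factors for repeated assembly on one mesh."""

    def __init__(self, space: P2Space, scale: float = 1.0):
        self.space = space
        self.scale = scale
        self.area, self.invJ = _geometry(space, scale)
        self.G = _phys_grads(self.invJ, DN_Q)  # (m,7,6,2)
        self.dofs = space.p2_dofs()  # (m,6)
        self.n2 = space.n_p2
        self.nv = space.n_vertices

    # -- bilinear forms -------------------------------------------------
    def stiffness(self, mu: float) -> sp.csr_matrix:
        Ke = mu * np.einsum("q,mqia,mqja,m->mij", QWEIGHTS, self.G, self.G, self.area)
        return _scatter(self.space, Ke, self.dofs, self.dofs, (self.n2, self.n2))

    def mass(self, coef: float = 1.0) -> sp.csr_matrix:
        Me = coef * np.einsum("q,qi,qj,m->mij", QWEIGHTS, N_Q, N_Q, self.area)
        return _scatter(self.space, Me, self.dofs, self.dofs, (self.n2, self.n2))

    def divergence(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Dx, Dy with (Dx u_x + Dy u_y)_k = integral psi_k du/dx + dv/dy."""
        Dxe = np.einsum("q,qk,mqj,m->mkj", QWEIGHTS, P1_Q, self.G[..., 0], self.area)
        Dye = np.einsum("q,qk,mqj,m->mkj", QWEIGHTS, P1_Q, self.G[..., 1], self.area)
        pdofs = self.space.triangles
        Dx = _scatter(self.space, Dxe, pdofs, self.dofs, (self.nv, self.n2))
        Dy = _scatter(self.space, Dye, pdofs, self.dofs, (self.nv, self.n2))
        return Dx, Dy

    def _vel_at_q(self, w: np.ndarray) -> np.ndarray:
        """(m, 7, 2) velocity at quadrature points from P2 nodal values."""
        wn = w[self.dofs]  # (m,6,2)
        return np.einsum("qi,mic->mqc", N_Q, wn)

    def convection(self, w: np.ndarray, rho: float) -> sp.csr_matrix:
        """C(w)_{ij} = rho * integral (w . grad phi_j) phi_i."""
        wq = self._vel_at_q(w)
        conv = np.einsum("mqc,mqjc->mqj", wq, self.G)  # (m,7,6)
        Ce = rho * np.einsum("q,qi,mqj,m->mij", QWEIGHTS, N_Q, conv, self.area)
        return _scatter(self.space, Ce, self.dofs, self.dofs, (self.n2, self.n2))

    def grad_weighted_mass(self, w: np.ndarray, rho: float):
        """Newton reaction blocks: Nab_{ij} = rho * integral phi_i phi_j d(w_a)/d(x_b)."""
        wn = w[self.dofs]  # (m,6,2)
        gw = np.einsum("mic,mqib->mqcb", wn, self.G)  # (m,7,2,2) grad w at q
        blocks = {}
        for a in range(2):
            for b in range(2):
                Be = rho * np.einsum(
                    "q,qi,qj,mq,m->mij", QWEIGHTS, N_Q, N_Q, gw[:, :, a, b], self.area
                )
                blocks[(a, b)] = _scatter(
                    self.space, Be, self.dofs, self.dofs, (self.n2, self.n2)
                )
        return blocks

    def velocity_gradients_centroid(self, w: np.ndarray) -> np.ndarray:
        """(m, 2, 2) grad w evaluated at element centroids: [a, b] = d w_a / d x_b."""
        Gc = _phys_grads(self.invJ, DN_C)[:, 0]  # (m,6,2)
        wn = w[self.dofs]
        return np.einsum("mic,mib->mcb", wn, Gc)


def velocity_gradient_at_centroids(space: P2Space, w: np.ndarray, scale: float = 1.0):
    return Assembler(space, scale).velocity_gradients_centroid(w)


def assemble_stokes_blocks(asm: Assembler, mu: float):
    K = asm.stiffness(mu)
    Dx, Dy = asm.divergence()
    return K, Dx, Dy


def assemble_convection(asm: Assembler, w: np.ndarray, rho: float):
    return asm.convection(w, rho)


def assemble_newton_blocks(asm: Assembler, w: np.ndarray, rho: float):
    return asm.grad_weighted_mass(w, rho)
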