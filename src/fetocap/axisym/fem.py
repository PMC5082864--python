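"""Low-level finite-element machinery on triangulated meridian meshes.

Provides the Taylor–Hood (P2 velocity / P1 pressure) discretization data:
global P2 numbering (corner nodes first, edge midpoints appended),
reference-element shape functions, per-element geometric factors,
vectorized assembly of the axisymmetric bilinear forms (all integrals
carry the measure r dr dz of the volume of revolution divided by 2*pi),
and 3-point Gauss quadrature on boundary edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import AxisymMesh

__all__ = ["FemSpace"]

# 6-point degree-4 triangle quadrature (barycentric points, weights sum to 1)
_A1, _W1 = 0.445948490915965, 0.223381589678011
_A2, _W2 = 0.091576213509771, 0.109951743655322
_TRI_QP = np.array(
    [
        [_A1, _A1, 1 - 2 * _A1],
        [_A1, 1 - 2 * _A1, _A1],
        [1 - 2 * _A1, _A1, _A1],
        [_A2, _A2, 1 - 2 * _A2],
        [_A2, 1 - 2 * _A2, _A2],
        [1 - 2 * _A2, _A2, _A2],
    ]
)
_TRI_QW = np.array([_W1, _W1, _W1, _W2, _W2, _W2]) * 0.5  # reference area 1/2

# 3-point Gauss on [0, 1]
_S = np.sqrt(3.0 / 5.0) / 2.0
_EDGE_QP = np.array([0.5 - _S, 0.5, 0.5 + _S])
_EDGE_QW = np.array([5.0, 8.0, 5.0]) / 18.0


def _p2_basis(lam: np.ndarray) -> np.ndarray:
    """P2 shape functions at barycentric points; order (v0, v1, v2, m12, m02, m01)."""
    l0, l1, l2 = lam[..., 0], lam[..., 1], lam[..., 2]
    return np.stack(
        [
            l0 * (2 * l0 - 1),
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            4 * l1 * l2,
            4 * l0 * l2,
            4 * l0 * l1,
        ],
        axis=-1,
    )


def _p2_grad_ref(lam: np.ndarray) -> np.ndarray:
    """Gradients of P2 shape functions w.r.t. (xi, eta) = (lam1, lam2)."""
    l0, l1, l2 = lam[..., 0], lam[..., 1], lam[..., 2]
    z = np.zeros_like(l0)
    d_xi = np.stack(
        [1 - 4 * l0, 4 * l1 - 1, z, 4 * l2, -4 * l2, 4 * (l0 - l1)], axis=-1
    )
    d_eta = np.stack(
        [1 - 4 * l0, z, 4 * l2 - 1, 4 * l1, 4 * (l0 - l2), -4 * l1], axis=-1
    )
    return np.stack([d_xi, d_eta], axis=-1)  # (..., 6, 2)


_P1_GRAD_REF = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # (3, 2)


@dataclass
class FemSpace:
    """Per-mesh discretization data shared by the Stokes and transport solves."""

    mesh: AxisymMesh

    def __post_init__(self) -> None:
        mesh = self.mesh
        self.n_p1 = mesh.n_nodes
        tris = mesh.tris
        # global edge-midpoint numbering
        edges = {}
        conn6 = np.empty((mesh.n_tris, 6), dtype=np.int64)
        conn6[:, :3] = tris
        mid_local = [(1, 2), (0, 2), (0, 1)]
        mid_coords = []
        nxt = self.n_p1
        for t, tri in enumerate(tris):
            for m, (i, j) in enumerate(mid_local):
                key = (min(tri[i], tri[j]), max(tri[i], tri[j]))
                if key not in edges:
                    edges[key] = nxt
                    mid_coords.append(0.5 * (mesh.nodes[key[0]] + mesh.nodes[key[1]]))
                    nxt += 1
                conn6[t, 3 + m] = edges[key]
        self.edge_mid = edges
        self.conn6 = conn6
        self.n_p2 = nxt
        self.p2_coords = np.vstack([mesh.nodes, np.asarray(mid_coords)])

        # affine geometry per element
        p = mesh.nodes[tris]  # (ntri, 3, 2)
        j11 = p[:, 1, 0] - p[:, 0, 0]
        j12 = p[:, 2, 0] - p[:, 0, 0]
        j21 = p[:, 1, 1] - p[:, 0, 1]
        j22 = p[:, 2, 1] - p[:, 0, 1]
        det = j11 * j22 - j12 * j21
        self.detJ = det
        inv = np.empty((mesh.n_tris, 2, 2))
        inv[:, 0, 0] = j22 / det
        inv[:, 0, 1] = -j12 / det
        inv[:, 1, 0] = -j21 / det
        inv[:, 1, 1] = j11 / det
        self.invJ = inv  # d(xi,eta)/d(r,z)

        # quadrature data
        self.qw = _TRI_QW
        lam = _TRI_QP
        self.phi2 = _p2_basis(lam)  # (nq, 6)
        g2ref = _p2_grad_ref(lam)  # (nq, 6, 2)
        # physical gradients: g[e, q, a, d] = sum_k g2ref[q, a, k] * invJ[e, k, d]
        self.grad2 = np.einsum("qak,ekd->eqad", g2ref, inv)
        self.grad1 = np.einsum("ak,ekd->ead", _P1_GRAD_REF, inv)  # (ntri, 3, 2)
        self.phi1 = lam  # (nq, 3) barycentric = P1 basis
        # physical r at quadrature points
        self.r_q = np.einsum("qc,ec->eq", lam, p[:, :, 0])  # (ntri, nq)
        self.z_q = np.einsum("qc,ec->eq", lam, p[:, :, 1])
        # integration weight including axisymmetric measure r
        self.wdet = self.qw[None, :] * np.abs(det)[:, None]  # (ntri, nq)
        self.wdet_r = self.wdet * self.r_q

    # ------------------------------------------------------------------
    # assembly helpers
    # ------------------------------------------------------------------
    def _scatter(self, local: np.ndarray, rows_conn: np.ndarray, cols_conn: np.ndarray,
                 shape: tuple[int, int]) -> sp.csr_matrix:
        ne, a, b = local.shape
        rows = np.repeat(rows_conn, b, axis=1).ravel()
        cols = np.tile(cols_conn, (1, a)).ravel()
        return sp.coo_matrix((local.ravel(), (rows, cols)), shape=shape).tocsr()

    def stiffness_p2_r(self) -> sp.csr_matrix:
        """int grad(phi_i) . grad(phi_j) r dr dz on P2."""
        local = np.einsum("eq,eqad,eqbd->eab", self.wdet_r, self.grad2, self.grad2)
        return self._scatter(local, self.conn6, self.conn6, (self.n_p2, self.n_p2))

    def mass_p2_over_r(self) -> sp.csr_matrix:
        """int phi_i phi_j / r * r dr dz = int phi_i phi_j dr dz on P2."""
        # the r of the axisymmetric measure cancels the 1/r exactly
        local = np.einsum("eq,qa,qb->eab", self.wdet, self.phi2, self.phi2)
        return self._scatter(local, self.conn6, self.conn6, (self.n_p2, self.n_p2))

    def divergence_blocks(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Pressure-coupling blocks G_r, G_z with G[i, j] = -int p1_j * div-term(phi2_i).

        G_r rows pair with u_r tests: -(r * d_r phi_i + phi_i) p_j;
        G_z rows pair with u_z tests: -(r * d_z phi_i) p_j.
        """
        gr = -np.einsum("eq,eqa,qb->eab", self.wdet_r, self.grad2[:, :, :, 0], self.phi1)
        gr -= np.einsum("eq,qa,qb->eab", self.wdet, self.phi2, self.phi1)
        gz = -np.einsum("eq,eqa,qb->eab", self.wdet_r, self.grad2[:, :, :, 1], self.phi1)
        shape = (self.n_p2, self.n_p1)
        return (
            self._scatter(gr, self.conn6, self.mesh.tris, shape),
            self._scatter(gz, self.conn6, self.mesh.tris, shape),
        )

    def stiffness_p1_r(self, coeff: float) -> sp.csr_matrix:
        """coeff * int grad(w_i) . grad(c_j) r dr dz on P1."""
        local = coeff * np.einsum("eq,ead,ebd->eab", self.wdet_r, self.grad1, self.grad1)
        return self._scatter(local, self.mesh.tris, self.mesh.tris, (self.n_p1, self.n_p1))

    def tensor_stiffness_p1(self, tensor_e: np.ndarray) -> sp.csr_matrix:
        """int grad(w_i) . T_e . grad(c_j) r dr dz with a per-element 2x2 tensor."""
        w = self.wdet_r.sum(axis=1)  # per-element integral of r dA
        local = np.einsum("e,ead,edf,ebf->eab", w, self.grad1, tensor_e, self.grad1)
        return self._scatter(local, self.mesh.tris, self.mesh.tris, (self.n_p1, self.n_p1))

    def velocity_at_qp(self, u_r: np.ndarray, u_z: np.ndarray) -> np.ndarray:
        """P2 velocity at the triangle quadrature points, shape (ntri, nq, 2)."""
        ur_q = np.einsum("qa,ea->eq", self.phi2, u_r[self.conn6])
        uz_q = np.einsum("qa,ea->eq", self.phi2, u_z[self.conn6])
        return np.stack([ur_q, uz_q], axis=-1)

    def advection_supg_p1(
        self, vel_q: np.ndarray, adv_coeff: float, diff_coeff: float,
        stabilize: bool = True,
    ) -> sp.csr_matrix:
        """Advection operator adv_coeff * int (u . grad c) w r, plus SUPG term.

        SUPG adds tau_e * int (a . grad w)(a . grad c) r with a = adv_coeff*u,
        per element, with tau from the directional element length h_UGN and
        the upwind function coth(Pe_h) - 1/Pe_h; it is active only where the
        element Péclet number exceeds 1.
        """
        a_q = adv_coeff * vel_q  # (ntri, nq, 2)
        # a . grad(c_j) at qps
        a_dot_grad = np.einsum("eqd,ebd->eqb", a_q, self.grad1)  # (ntri, nq, 3)
        local = np.einsum("eq,qa,eqb->eab", self.wdet_r, self.phi1, a_dot_grad)
        if stabilize:
            a_mean = a_q.mean(axis=1)  # (ntri, 2)
            speed = np.linalg.norm(a_mean, axis=1)
            ok = speed > 0
            s_hat = np.zeros_like(a_mean)
            s_hat[ok] = a_mean[ok] / speed[ok, None]
            # directional element length h = 2 / sum_i |s_hat . grad N_i|
            denom = np.abs(np.einsum("ed,ead->ea", s_hat, self.grad1)).sum(axis=1)
            h = np.zeros_like(speed)
            h[denom > 0] = 2.0 / denom[denom > 0]
            pe_h = speed * h / (2.0 * diff_coeff)
            xi = np.zeros_like(pe_h)
            big = pe_h > 1.0
            small = ok & ~big
            xi[big] = 1.0 / np.tanh(pe_h[big]) - 1.0 / pe_h[big]
            # keep tau continuous but vanishing for well-resolved elements
            xi[small] = 0.0
            tau = np.zeros_like(speed)
            tau[ok & big] = h[ok & big] * xi[ok & big] / (2.0 * speed[ok & big])
            a_dot_gw = np.einsum("eqd,ead->eqa", a_q, self.grad1)
            local += tau[:, None, None] * np.einsum(
                "eq,eqa,eqb->eab", self.wdet_r, a_dot_gw, a_dot_grad
            )
        return self._scatter(local, self.mesh.tris, self.mesh.tris, (self.n_p1, self.n_p1))

    # ------------------------------------------------------------------
    # boundary edges
    # ------------------------------------------------------------------
    def edge_nodes_p2(self, tag: str) -> np.ndarray:
        """Sorted unique P2 node ids on a tagged boundary."""
        ids = set()
        for e in self.mesh.boundary.get(tag, np.empty((0, 2), dtype=int)):
            key = (min(e), max(e))
            ids.update((int(e[0]), int(e[1]), self.edge_mid[key]))
        return np.array(sorted(ids), dtype=np.int64)

    def edge_nodes_p1(self, tag: str) -> np.ndarray:
        edges = self.mesh.boundary.get(tag, np.empty((0, 2), dtype=int))
        return np.unique(np.asarray(edges, dtype=np.int64).ravel())

    def edge_quadrature(self, tag: str):
        """Per-edge 1D Gauss data: yields (p2 ids, p1 ids, qp coords, weights*|J|, basis)."""
        for e in self.mesh.boundary.get(tag, np.empty((0, 2), dtype=int)):
            n0, n1 = int(e[0]), int(e[1])
            mid = self.edge_mid[(min(n0, n1), max(n0, n1))]
            x0, x1 = self.mesh.nodes[n0], self.mesh.nodes[n1]
            length = float(np.linalg.norm(x1 - x0))
            t = _EDGE_QP
            pts = x0[None, :] + t[:, None] * (x1 - x0)[None, :]
            # quadratic edge basis on (n0, n1, mid)
            phi2 = np.stack(
                [(1 - t) * (1 - 2 * t), t * (2 * t - 1), 4 * t * (1 - t)], axis=-1
            )
            phi1 = np.stack([1 - t, t], axis=-1)
            yield (
                np.array([n0, n1, mid]),
                np.array([n0, n1]),
                pts,
                _EDGE_QW * length,
                phi2,
                phi1,
            )

    def edge_integral_p2(self, tag: str, nodal: np.ndarray, weight_r: bool = True) -> float:
        """int_Gamma f ds (or f r ds) of a P2 field over a tagged boundary."""
        total = 0.0
        for p2ids, _, pts, w, phi2, _ in self.edge_quadrature(tag):
            f = phi2 @ nodal[p2ids]
            r = pts[:, 0]
            total += float(np.sum(w * f * (r if weight_r else 1.0)))
        return total

    def edge_integral_product(self, tag: str, nodal_p2: np.ndarray, nodal_p1: np.ndarray) -> float:
        """int_Gamma (P2 field)*(P1 field) r ds over a tagged boundary."""
        total = 0.0
        for p2ids, p1ids, pts, w, phi2, phi1 in self.edge_quadrature(tag):
            f = phi2 @ nodal_p2[p2ids]
            g = phi1 @ nodal_p1[p1ids]
            total += float(np.sum(w * f * g * pts[:, 0]))
        return total
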