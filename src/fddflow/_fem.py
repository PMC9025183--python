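"""Taylor-Hood (P2/P1) finite elements for incompressible flow on triangles.

Internal machinery shared by the steady and pulsatile solvers: quadratic
velocity / linear pressure spaces, vectorized assembly of the linearized
(Picard) momentum + continuity saddle system, Dirichlet elimination, and
evaluation utilities (cell-wise velocity gradients, boundary fluxes, point
sampling).

Supports two coordinate modes.  In ``PLANAR_2D`` all integrals use the
Cartesian measure dx dy (unit depth).  In ``AXISYMMETRIC`` the coordinates
are (z, r) = (x, y), the measure is r dr dz (the constant 2*pi is kept out
of the matrices but included in reported physical fluxes/areas), the
viscous form gains the hoop term 2*mu*u_r*v_r/r^2 and the divergence the
u_r/r term.  Quadrature points are strictly interior, so 1/r is finite on
elements touching the axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .geometry import AXISYMMETRIC, Mesh

# 7-point degree-5 Gauss rule on the reference triangle
_QW = np.array([0.225,
                0.13239415278850618, 0.13239415278850618, 0.13239415278850618,
                0.12593918054482715, 0.12593918054482715, 0.12593918054482715]
               ) * 0.5
_a = 0.4701420641051151   # goes with weight 0.13239415...
_b = 0.1012865073234563   # goes with weight 0.12593918...
_QP = np.array([
    [1 / 3, 1 / 3],
    [_a, _a], [1 - 2 * _a, _a], [_a, 1 - 2 * _a],
    [_b, _b], [1 - 2 * _b, _b], [_b, 1 - 2 * _b],
])


def p2_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P2 basis values (q,6) and reference gradients (q,6,2).

    Node order: 3 vertices, then midpoints of edges (0,1), (1,2), (2,0).
    """
    x, y = xi[:, 0], xi[:, 1]
    l1, l2, l3 = 1 - x - y, x, y
    N = np.stack([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                  4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1], axis=1)
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    G = np.zeros((len(xi), 6, 2))
    for d in range(2):
        G[:, 0, d] = (4 * l1 - 1) * dl[0, d]
        G[:, 1, d] = (4 * l2 - 1) * dl[1, d]
        G[:, 2, d] = (4 * l3 - 1) * dl[2, d]
        G[:, 3, d] = 4 * (l1 * dl[1, d] + l2 * dl[0, d])
        G[:, 4, d] = 4 * (l2 * dl[2, d] + l3 * dl[1, d])
        G[:, 5, d] = 4 * (l3 * dl[0, d] + l1 * dl[2, d])
    return N, G


def p1_shape(xi: np.ndarray) -> np.ndarray:
    x, y = xi[:, 0], xi[:, 1]
    return np.stack([1 - x - y, x, y], axis=1)


@dataclass
class FEMSpace:
    """Connectivity of the Taylor-Hood space on a given mesh."""

    mesh: Mesh
    edges: np.ndarray          # (n_edges, 2) sorted vertex pairs
    cell_edges: np.ndarray     # (n_cells, 3) edge ids per cell
    edge_index: dict           # (a,b) sorted -> edge id
    vnodes: np.ndarray         # (nv, 2) velocity node coords (vertices+mids)

    @property
    def n_vnodes(self) -> int:
        return len(self.vnodes)

    @property
    def n_pnodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def n_dofs(self) -> int:
        return 2 * self.n_vnodes + self.n_pnodes

    def cell_vdofs(self) -> np.ndarray:
        """(n_cells, 6) velocity node ids per cell (vertices then mids)."""
        return np.hstack([self.mesh.cells,
                          self.mesh.n_nodes + self.cell_edges])

    def facet_vnodes(self, facets: np.ndarray) -> np.ndarray:
        """(k, 3) velocity node ids on each facet: both ends + midpoint."""
        mids = np.array([self.edge_index[(min(a, b), max(a, b))]
                         for a, b in facets], dtype=np.int64)
        return np.column_stack([facets, self.mesh.n_nodes + mids])


def build_space(mesh: Mesh) -> FEMSpace:
    cells = mesh.cells
    raw = np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    raw.sort(axis=1)
    edges, inv = np.unique(raw, axis=0, return_inverse=True)
    cell_edges = inv.reshape(3, -1).T
    edge_index = {(int(a), int(b)): i for i, (a, b) in enumerate(edges)}
    mids = 0.5 * (mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]])
    vnodes = np.vstack([mesh.nodes, mids])
    return FEMSpace(mesh=mesh, edges=edges, cell_edges=cell_edges,
                    edge_index=edge_index, vnodes=vnodes)


def _geometry_tables(space: FEMSpace):
    mesh = space.mesh
    p = mesh.nodes[mesh.cells]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # dx/dxi
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJT = np.empty_like(J)  # J^{-T}
    invJT[:, 0, 0] = J[:, 1, 1]
    invJT[:, 0, 1] = -J[:, 1, 0]
    invJT[:, 1, 0] = -J[:, 0, 1]
    invJT[:, 1, 1] = J[:, 0, 0]
    invJT /= detJ[:, None, None]
    return p, detJ, invJT


def assemble(space: FEMSpace, mu_cell: np.ndarray, rho: float,
             adv: np.ndarray | None = None,
             D_cell: np.ndarray | None = None,
             dt: float | None = None,
             u_old: np.ndarray | None = None,
             newton: bool = False
             ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the linearized Navier-Stokes saddle system.

    Momentum: rho*(u - u_old)/dt + rho*(adv . grad)u - div(mu*(grad u +
    grad u^T)) + D*mu*u + grad p = 0; continuity: div u = 0.  ``adv`` is the
    Picard advection field on velocity nodes (None = Stokes); ``D_cell`` the
    per-cell porous dissipation tensor (None or zeros = no stent); ``dt``
    None for steady.

    Returns the CSR matrix and right-hand side (before Dirichlet
    elimination).  Dof layout: [ux (nv), uy (nv), p (np)].
    """
    mesh = space.mesh
    axisym = mesh.mode == AXISYMMETRIC
    nv, npn = space.n_vnodes, space.n_pnodes
    ndof = 2 * nv + npn
    cvd = space.cell_vdofs()                     # (nc, 6)
    cpd = mesh.cells                             # (nc, 3)
    p, detJ, invJT = _geometry_tables(space)
    nc = mesh.n_cells

    Nq, Gref = p2_shape(_QP)                     # (q,6), (q,6,2)
    Pq = p1_shape(_QP)                           # (q,3)
    nq = len(_QW)

    # physical gradients per (cell, qp, basis, dim)
    G = np.einsum("cde,qbe->cqbd", invJT, Gref)
    # quadrature point coordinates via the affine (P1) map; r = y in axisym
    xq = np.einsum("qb,cbd->cqd", Pq, p)
    rq = xq[:, :, 1]

    wfac = _QW[None, :] * np.abs(detJ)[:, None]
    if axisym:
        wfac = wfac * rq

    if adv is None:
        a_q = None
    else:
        a_cell = adv[cvd]                        # (nc,6,2)
        a_q = np.einsum("qb,cbd->cqd", Nq, a_cell)

    mu = mu_cell[:, None]                        # (nc,1) broadcast over q

    # velocity-velocity blocks (nc,6,6)
    Gx, Gy = G[..., 0], G[..., 1]
    w = wfac[:, :, None, None]
    Kxx = (mu[:, :, None, None]
           * (2 * Gx[:, :, :, None] * Gx[:, :, None, :]
              + Gy[:, :, :, None] * Gy[:, :, None, :]) * w).sum(axis=1)
    Kyy = (mu[:, :, None, None]
           * (2 * Gy[:, :, :, None] * Gy[:, :, None, :]
              + Gx[:, :, :, None] * Gx[:, :, None, :]) * w).sum(axis=1)
    Kxy = (mu[:, :, None, None]
           * Gy[:, :, :, None] * Gx[:, :, None, :] * w).sum(axis=1)
    Kyx = (mu[:, :, None, None]
           * Gx[:, :, :, None] * Gy[:, :, None, :] * w).sum(axis=1)

    NN = Nq[None, :, :, None] * Nq[None, :, None, :]   # (1,q,6,6)
    if axisym:
        # hoop term 2*mu*u_r*v_r/r^2 with measure r -> weight wfac/r^2
        Kyy = Kyy + (2.0 * mu[:, :, None, None] * NN
                     * (wfac / rq ** 2)[:, :, None, None]).sum(axis=1)

    rhs = np.zeros(ndof)
    if a_q is not None:
        conv = rho * (a_q[..., 0][:, :, None] * Gx
                      + a_q[..., 1][:, :, None] * Gy)   # (nc,q,6) trial part
        Cm = (Nq[None, :, :, None] * conv[:, :, None, :]
              * wfac[:, :, None, None]).sum(axis=1)
        Kxx += Cm
        Kyy += Cm
        if newton:
            # Newton linearization: + rho*(u.grad)a, rhs += rho*(a.grad)a
            ga = np.einsum("cbi,cqbd->cqid", a_cell, G)   # grad a at qp

            def _react(i, d):
                return rho * (NN * (ga[:, :, i, d] * wfac)[:, :, None, None]
                              ).sum(axis=1)

            Kxx += _react(0, 0)
            Kxy += _react(0, 1)
            Kyx += _react(1, 0)
            Kyy += _react(1, 1)
            aga = np.einsum("cqd,cqid->cqi", a_q, ga)     # (a.grad)a at qp
            fx = rho * (Nq[None, :, :] * (aga[:, :, 0] * wfac)[:, :, None]
                        ).sum(axis=1)
            fy = rho * (Nq[None, :, :] * (aga[:, :, 1] * wfac)[:, :, None]
                        ).sum(axis=1)
            np.add.at(rhs, cvd, fx)
            np.add.at(rhs, nv + cvd, fy)

    if D_cell is not None:
        M = (NN * wfac[:, :, None, None]).sum(axis=1)   # (nc,6,6)
        Kxx += D_cell[:, 0, 0, None, None] * mu_cell[:, None, None] * M
        Kxy += D_cell[:, 0, 1, None, None] * mu_cell[:, None, None] * M
        Kyx += D_cell[:, 1, 0, None, None] * mu_cell[:, None, None] * M
        Kyy += D_cell[:, 1, 1, None, None] * mu_cell[:, None, None] * M

    if dt is not None:
        M = (NN * wfac[:, :, None, None]).sum(axis=1)
        Kxx += (rho / dt) * M
        Kyy += (rho / dt) * M
        uo = u_old[cvd]                                  # (nc,6,2)
        fx = (rho / dt) * np.einsum("cij,cj->ci", M, uo[..., 0])
        fy = (rho / dt) * np.einsum("cij,cj->ci", M, uo[..., 1])
        np.add.at(rhs, cvd, fx)
        np.add.at(rhs, nv + cvd, fy)

    # pressure blocks: B_x[i,jp] = -int psi_jp dN_i/dx ; axisym adds v_r/r
    Bx = -(Gx[:, :, :, None] * Pq[None, :, None, :]
           * wfac[:, :, None, None]).sum(axis=1)        # (nc,6,3)
    divy = Gy.copy()
    if axisym:
        divy = divy + Nq[None, :, :] / rq[:, :, None]
    By = -(divy[:, :, :, None] * Pq[None, :, None, :]
           * wfac[:, :, None, None]).sum(axis=1)

    # scatter
    I, Jc, V = [], [], []
    for K, ro, co in ((Kxx, 0, 0), (Kxy, 0, nv), (Kyx, nv, 0), (Kyy, nv, nv)):
        i = np.repeat(cvd + ro, 6, axis=1).ravel()
        j = np.tile(cvd + co, (1, 6)).ravel()
        I.append(i); Jc.append(j); V.append(K.ravel())
    for B, ro in ((Bx, 0), (By, nv)):
        i = np.repeat(cvd + ro, 3, axis=1).ravel()
        j = np.tile(2 * nv + cpd, (1, 6)).ravel()
        I.append(i); Jc.append(j); V.append(B.ravel())
        # continuity rows: transpose
        I.append(j); Jc.append(i); V.append(B.ravel())
    A = sp.coo_matrix((np.concatenate(V),
                       (np.concatenate(I), np.concatenate(Jc))),
                      shape=(ndof, ndof)).tocsr()
    return A, rhs


def apply_dirichlet(A: sp.csr_matrix, rhs: np.ndarray,
                    dofs: np.ndarray, vals: np.ndarray
                    ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Eliminate Dirichlet dofs symmetric-free: move columns to the RHS,
    identity rows."""
    ndof = A.shape[0]
    x0 = np.zeros(ndof)
    x0[dofs] = vals
    rhs = rhs - A @ x0
    keep = np.ones(ndof, dtype=bool)
    keep[dofs] = False
    d = sp.diags(keep.astype(float))
    A = d @ A @ d
    A = A.tolil()
    A[dofs, dofs] = 1.0
    A = A.tocsr()
    rhs[dofs] = vals
    return A, rhs


def solve_linear(A: sp.csr_matrix, rhs: np.ndarray) -> np.ndarray:
    return spla.spsolve(A.tocsc(), rhs)


def cell_velocity_gradients(space: FEMSpace, u: np.ndarray,
                            where: np.ndarray | None = None,
                            ref_pts: np.ndarray | None = None) -> np.ndarray:
    """Velocity-gradient tensors du_i/dx_j per cell.

    Evaluated at the cell barycentre by default (``ref_pts`` is a single
    reference point).  Returns ``(n, 2, 2)``.
    """
    mesh = space.mesh
    cells = np.arange(mesh.n_cells) if where is None else where
    if ref_pts is None:
        ref_pts = np.array([[1 / 3, 1 / 3]])
    _, detJ, invJT = _geometry_tables(space)
    _, Gref = p2_shape(ref_pts)
    G = np.einsum("cde,qbe->cqbd", invJT[cells], Gref)[:, 0]   # (n,6,2)
    ucell = u[space.cell_vdofs()[cells]]                       # (n,6,2)
    return np.einsum("cbi,cbj->cij", ucell, G)


def facet_flux(space: FEMSpace, u: np.ndarray, facets: np.ndarray,
               normals: np.ndarray, positive_only: bool = False
               ) -> float:
    """Integral of u.n over a facet set (P2-exact 2-pt Gauss per facet).

    In axisymmetric mode the result includes the 2*pi*r factor (true
    volumetric flux, m^3/s); planar mode gives flux per unit depth (m^2/s).
    With ``positive_only`` each facet contributes max(u.n, 0) evaluated at
    quadrature points.
    """
    mesh = space.mesh
    fv = space.facet_vnodes(facets)          # (k,3): a, b, mid
    pa, pb = mesh.nodes[facets[:, 0]], mesh.nodes[facets[:, 1]]
    L = np.hypot(*(pb - pa).T)
    # 2-point Gauss on [0,1]
    gp = np.array([0.5 - 0.5 / np.sqrt(3), 0.5 + 0.5 / np.sqrt(3)])
    # quadratic shape along the edge: ends + midpoint
    total = 0.0
    for s, wq in zip(gp, (0.5, 0.5)):
        Na = (1 - s) * (1 - 2 * s)
        Nb = s * (2 * s - 1)
        Nm = 4 * s * (1 - s)
        uv = (Na * u[fv[:, 0]] + Nb * u[fv[:, 1]] + Nm * u[fv[:, 2]])
        un = np.einsum("ki,ki->k", uv, normals)
        if positive_only:
            un = np.maximum(un, 0.0)
        w = wq * L
        if mesh.mode == AXISYMMETRIC:
            r = (1 - s) * pa[:, 1] + s * pb[:, 1]
            w = w * 2.0 * np.pi * r
        total += float(np.sum(un * w))
    return total


def outward_normals(mesh: Mesh, facets: np.ndarray) -> np.ndarray:
    """Unit normals of outer-boundary facets pointing out of the domain."""
    edge_cells: dict[tuple[int, int], int] = {}
    cen = mesh.cell_centroids()
    want = {(min(int(a), int(b)), max(int(a), int(b))) for a, b in facets}
    for ci, tri in enumerate(mesh.cells):
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            k = (a, b) if a < b else (b, a)
            if k in want:
                edge_cells[k] = ci
    out = np.empty((len(facets), 2))
    for idx, (a, b) in enumerate(facets):
        k = (min(int(a), int(b)), max(int(a), int(b)))
        t = mesh.nodes[b] - mesh.nodes[a]
        n = np.array([t[1], -t[0]])
        n /= np.linalg.norm(n)
        mid = 0.5 * (mesh.nodes[a] + mesh.nodes[b])
        if np.dot(n, mid - cen[edge_cells[k]]) < 0:
            n = -n
        out[idx] = n
    return out


class PointLocator:
    """Locate mesh cells containing arbitrary points (KD-tree candidates +
    barycentric test)."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.tree = cKDTree(mesh.cell_centroids())
        p = mesh.nodes[mesh.cells]
        self.p0 = p[:, 0]
        T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        self.Tinv = np.empty_like(T)
        self.Tinv[:, 0, 0] = T[:, 1, 1]
        self.Tinv[:, 0, 1] = -T[:, 0, 1]
        self.Tinv[:, 1, 0] = -T[:, 1, 0]
        self.Tinv[:, 1, 1] = T[:, 0, 0]
        self.Tinv /= det[:, None, None]

    def locate(self, pts: np.ndarray, k: int = 12, tol: float = 1e-10
               ) -> tuple[np.ndarray, np.ndarray]:
        """Return (cell ids, reference coords); raises if a point is
        outside the mesh."""
        pts = np.atleast_2d(pts)
        kq = min(k, self.mesh.n_cells)
        _, cand = self.tree.query(pts, k=kq)
        cand = np.atleast_2d(cand)
        cells = np.full(len(pts), -1, dtype=np.int64)
        refs = np.zeros((len(pts), 2))
        for i, pt in enumerate(pts):
            for c in cand[i]:
                xi = self.Tinv[c] @ (pt - self.p0[c])
                if (xi[0] >= -tol and xi[1] >= -tol
                        and xi[0] + xi[1] <= 1 + tol):
                    cells[i] = c
                    refs[i] = xi
                    break
            else:
                raise ValueError(f"point {pt} not found in mesh "
                                 "(increase k or check bounds)")
        return cells, refs


def sample_velocity(space: FEMSpace, u: np.ndarray, pts: np.ndarray,
                    locator: PointLocator | None = None) -> np.ndarray:
    """P2-interpolated velocity at arbitrary points, shape (k, 2)."""
    locator = locator or PointLocator(space.mesh)
    cells, refs = locator.locate(pts)
    N, _ = p2_shape(refs)                        # (k,6)
    ucell = u[space.cell_vdofs()[cells]]         # (k,6,2)
    return np.einsum("kb,kbd->kd", N, ucell)
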