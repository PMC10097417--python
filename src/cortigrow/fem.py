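"""Bilinear quadrilateral finite-element operators and mechanics assembly.

Plain displacement Q4 elements with 2x2 Gauss quadrature, total-Lagrangian
weak form on the reference mesh. The growth tensor enters through the
multiplicative split F = Fe Fg: the stored energy per unit reference
volume is ``det(Fg) psi(Fe)``, so the nominal stress is
``P = det(Fg) dpsi/dFe Fg^{-T}`` and the tangent follows by the chain
rule. Assembly is vectorized over all elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as con
from .geometry import Mesh

__all__ = [
    "FemOperators",
    "ElementInversionError",
    "deformation_gradient",
    "assemble_mechanics",
    "dirichlet_dofs",
    "apply_dirichlet",
    "newton_solve",
]

# 2x2 Gauss points on [-1, 1]^2
_G = 1.0 / np.sqrt(3.0)
_QP = np.array([[-_G, -_G], [_G, -_G], [_G, _G], [-_G, _G]])
_QW = np.ones(4)


class ElementInversionError(RuntimeError):
    """Raised when det F <= 0 at a quadrature point (step must be rejected)."""


def _shape_functions(xi, eta):
    """Q4 shape functions and parent-space gradients at (xi, eta)."""
    N = 0.25 * np.array(
        [
            (1 - xi) * (1 - eta),
            (1 + xi) * (1 - eta),
            (1 + xi) * (1 + eta),
            (1 - xi) * (1 + eta),
        ]
    )
    dN = 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )
    return N, dN


# Precompute shape values/derivatives at the 4 quadrature points.
_NQ = np.empty((4, 4))        # (qp, node)
_DNQ = np.empty((4, 4, 2))    # (qp, node, xi/eta)
for _q, (_xi, _eta) in enumerate(_QP):
    _n, _d = _shape_functions(_xi, _eta)
    _NQ[_q] = _n
    _DNQ[_q] = _d


@dataclass
class FemOperators:
    """Per-mesh immutable assembly data (geometry factors, gather indices)."""

    mesh: Mesh
    dNdX: np.ndarray        # (ne, nq, 4, 2) shape-fn gradients wrt reference X
    wdetJ: np.ndarray       # (ne, nq) quadrature weights x |J|
    qp_coords: np.ndarray   # (ne, nq, 2) reference quadrature-point positions
    qp_ri: np.ndarray       # (ne, nq) material radius at quadrature points
    qp_theta: np.ndarray    # (ne, nq) reference polar angle at qps
    qp_fiber: np.ndarray    # (ne, nq, 2) reference fiber direction N
    rows_vec: np.ndarray    # COO row indices for 2-dof vector assembly
    cols_vec: np.ndarray
    rows_sca: np.ndarray    # COO indices for scalar assembly
    cols_sca: np.ndarray

    @classmethod
    def build(cls, mesh: Mesh) -> "FemOperators":
        X = mesh.nodes[mesh.elements]                       # (ne, 4, 2)
        # Jacobian dX/dxi at each qp: (ne, nq, 2, 2)
        Jmat = np.einsum("qak,eai->eqik", _DNQ, X)
        detJ = np.linalg.det(Jmat)
        if np.any(detJ <= 0):
            raise ValueError("mesh contains inverted elements")
        Jinv = np.linalg.inv(Jmat)
        dNdX = np.einsum("qak,eqkJ->eqaJ", _DNQ, Jinv)
        wdetJ = detJ * _QW[None, :]
        qp = np.einsum("qa,eai->eqi", _NQ, X)
        ri = np.einsum("qa,ea->eq", _NQ, mesh.material_radius[mesh.elements])
        theta = np.arctan2(qp[..., 1], qp[..., 0])
        nrm = np.linalg.norm(qp, axis=-1, keepdims=True)
        fiber = qp / nrm

        conn = mesh.elements
        ne = conn.shape[0]
        # vector (2 dof/node) gather: element dof order (a0x, a0y, a1x, ...)
        edofs = np.empty((ne, 8), dtype=np.int64)
        edofs[:, 0::2] = 2 * conn
        edofs[:, 1::2] = 2 * conn + 1
        rows_vec = np.repeat(edofs, 8, axis=1).ravel()
        cols_vec = np.tile(edofs, (1, 8)).ravel()
        rows_sca = np.repeat(conn, 4, axis=1).ravel()
        cols_sca = np.tile(conn, (1, 4)).ravel()
        return cls(
            mesh, dNdX, wdetJ, qp, ri, theta, fiber,
            rows_vec, cols_vec, rows_sca, cols_sca,
        )

    # -- field interpolation helpers ------------------------------------
    def interp_scalar(self, nodal: np.ndarray) -> np.ndarray:
        """Nodal scalar -> value at each quadrature point, (ne, nq)."""
        return np.einsum("qa,ea->eq", _NQ, nodal[self.mesh.elements])

    def grad_scalar_ref(self, nodal: np.ndarray) -> np.ndarray:
        """Reference gradient of a nodal scalar at qps, (ne, nq, 2)."""
        return np.einsum("eqaJ,ea->eqJ", self.dNdX, nodal[self.mesh.elements])

    def element_size(self) -> np.ndarray:
        """Characteristic reference element size h per element, (ne,)."""
        area = self.wdetJ.sum(axis=1)
        return np.sqrt(area)

    def integrate(self, qp_values: np.ndarray) -> float:
        """Integral over the reference domain of a qp field (ne, nq)."""
        return float(np.sum(qp_values * self.wdetJ))

    def lumped_mass(self, qp_weight: np.ndarray | None = None) -> np.ndarray:
        """Row-sum lumped mass vector, optionally weighted per qp."""
        w = self.wdetJ if qp_weight is None else self.wdetJ * qp_weight
        me = np.einsum("qa,eq->ea", _NQ, w)
        m = np.zeros(self.mesh.n_nodes)
        np.add.at(m, self.mesh.elements.ravel(), me.ravel())
        return m

    def assemble_scalar_matrix(self, kernel: np.ndarray) -> sp.csr_matrix:
        """Assemble sum_e int N_a-kernel-N_b style matrices from per-element
        dense blocks ``kernel`` of shape (ne, 4, 4)."""
        n = self.mesh.n_nodes
        A = sp.coo_matrix(
            (kernel.ravel(), (self.rows_sca, self.cols_sca)), shape=(n, n)
        )
        return A.tocsr()


def deformation_gradient(ops: FemOperators, u: np.ndarray) -> np.ndarray:
    """Total deformation gradient F = I + Grad(u) at quadrature points.

    ``u`` is nodal displacement (n, 2); returns (ne, nq, 2, 2).
    """
    ue = u[ops.mesh.elements]                                # (ne, 4, 2)
    G = np.einsum("eqaJ,eai->eqiJ", ops.dNdX, ue)
    return G + np.eye(2)


def assemble_mechanics(
    ops: FemOperators,
    u: np.ndarray,
    mu_qp: np.ndarray,
    lam_qp: np.ndarray,
    theta_perp: np.ndarray,
    theta_par: np.ndarray,
    want_tangent: bool = True,
):
    """Residual (and tangent) of the quasi-static growth mechanics.

    Fields ``mu_qp, lam_qp, theta_perp, theta_par`` are (ne, nq) arrays.
    Returns ``(R, K)`` with R the (2n,) residual of the total-Lagrangian
    weak form and K the consistent tangent (None if not requested).
    Raises :class:`ElementInversionError` if det F <= 0 anywhere.
    """
    mesh = ops.mesh
    F = deformation_gradient(ops, u)
    if np.any(np.linalg.det(F) <= 0.0):
        raise ElementInversionError("negative Jacobian during assembly")

    Fg = con.growth_tensor(theta_perp, theta_par, ops.qp_fiber)
    Jg = theta_perp * theta_par
    Fginv = np.linalg.inv(Fg)
    Fe = F @ Fginv
    if np.any(np.linalg.det(Fe) <= 0.0):
        raise ElementInversionError("negative elastic Jacobian")

    Pe = con.first_piola_elastic(Fe, mu_qp, lam_qp)
    # P_iJ = Jg * Pe_iM * Fginv_JM
    P = np.einsum("eq,eqiM,eqJM->eqiJ", Jg, Pe, Fginv)

    w = ops.wdetJ
    Rel = np.einsum("eq,eqiJ,eqaJ->eai", w, P, ops.dNdX)     # (ne, 4, 2)
    R = np.zeros(2 * mesh.n_nodes)
    np.add.at(R, (2 * mesh.elements).ravel(), Rel[..., 0].ravel())
    np.add.at(R, (2 * mesh.elements + 1).ravel(), Rel[..., 1].ravel())

    K = None
    if want_tangent:
        A = con.elastic_moduli(Fe, mu_qp, lam_qp)            # (ne,nq,2,2,2,2)
        # C_iJkL = Jg A_iMkN Fginv_JM Fginv_LN
        C = np.einsum(
            "eq,eqiMkN,eqJM,eqLN->eqiJkL", Jg, A, Fginv, Fginv, optimize=True
        )
        Kel = np.einsum(
            "eq,eqaJ,eqiJkL,eqbL->eaibk", w, ops.dNdX, C, ops.dNdX, optimize=True
        )
        # element dof blocks (8x8) with dof index = 2a + i
        Kel = Kel.reshape(Kel.shape[0], 8, 8)
        n = 2 * mesh.n_nodes
        K = sp.coo_matrix(
            (Kel.ravel(), (ops.rows_vec, ops.cols_vec)), shape=(n, n)
        ).tocsr()
    return R, K


def dirichlet_dofs(mesh: Mesh) -> np.ndarray:
    """Constrained displacement dofs for the quarter-annulus problem.

    Inner (ventricular) boundary: fully fixed. Edge on the x-axis: zero
    y-displacement. Edge on the y-axis: zero x-displacement. Outer
    boundary: traction-free (natural).
    """
    dofs = set()
    for nid in mesh.boundary["inner"]:
        dofs.add(2 * int(nid))
        dofs.add(2 * int(nid) + 1)
    for nid in mesh.boundary["edge_y0"]:
        dofs.add(2 * int(nid) + 1)
    for nid in mesh.boundary["edge_x0"]:
        dofs.add(2 * int(nid))
    return np.array(sorted(dofs), dtype=np.int64)


def apply_dirichlet(K: sp.csr_matrix, R: np.ndarray, dofs: np.ndarray):
    """Eliminate homogeneous Dirichlet dofs: identity rows/cols, zero RHS."""
    n = K.shape[0]
    free = np.ones(n)
    free[dofs] = 0.0
    P = sp.diags(free)
    fixed = np.zeros(n)
    fixed[dofs] = 1.0
    Kc = (P @ K @ P + sp.diags(fixed)).tocsr()
    R = R.copy()
    R[dofs] = 0.0
    return Kc, R


def newton_solve(
    ops: FemOperators,
    u0: np.ndarray,
    mu_qp: np.ndarray,
    lam_qp: np.ndarray,
    theta_perp: np.ndarray,
    theta_par: np.ndarray,
    fixed_dofs: np.ndarray | None = None,
    tol: float = 1e-8,
    abs_tol: float = 1e-12,
    max_iter: int = 25,
):
    """Newton iteration for mechanical equilibrium at frozen growth/density.

    Returns ``(u, converged, n_iter, res_norm)``. The relative residual is
    measured against the first iterate's residual norm (with an absolute
    floor so an already-equilibrated state converges immediately).
    """
    mesh = ops.mesh
    if fixed_dofs is None:
        fixed_dofs = dirichlet_dofs(mesh)

    def residual_norm(u_):
        try:
            R_, _ = assemble_mechanics(
                ops, u_, mu_qp, lam_qp, theta_perp, theta_par, want_tangent=False
            )
        except ElementInversionError:
            return None
        R_ = R_.copy()
        R_[fixed_dofs] = 0.0
        return np.linalg.norm(R_)

    u = u0.copy()
    res0 = None
    nrm = None
    for it in range(max_iter):
        try:
            R, K = assemble_mechanics(ops, u, mu_qp, lam_qp, theta_perp, theta_par)
        except ElementInversionError:
            return u, False, it, np.inf
        Kc, Rc = apply_dirichlet(K, R, fixed_dofs)
        nrm = np.linalg.norm(Rc)
        if res0 is None:
            res0 = nrm
        if nrm <= abs_tol or (res0 > 0 and nrm <= tol * res0):
            return u, True, it, nrm
        du = spla.spsolve(Kc.tocsc(), -Rc).reshape(-1, 2)
        # backtracking line search on the residual norm, also guarding
        # against element inversion (robustness through bifurcations)
        step = 1.0
        accepted = False
        for _ in range(10):
            cand = residual_norm(u + step * du)
            if cand is not None and cand < nrm:
                u = u + step * du
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return u, False, it, nrm
    nrm = residual_norm(u)
    ok = (
        nrm is not None
        and res0 is not None
        and (nrm <= abs_tol or nrm <= tol * max(res0, 1e-30))
    )
    return u, ok, max_iter, (nrm if nrm is not None else np.inf)
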