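"""Cell-density balance: proliferation, migration, cortical diffusion.

The scalar density field c(x, t) (cells per mm^2) obeys an
advection-diffusion-reaction balance on the growing, deforming domain:

    (Jdot/J) c + cdot = -div[ v_hat c - d grad c ] + r_vz + r_osvz

Cells are born in two proliferative zones (VZ near the ventricle, OSVZ
whose outer boundary expands at the MST speed), migrate radially along
the deformed glial-fiber directions once the local density exceeds a
threshold, and diffuse isotropically once they reach the cortex.
Division rates in both zones are down-regulated by the maximum stretch
in the domain (mechanical feedback).

The time discretization is implicit Euler on the Lagrangian mesh with
the dilution term realized by balancing the total cell number J c per
material volume; advection uses streamline (SUPG-type) stabilization
plus a residual-based artificial viscosity that vanishes on resolved
solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import smooth_heaviside
from .fem import FemOperators, _NQ
from .geometry import (
    GeometryParams,
    osvz_outer_radius,
    zone_weight_osvz,
    zone_weight_vz,
)

__all__ = [
    "TransportParams",
    "HeterogeneityPattern",
    "osvz_outer_radius",
    "stretch_modulated_rate",
    "pattern_multiplier",
    "source_vz",
    "source_osvz",
    "migration_speed_profile",
    "migration_velocity",
    "diffusivity_profile",
    "artificial_viscosity",
    "max_stretch",
    "step_density",
    "TransportDiagnostics",
]


@dataclass(frozen=True)
class HeterogeneityPattern:
    """Angular modulation of the OSVZ division rate.

    kinds: ``homogeneous`` (multiplier 1), ``circumferential_gradient``
    (linear in theta from the upper multiplier at theta = 0 down to the
    lower one at theta = pi/2) and ``random_sectors`` (seeded
    piecewise-constant multipliers on equal angular sectors).
    """

    kind: str = "homogeneous"
    n_sectors: int = 8
    relative_range: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("homogeneous", "circumferential_gradient", "random_sectors"):
            raise ValueError(f"unknown heterogeneity kind {self.kind!r}")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")
        if self.relative_range is not None:
            lo, hi = self.relative_range
            if lo < 0 or hi < lo:
                raise ValueError("relative_range must satisfy 0 <= lo <= hi")

    @property
    def range_(self) -> tuple:
        if self.relative_range is not None:
            return tuple(self.relative_range)
        if self.kind == "circumferential_gradient":
            return (0.0, 1.0)
        return (0.5, 1.5)


@dataclass(frozen=True)
class TransportParams:
    """Parameters of the cell-density problem (rates per day, lengths mm).

    Note on units: the diffusivity d_cc is a true diffusivity and carries
    mm^2/day.
    """

    G_vz: float = 120.0       # initial division rate in the VZ, mm^-2 day^-1
    G_osvz: float = 20.0      # initial division rate in the OSVZ, mm^-2 day^-1
    v_max: float = 5.0        # maximum migration speed, mm/day
    c0: float = 500.0         # migration threshold density, mm^-2
    gamma_c: float = 0.008    # logistic exponent of the migration gate, mm^2
    d_cc: float = 0.11        # cortical diffusivity, mm^2/day
    heterogeneity: HeterogeneityPattern = field(default_factory=HeterogeneityPattern)
    # numerical stabilization (consistent, vanishes on resolved solutions)
    c_art: float = 0.5        # artificial-viscosity constant
    nu_cap: float | None = None   # absolute viscosity cap; None -> no cap
    # (the solver always limits nu by the first-order upwind viscosity
    # h |v| / 2, so regions without advection are never polluted)
    eps_reg: float = 1e-8     # gradient regularization in the viscosity
    use_streamline: bool = True   # SUPG-type streamline diffusion
    picard_iters: int = 2     # lagged-gate fixed-point sweeps per step

    def __post_init__(self):
        for name in ("G_vz", "G_osvz", "v_max", "c0", "d_cc", "gamma_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def nu_cap_(self) -> float:
        return np.inf if self.nu_cap is None else self.nu_cap

    def with_(self, **kw) -> "TransportParams":
        return replace(self, **kw)


def stretch_modulated_rate(G, s):
    """Division rate reduced by the maximum stretch s in the domain.

    G (2 - s) for s < 1.8, saturating at 0.2 G beyond; equals G at s = 1
    (s below 1 is clamped to 1). Continuous at the breakpoint.
    """
    s = np.maximum(np.asarray(s, dtype=float), 1.0)
    drop = np.minimum(s - 1.0, 0.8)
    return np.asarray(G, dtype=float) * (1.0 - drop)


def pattern_multiplier(theta, pattern: HeterogeneityPattern):
    """Angular multiplier of the OSVZ division rate in [0, inf)."""
    theta = np.asarray(theta, dtype=float)
    if pattern.kind == "homogeneous":
        return np.ones_like(theta)
    lo, hi = pattern.range_
    if pattern.kind == "circumferential_gradient":
        return hi + (lo - hi) * np.clip(theta / (np.pi / 2.0), 0.0, 1.0)
    # random_sectors
    rng = np.random.default_rng(pattern.seed)
    mult = rng.uniform(lo, hi, size=pattern.n_sectors)
    idx = np.clip(
        (theta / (np.pi / 2.0) * pattern.n_sectors).astype(int),
        0,
        pattern.n_sectors - 1,
    )
    return mult[idx]


def source_vz(ri, s, p: TransportParams, geom: GeometryParams = GeometryParams()):
    """VZ source r1 = G_vz(s) [1 - H(ri - r_vz; 50)], mm^-2 day^-1."""
    return stretch_modulated_rate(p.G_vz, s) * zone_weight_vz(ri, geom)


def source_osvz(
    ri, theta, t, s, p: TransportParams, geom: GeometryParams = GeometryParams()
):
    """OSVZ source r2 with angular heterogeneity and the MST-expanding band."""
    G = p.G_osvz * pattern_multiplier(theta, p.heterogeneity)
    return stretch_modulated_rate(G, s) * zone_weight_osvz(ri, t, geom)


def migration_speed_profile(ri, p: TransportParams, r_cp: float = 1.8):
    """Migration speed v(ri) = v_max [1 - H(ri - r_cp; 10)]; vanishes
    smoothly at the cortical plate."""
    return p.v_max * (1.0 - smooth_heaviside(np.asarray(ri, dtype=float) - r_cp, 10.0))


def migration_velocity(c, ri, n, p: TransportParams, r_cp: float = 1.8):
    """Migration velocity v_hat = H(c - c0; gamma_c) v(ri) n/||n||.

    ``n`` is the deformed fiber direction F N (push-forward of the
    reference radial direction); only its direction matters.
    """
    n = np.asarray(n, dtype=float)
    nrm = np.linalg.norm(n, axis=-1)
    if np.any(nrm == 0):
        raise ValueError("zero fiber vector")
    gate = smooth_heaviside(np.asarray(c, dtype=float) - p.c0, p.gamma_c)
    speed = gate * migration_speed_profile(ri, p, r_cp)
    return speed[..., None] * (n / nrm[..., None])


def diffusivity_profile(ri, p: TransportParams, r_cp: float = 1.8):
    """Cortical diffusivity d(ri) = d_cc H(ri - r_cp; 10), mm^2/day."""
    return p.d_cc * smooth_heaviside(np.asarray(ri, dtype=float) - r_cp, 10.0)


def artificial_viscosity(element_residual, grad_c, h, p: TransportParams):
    """Residual-based artificial viscosity nu_c, mm^2/day.

    nu_c = C_art h |R_e| / (||grad c|| + eps), capped at nu_cap (when
    set). Zero when the discrete balance residual vanishes, so exact
    solutions are left unperturbed; on smooth resolved solutions it
    shrinks at least linearly with the element size h. The caller
    additionally limits nu by the first-order upwind viscosity h |v| / 2.
    """
    if np.any(np.asarray(h) <= 0):
        raise ValueError("element size must be positive")
    nu = (
        p.c_art
        * np.asarray(h)
        * np.abs(element_residual)
        / (np.asarray(grad_c) + p.eps_reg)
    )
    return np.minimum(nu, p.nu_cap_)


def max_stretch(F):
    """Largest principal stretch (max singular value) over all points of
    the total deformation gradient field ``F`` (..., 2, 2)."""
    F = np.asarray(F, dtype=float)
    if np.any(np.linalg.det(F) <= 0):
        raise ValueError("element inversion: det F <= 0")
    C = np.swapaxes(F, -1, -2) @ F
    ev = np.linalg.eigvalsh(C)
    return float(np.sqrt(ev[..., -1].max()))


@dataclass
class TransportDiagnostics:
    """Per-step bookkeeping of the density solve."""

    clipped_mass: float = 0.0      # cell number removed by the positivity clip
    total_cells: float = 0.0       # integral of c J over the reference domain
    max_density: float = 0.0
    max_artificial_viscosity: float = 0.0


def step_density(
    ops: FemOperators,
    c_old: np.ndarray,
    dt: float,
    t_new: float,
    F_qp: np.ndarray,
    J_old_qp: np.ndarray,
    s: float,
    p: TransportParams,
    geom: GeometryParams,
    sources: bool = True,
) -> tuple[np.ndarray, TransportDiagnostics]:
    """One implicit-Euler step of the density balance on frozen mechanics.

    ``F_qp`` is the total deformation gradient of the last converged
    mechanics solve (the staggered lag); ``J_old_qp`` is det F of the
    previous transport step so that the mass term discretizes
    d(J c)/dt. ``s`` is the lagged maximum stretch entering the division
    rates. Returns the clipped density and diagnostics.
    """
    mesh = ops.mesh
    J_qp = np.linalg.det(F_qp)
    Finv = np.linalg.inv(F_qp)
    # spatial shape-function gradients: dNdx_i = Finv_Ji dNdX_J
    dNdx = np.einsum("eqaJ,eqJi->eqai", ops.dNdX, Finv)
    wJ = ops.wdetJ * J_qp
    wJold = ops.wdetJ * J_old_qp

    ri = ops.qp_ri
    theta_q = ops.qp_theta
    d_iso = diffusivity_profile(ri, p, geom.r_cp)
    vmag_profile = migration_speed_profile(ri, p, geom.r_cp)
    fib = np.einsum("eqiJ,eqJ->eqi", F_qp, ops.qp_fiber)
    fib = fib / np.linalg.norm(fib, axis=-1, keepdims=True)

    if sources:
        r_qp = source_vz(ri, s, p, geom) + source_osvz(ri, theta_q, t_new, s, p, geom)
    else:
        r_qp = np.zeros_like(ri)

    # mass matrices (J-weighted): M[a,b] = int N_a N_b J dV
    Mk = np.einsum("eq,qa,qb->eab", wJ, _NQ, _NQ)
    Mko = np.einsum("eq,qa,qb->eab", wJold, _NQ, _NQ)
    M = ops.assemble_scalar_matrix(Mk)
    Mold = ops.assemble_scalar_matrix(Mko)
    fel = np.einsum("eq,qa,eq->ea", wJ, _NQ, r_qp)
    f = np.zeros(mesh.n_nodes)
    np.add.at(f, mesh.elements.ravel(), fel.ravel())

    h_ref = ops.element_size()
    h_sp = h_ref * np.sqrt(J_qp.mean(axis=1))

    c = c_old.copy()
    c_old_qp = ops.interp_scalar(c_old)
    nu_e = np.zeros(ops.wdetJ.shape[0])
    nu_max = 0.0
    for sweep in range(max(1, p.picard_iters)):
        c_qp = ops.interp_scalar(c)
        gate = smooth_heaviside(c_qp - p.c0, p.gamma_c)
        vel = (gate * vmag_profile)[..., None] * fib        # (ne, nq, 2)
        grad_c = np.einsum("eqai,ea->eqi", dNdx, c[mesh.elements])

        # residual-based artificial viscosity, lagged one sweep: the first
        # solve runs with nu = 0 and later sweeps evaluate the strong-form
        # residual of the *solved* iterate (the discretization error), so
        # resolved solutions are left unperturbed. The elementwise-constant
        # diffusive term is dropped on Q4.
        if sweep > 0:
            resid = (
                (J_qp * c_qp - J_old_qp * c_old_qp) / (dt * J_qp)
                + np.einsum("eqi,eqi->eq", vel, grad_c)
                - r_qp
            )
            gnorm = np.linalg.norm(grad_c, axis=-1)
            nu_e = artificial_viscosity(
                np.abs(resid).mean(axis=1), gnorm.mean(axis=1), h_sp, p
            )
            # first-order upwind limit: no pollution where advection is off
            vmax_e = np.linalg.norm(vel, axis=-1).max(axis=1)
            nu_e = np.minimum(nu_e, 0.5 * h_sp * vmax_e)
            nu_max = max(nu_max, float(nu_e.max(initial=0.0)))

        # diffusion tensor D = (d_iso + nu_c) I + tau v (x) v
        Dii = d_iso + nu_e[:, None]
        Kd = np.einsum("eq,eq,eqai,eqbi->eab", wJ, Dii, dNdx, dNdx)
        if p.use_streamline:
            vnorm = np.linalg.norm(vel, axis=-1)
            tau = h_sp[:, None] / (2.0 * vnorm + 1e-12)
            tau = np.where(vnorm > 1e-10, tau, 0.0)
            Kd += np.einsum(
                "eq,eq,eqai,eqi,eqbj,eqj->eab", wJ, tau, dNdx, vel, dNdx, vel
            )
        # advection (integrated by parts; natural zero-flux boundary)
        Ka = -np.einsum("eq,eqai,eqi,qb->eab", wJ, dNdx, vel, _NQ)

        A = M.multiply(1.0 / dt) + ops.assemble_scalar_matrix(Kd + Ka)
        b = Mold.dot(c_old) / dt + f
        c = spla.spsolve(A.tocsc(), b)

    diag = TransportDiagnostics()
    neg = np.minimum(c, 0.0)
    if np.any(neg < 0):
        lump = ops.lumped_mass(J_qp)
        diag.clipped_mass = float(-(lump * neg).sum())
        c = np.maximum(c, 0.0)
    diag.total_cells = float(ops.integrate(ops.interp_scalar(c) * J_qp))
    diag.max_density = float(c.max(initial=0.0))
    diag.max_artificial_viscosity = nu_max
    return c, diag
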