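"""Constitutive laws for growing brain tissue.

Implements the material side of the two-field model: a compressible
neo-Hookean energy under plane strain, a cell-density-dependent cortical
shear modulus with a smooth cortex/subcortex transition, and an
anisotropic, irreversible growth tensor whose multipliers are driven by
the local cell density.

All tensor-valued functions are written for batched input: arrays of
shape ``(..., 2, 2)`` (plane-strain in-plane part) or ``(..., 3, 3)``
are accepted wherever a deformation tensor is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "MaterialParams",
    "GrowthState",
    "smooth_heaviside",
    "cortical_shear_modulus",
    "shear_modulus_profile",
    "lame_lambda",
    "growth_factors",
    "growth_multipliers",
    "growth_tensor",
    "elastic_part",
    "strain_energy",
    "cauchy_stress",
    "first_piola_elastic",
    "elastic_moduli",
    "update_growth_state",
]


def smooth_heaviside(x, gamma):
    """Logistic step ``H(x; gamma) = e^{gamma x} / (1 + e^{gamma x})``.

    Overflow-safe for large ``|gamma * x|``; satisfies ``H(0) = 0.5`` and
    ``H(x) + H(-x) = 1``.
    """
    return expit(np.multiply(gamma, x))


@dataclass(frozen=True)
class MaterialParams:
    """Mechanical and growth parameters of the tissue.

    ``stiffness_mode`` selects between a cortex whose shear modulus tracks
    the local cell density ("varying") and a constant cortical stiffness
    ("constant", the classical bilayer limit).
    """

    mu_inf: float = 2.07          # saturated cortical shear modulus, kPa
    poisson_nu: float = 0.38      # Poisson ratio (held fixed everywhere)
    beta_mu: float = 3.0          # stiffness ratio mu_inf / mu_s
    c_max: float = 700.0          # density at which mu_c saturates, mm^-2
    c_min: float = 200.0          # density below which mu_c = mu_s, mm^-2
    kappa_s: float = 4.07e-4      # subcortical growth factor, mm^2
    alpha: float = 1.65           # growth exponent
    beta_kappa: float = 3.0       # cortical growth anisotropy ratio
    stiffness_mode: str = "varying"

    def __post_init__(self):
        if self.mu_inf <= 0:
            raise ValueError("mu_inf must be positive")
        if not 0 < self.poisson_nu < 0.5:
            raise ValueError("poisson_nu must lie in (0, 0.5)")
        if self.beta_mu < 1:
            raise ValueError("beta_mu must be >= 1")
        if not self.c_max > self.c_min >= 0:
            raise ValueError("require c_max > c_min >= 0")
        if self.kappa_s < 0:
            raise ValueError("kappa_s must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta_kappa < 1:
            raise ValueError("beta_kappa must be >= 1")
        if self.stiffness_mode not in ("constant", "varying"):
            raise ValueError("stiffness_mode must be 'constant' or 'varying'")

    @property
    def mu_s(self) -> float:
        """Subcortical shear modulus mu_inf / beta_mu, kPa."""
        return self.mu_inf / self.beta_mu

    @property
    def m_c(self) -> float:
        """Slope of the density->stiffness ramp, kPa mm^2."""
        return (self.mu_inf - self.mu_s) / (self.c_max - self.c_min)

    def with_(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


def cortical_shear_modulus(c, p: MaterialParams):
    """Cortical shear modulus mu_c(c), kPa.

    Constant mode returns mu_inf regardless of density. Varying mode is a
    continuous piecewise-linear ramp from mu_s (c <= c_min) to mu_inf
    (c >= c_max).
    """
    c = np.asarray(c, dtype=float)
    if p.stiffness_mode == "constant":
        return np.broadcast_to(np.float64(p.mu_inf), c.shape).copy()
    ramp = p.mu_s + p.m_c * (c - p.c_min)
    return np.clip(ramp, p.mu_s, p.mu_inf)


def shear_modulus_profile(ri, c, p: MaterialParams, r_cp: float = 1.8):
    """Shear modulus mu(ri, c): mu_s in the subcortex blending to mu_c(c)
    in the cortex via the logistic step at the material cortex radius."""
    muc = cortical_shear_modulus(c, p)
    h = smooth_heaviside(np.asarray(ri, dtype=float) - r_cp, 20.0)
    return p.mu_s + (muc - p.mu_s) * h


def lame_lambda(mu, nu):
    """First Lame parameter from the shear modulus and Poisson ratio."""
    nu = np.asarray(nu, dtype=float)
    if np.any(nu >= 0.5):
        raise ValueError("nu must be < 0.5")
    return 2.0 * np.asarray(mu, dtype=float) * nu / (1.0 - 2.0 * nu)


def growth_factors(ri, p: MaterialParams, r_cp: float = 1.8):
    """Radial profiles of the growth factors (kappa_perp, kappa_par).

    Deep subcortex: isotropic (kappa_s, kappa_s). Cortex: tangentially
    biased (kappa_s * beta_kappa, kappa_s / beta_kappa); smooth logistic
    transition at r_cp.
    """
    h = smooth_heaviside(np.asarray(ri, dtype=float) - r_cp, 20.0)
    k_perp = p.kappa_s + p.kappa_s * (p.beta_kappa - 1.0) * h
    k_par = p.kappa_s + p.kappa_s * (1.0 / p.beta_kappa - 1.0) * h
    return k_perp, k_par


def growth_multipliers(c, kappa_perp, kappa_par, alpha):
    """Density-driven growth multipliers (theta_perp, theta_par) =
    ((1 + kappa c)^alpha) in each direction; both 1 at zero density."""
    c = np.asarray(c, dtype=float)
    tp = np.power(1.0 + np.asarray(kappa_perp) * c, alpha)
    tl = np.power(1.0 + np.asarray(kappa_par) * c, alpha)
    return tp, tl


def growth_tensor(theta_perp, theta_par, N):
    """Growth tensor Fg = theta_perp [I - N (x) N] + theta_par N (x) N.

    ``N`` is the unit radial fiber direction in the reference
    configuration; broadcasting over leading axes is supported.
    """
    N = np.asarray(N, dtype=float)
    nrm = np.linalg.norm(N, axis=-1)
    if not np.allclose(nrm, 1.0, atol=1e-8):
        raise ValueError("fiber direction N must be a unit vector")
    d = N.shape[-1]
    eye = np.eye(d)
    NN = N[..., :, None] * N[..., None, :]
    tp = np.asarray(theta_perp, dtype=float)[..., None, None]
    tl = np.asarray(theta_par, dtype=float)[..., None, None]
    return tp * (eye - NN) + tl * NN


def elastic_part(F, Fg):
    """Elastic deformation Fe = F Fg^{-1} from the multiplicative split."""
    detg = np.linalg.det(Fg)
    if np.any(detg <= 0):
        raise ValueError("growth tensor must have positive determinant")
    return F @ np.linalg.inv(Fg)


def _plane_strain_trace(Fe):
    """Fe : Fe with the out-of-plane unit stretch included for 2x2 input."""
    d = Fe.shape[-1]
    tr = np.einsum("...ij,...ij->...", Fe, Fe)
    if d == 2:
        tr = tr + 1.0
    return tr


def strain_energy(Fe, mu, lam):
    """Neo-Hookean energy density psi = lam/2 ln^2(Je) + mu/2 (Fe:Fe - 3
    - 2 ln Je), with 2x2 input embedded as plane strain."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be positive")
    lnJ = np.log(Je)
    return 0.5 * np.asarray(lam) * lnJ ** 2 + 0.5 * np.asarray(mu) * (
        _plane_strain_trace(Fe) - 3.0 - 2.0 * lnJ
    )


def first_piola_elastic(Fe, mu, lam):
    """dpsi/dFe = lam ln(Je) Fe^{-T} + mu (Fe - Fe^{-T})."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be positive")
    FeinvT = np.swapaxes(np.linalg.inv(Fe), -1, -2)
    lnJ = np.log(Je)[..., None, None]
    mu = np.asarray(mu, dtype=float)[..., None, None]
    lam = np.asarray(lam, dtype=float)[..., None, None]
    return lam * lnJ * FeinvT + mu * (Fe - FeinvT)


def cauchy_stress(Fe, mu, lam):
    """Cauchy stress sigma = (1/Je)[lam ln(Je) I + mu (Fe Fe^T - I)].

    Returns the in-plane 2x2 block for 2x2 input (plane strain); the
    out-of-plane component is ``lam ln(Je) / Je``.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be positive")
    d = Fe.shape[-1]
    Be = Fe @ np.swapaxes(Fe, -1, -2)
    lnJ = np.log(Je)[..., None, None]
    mu = np.asarray(mu, dtype=float)[..., None, None]
    lam = np.asarray(lam, dtype=float)[..., None, None]
    return (lam * lnJ * np.eye(d) + mu * (Be - np.eye(d))) / Je[..., None, None]


def elastic_moduli(Fe, mu, lam):
    """Consistent tangent A_iJkL = d(dpsi/dFe_iJ)/dFe_kL.

    A = lam Fe^{-T} (x) Fe^{-T} + (mu - lam lnJe) Fe^{-T}_iL Fe^{-T}_kJ
        + mu delta_ik delta_JL
    """
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    FeinvT = np.swapaxes(np.linalg.inv(Fe), -1, -2)
    lnJ = np.log(Je)
    d = Fe.shape[-1]
    eye = np.eye(d)
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    A = (
        lam[..., None, None, None, None]
        * np.einsum("...iJ,...kL->...iJkL", FeinvT, FeinvT)
        + (mu - lam * lnJ)[..., None, None, None, None]
        * np.einsum("...iL,...kJ->...iJkL", FeinvT, FeinvT)
        + mu[..., None, None, None, None]
        * np.einsum("ik,JL->iJkL", eye, eye)
    )
    return A


@dataclass
class GrowthState:
    """Irreversible growth multipliers per quadrature point."""

    theta_perp: np.ndarray
    theta_par: np.ndarray

    def __post_init__(self):
        self.theta_perp = np.asarray(self.theta_perp, dtype=float)
        self.theta_par = np.asarray(self.theta_par, dtype=float)
        if self.theta_perp.shape != self.theta_par.shape:
            raise ValueError("theta fields must share a shape")

    def copy(self) -> "GrowthState":
        return GrowthState(self.theta_perp.copy(), self.theta_par.copy())


def update_growth_state(prev: GrowthState, proposed: GrowthState) -> GrowthState:
    """Ratchet: componentwise max of previous and proposed multipliers.

    Growth is irreversible; the algebraic law theta(c) would shrink if the
    density dropped, so the stored state only ever increases.
    """
    if prev.theta_perp.shape != proposed.theta_perp.shape:
        raise ValueError("growth states live on different point sets")
    return GrowthState(
        np.maximum(prev.theta_perp, proposed.theta_perp),
        np.maximum(prev.theta_par, proposed.theta_par),
    )
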