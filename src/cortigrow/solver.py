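"""Quasi-static staggered time integration of the coupled two-field model.

Each step advances the cell density by one implicit-Euler substep on the
frozen mechanics, converts the new density into proposed growth
multipliers (passed through the irreversibility ratchet), and re-solves
mechanical equilibrium by Newton iteration. On Newton failure the step
is subdivided. All randomness (the symmetry-breaking boundary
perturbation, random heterogeneity sectors) is routed through the config
seed, so trajectories are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constitutive as con
from . import transport as tr
from .fem import FemOperators, dirichlet_dofs, newton_solve, deformation_gradient
from .geometry import (
    GeometryParams,
    Mesh,
    apply_boundary_perturbation,
    build_quarter_annulus,
)
from .morphometrics import (
    MorphoTrace,
    SurfaceTrace,
    all_sulcus_depths,
    trace_self_intersects,
)

__all__ = ["SolverConfig", "SimulationState", "StepFailure", "initialize", "step", "run"]


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping, Newton, coupling and discretization controls."""

    dt: float = 0.25                # days
    t_end: float = 175.0            # days (GW11 -> GW36)
    newton_tol: float = 1e-8        # relative residual
    newton_max_iter: int = 25
    coupling: str = "staggered"     # or "staggered_iterated"
    coupling_iters: int = 2         # sweeps for staggered_iterated
    max_subdivisions: int = 8
    checkpoint_every: int = 50      # steps between stored checkpoints
    n_radial: int = 40
    n_circumferential: int = 80
    perturb_amplitude: float = 0.002   # mm, 0.1% of R
    perturb_modes: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if self.coupling not in ("staggered", "staggered_iterated"):
            raise ValueError("coupling must be staggered or staggered_iterated")

    def with_(self, **kw) -> "SolverConfig":
        return replace(self, **kw)


class StepFailure(RuntimeError):
    """Newton failed to converge after all subdivisions."""


@dataclass
class SimulationState:
    """Full simulation state at one instant."""

    time: float
    u: np.ndarray                 # nodal displacement (n, 2)
    c: np.ndarray                 # nodal density (n,)
    growth: con.GrowthState       # ratcheted multipliers per qp (ne, nq)
    mesh: Mesh
    geom: GeometryParams
    J_qp: np.ndarray              # det F at qps of last accepted step
    s: float = 1.0                # lagged maximum stretch

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.time, self.u.copy(), self.c.copy(), self.growth.copy(),
            self.mesh, self.geom, self.J_qp.copy(), self.s,
        )


def initialize(
    geom: GeometryParams,
    solver: SolverConfig,
) -> tuple[SimulationState, FemOperators]:
    """Build the (perturbed) mesh and the initial zero-density state."""
    mesh = build_quarter_annulus(geom, solver.n_radial, solver.n_circumferential)
    mesh = apply_boundary_perturbation(
        mesh, solver.perturb_amplitude, solver.perturb_modes, solver.seed, geom
    )
    ops = FemOperators.build(mesh)
    ne, nq = ops.wdetJ.shape
    growth = con.GrowthState(np.ones((ne, nq)), np.ones((ne, nq)))
    state = SimulationState(
        time=0.0,
        u=np.zeros_like(mesh.nodes),
        c=np.zeros(mesh.n_nodes),
        growth=growth,
        mesh=mesh,
        geom=geom,
        J_qp=np.ones((ne, nq)),
        s=1.0,
    )
    return state, ops


def _material_fields(ops, c_nodal, mat: con.MaterialParams, geom: GeometryParams):
    """Quadrature-point shear modulus and Lame lambda from nodal density."""
    c_qp = np.maximum(ops.interp_scalar(c_nodal), 0.0)
    mu = con.shear_modulus_profile(ops.qp_ri, c_qp, mat, geom.r_cp)
    lam = con.lame_lambda(mu, mat.poisson_nu)
    return c_qp, mu, lam


def _proposed_growth(ops, c_qp, mat: con.MaterialParams, geom: GeometryParams):
    kp, kl = con.growth_factors(ops.qp_ri, mat, geom.r_cp)
    tp, tl = con.growth_multipliers(c_qp, kp, kl, mat.alpha)
    return con.GrowthState(tp, tl)


def step(
    state: SimulationState,
    ops: FemOperators,
    dt: float,
    mat: con.MaterialParams,
    trans: tr.TransportParams,
    solver: SolverConfig,
    fixed_dofs: np.ndarray | None = None,
):
    """One staggered step; returns (new_state, diagnostics dict).

    Raises :class:`StepFailure` if the mechanics Newton loop does not
    converge (caller may subdivide dt).
    """
    if fixed_dofs is None:
        fixed_dofs = dirichlet_dofs(state.mesh)
    t_new = state.time + dt
    sweeps = solver.coupling_iters if solver.coupling == "staggered_iterated" else 1

    u = state.u
    c = state.c
    growth = state.growth
    diag = None
    for _ in range(max(1, sweeps)):
        F_qp = deformation_gradient(ops, u)
        c, diag = tr.step_density(
            ops, state.c, dt, t_new, F_qp, state.J_qp, state.s, trans, state.geom
        )
        c_qp, mu, lam = _material_fields(ops, c, mat, state.geom)
        growth = con.update_growth_state(
            state.growth, _proposed_growth(ops, c_qp, mat, state.geom)
        )
        u, ok, n_it, res = newton_solve(
            ops, u, mu, lam, growth.theta_perp, growth.theta_par,
            fixed_dofs=fixed_dofs, tol=solver.newton_tol,
            max_iter=solver.newton_max_iter,
        )
        if not ok:
            raise StepFailure(f"Newton stalled at t={t_new:.3f} (res={res:.3e})")

    F_new = deformation_gradient(ops, u)
    new = SimulationState(
        time=t_new, u=u, c=c, growth=growth, mesh=state.mesh, geom=state.geom,
        J_qp=np.linalg.det(F_new), s=tr.max_stretch(F_new),
    )
    info = {
        "newton_iters": n_it,
        "residual": res,
        "clipped_mass": diag.clipped_mass,
        "total_cells": diag.total_cells,
        "max_density": diag.max_density,
        "max_artificial_viscosity": diag.max_artificial_viscosity,
    }
    return new, info


def outer_trace(state: SimulationState) -> SurfaceTrace:
    """Deformed outer-boundary polyline, ordered along the boundary."""
    idx = state.mesh.boundary["outer"]
    return SurfaceTrace(state.mesh.nodes[idx] + state.u[idx])


def run(
    geom: GeometryParams,
    mat: con.MaterialParams,
    trans: tr.TransportParams,
    solver: SolverConfig,
    callback=None,
):
    """Integrate from GW11 (t = 0) to ``solver.t_end``.

    Returns ``(state, morpho, checkpoints, events)``: the final state,
    the metric time series, a list of checkpointed states, and an event
    log (dt subdivisions, clipping totals). ``callback(state, info)`` is
    invoked after every accepted step, and may return True to stop the
    run early (used by stop-at-instability experiments).
    """
    state, ops = initialize(geom, solver)
    fixed = dirichlet_dofs(state.mesh)
    trace0 = outer_trace(state)
    perim0 = trace0.length

    morpho = MorphoTrace()
    checkpoints = [state.copy()]
    events = []
    total_clipped = 0.0

    n_accepted = 0
    while state.time < solver.t_end - 1e-12:
        dt = min(solver.dt, solver.t_end - state.time)
        level = 0
        while True:
            try:
                new_state, info = step(state, ops, dt, mat, trans, solver, fixed)
                break
            except StepFailure as exc:
                level += 1
                if level > solver.max_subdivisions:
                    events.append(
                        {"t": state.time, "event": "abort", "detail": str(exc)}
                    )
                    return state, morpho, checkpoints, events
                dt *= 0.5
                events.append(
                    {"t": state.time, "event": "dt_subdivision", "dt": dt}
                )
        state = new_state
        n_accepted += 1
        total_clipped += info["clipped_mass"]

        trace = outer_trace(state)
        depths = all_sulcus_depths(trace)
        morpho.append(
            state.time,
            trace.length / perim0,
            info["max_density"],
            state.s,
            depths,
        )
        if n_accepted % max(1, solver.checkpoint_every) == 0:
            checkpoints.append(state.copy())
        if trace_self_intersects(trace):
            events.append({"t": state.time, "event": "self_contact"})
            break
        if callback is not None and callback(state, info):
            events.append({"t": state.time, "event": "early_stop"})
            break

    events.append({"t": state.time, "event": "finished", "clipped_mass": total_clipped})
    morpho.events = events
    return state, morpho, checkpoints, events
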