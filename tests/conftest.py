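"""Shared session-scoped simulation fixtures.

The acceptance trend suite and several solver-level tests consume full
folding runs. Runs are expensive, so each configuration is simulated
once per session at a fixed reduced resolution (16 x 64 elements,
dt = 0.5 d, seed 1) chosen a priori to resolve the expected wrinkling
wavelength (~1.7 mm) with >20 surface elements while keeping the whole
suite inside its time budget.
"""

import dataclasses

import numpy as np
import pytest

from cortigrow.constitutive import MaterialParams
from cortigrow.geometry import GeometryParams
from cortigrow.morphometrics import SurfaceTrace, all_sulcus_depths
from cortigrow.solver import SolverConfig, outer_trace, run
from cortigrow.transport import HeterogeneityPattern, TransportParams

N_RADIAL = 16
N_CIRC = 64
DT = 0.5
SEED = 1


@dataclasses.dataclass
class RunResult:
    state: object
    morpho: object
    checkpoints: list
    events: list
    first_fold_trace: SurfaceTrace | None  # surface when folds first appear

    @property
    def trace(self) -> SurfaceTrace:
        return outer_trace(self.state)

    def at_time(self, t: float) -> int:
        """Index of the recorded step closest to time t."""
        times = np.asarray(self.morpho.times)
        return int(np.argmin(np.abs(times - t)))


def simulate(
    mat: MaterialParams,
    trans: TransportParams,
    t_end: float = 175.0,
    stop_depth: float | None = None,
    stop_density: float | None = None,
):
    geom = GeometryParams()
    solver = SolverConfig(
        dt=DT, t_end=t_end, n_radial=N_RADIAL, n_circumferential=N_CIRC, seed=SEED
    )
    first_fold = {"trace": None}

    def cb(state, info):
        if first_fold["trace"] is None:
            d = all_sulcus_depths(outer_trace(state))
            if len(d) and d.max() > 0.01:
                first_fold["trace"] = outer_trace(state)
        if stop_depth is not None:
            d = all_sulcus_depths(outer_trace(state))
            if len(d) and d.max() > stop_depth:
                return True
        if stop_density is not None and info["max_density"] >= stop_density:
            return True
        return False

    state, morpho, cps, events = run(geom, mat, trans, solver, callback=cb)
    return RunResult(state, morpho, cps, events, first_fold["trace"])


@pytest.fixture(scope="session")
def varying_runs():
    """Varying-stiffness Gvz = 120 sweep over Gosvz (headline runs)."""
    out = {}
    for go in (0, 10, 20, 30):
        out[go] = simulate(
            MaterialParams(stiffness_mode="varying", beta_mu=3.0),
            TransportParams(G_vz=120.0, G_osvz=float(go)),
        )
    return out


@pytest.fixture(scope="session")
def constant_run():
    """Constant-stiffness bilayer (beta_mu = 8), stopped just after the
    primary wrinkling instability for the wavelength measurement."""
    return simulate(
        MaterialParams(stiffness_mode="constant", beta_mu=8.0),
        TransportParams(G_vz=120.0, G_osvz=20.0),
        stop_depth=0.02,
    )


@pytest.fixture(scope="session")
def tradeoff_runs():
    """VZ/OSVZ tradeoff pair, run to a common late time at which the
    expanding OSVZ dominates the density budget."""
    out = {}
    for gvz, go in ((120.0, 0.0), (30.0, 30.0)):
        out[(gvz, go)] = simulate(
            MaterialParams(),
            TransportParams(G_vz=gvz, G_osvz=go),
            t_end=25.0,
        )
    return out


@pytest.fixture(scope="session")
def mst_runs():
    """MST-speed pair (same rates, different OSVZ expansion speed)."""
    out = {}
    for m in (0.01, 0.04):
        geom = GeometryParams(m_mst=m)
        solver = SolverConfig(
            dt=DT, t_end=20.0, n_radial=N_RADIAL, n_circumferential=N_CIRC,
            seed=SEED,
        )
        state, morpho, cps, ev = run(
            geom, MaterialParams(), TransportParams(G_vz=30.0, G_osvz=30.0), solver
        )
        out[m] = RunResult(state, morpho, cps, ev, None)
    return out


@pytest.fixture(scope="session")
def hetero_runs():
    """Heterogeneous-OSVZ pair (gradient vs random sectors)."""
    out = {}
    for kind in ("circumferential_gradient", "random_sectors"):
        out[kind] = simulate(
            MaterialParams(),
            TransportParams(
                G_vz=120.0,
                G_osvz=20.0,
                heterogeneity=HeterogeneityPattern(kind=kind, seed=SEED),
            ),
        )
    return out
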