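"""A single folding run at reduced resolution (~20 s on one CPU).

Simulates the varying-stiffness case with G_vz = 120, G_osvz = 20 on a
16 x 64 mesh and prints the metric timeline: folding evolution, maximum
cell density, number of sulci, and the detected instability times. The
run stops automatically when sulcal walls touch (self-contact is not
modeled).
"""

from cortigrow.constitutive import MaterialParams
from cortigrow.geometry import GeometryParams
from cortigrow.morphometrics import detect_instability_points
from cortigrow.solver import SolverConfig, run
from cortigrow.transport import TransportParams

state, morpho, checkpoints, events = run(
    GeometryParams(),
    MaterialParams(stiffness_mode="varying", beta_mu=3.0),
    TransportParams(G_vz=120.0, G_osvz=20.0),
    SolverConfig(dt=0.5, t_end=175.0, n_radial=16, n_circumferential=64, seed=1),
)

print(f"{'t [d]':>6} {'GW':>5} {'fold. evol.':>11} {'c_max':>7} {'n_sulci':>7}")
for i in range(0, len(morpho.times), 10):
    t = morpho.times[i]
    print(
        f"{t:6.1f} {11 + t / 7:5.1f} {morpho.folding_evolution[i]:11.4f} "
        f"{morpho.max_density[i]:7.1f} {len(morpho.sulcus_depths[i]):7d}"
    )

t_primary, t_secondary = detect_instability_points(morpho)
print(f"\nprimary instability (wrinkling)      : t = {t_primary} d")
print(f"secondary instability (period doubling): t = {t_secondary} d")
print(f"run ended at t = {state.time:.1f} d with event '{events[-2]['event'] if len(events) > 1 else events[-1]['event']}'")
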