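# cortigrow

A two-field finite-element simulator of fetal cortical folding in 2D.
The model couples quasi-static finite-growth hyperelasticity of the
developing brain slab to an advection–diffusion–reaction equation for
the neural cell density, with two proliferative zones: the ventricular
zone (VZ) at the ventricle and the outer subventricular zone (OSVZ),
whose outward expansion tracks the mitotic somal translocation (MST) of
outer radial glia cells. Cells divide in the two zones, migrate outward
along deformed radial fibers once the local density exceeds a
threshold, and accumulate in the cortical plate; density-driven
anisotropic growth of the cortex then triggers mechanical wrinkling and
period-doubling instabilities — the onset of gyrification.

## Model in brief

* **Domain** — a quarter annulus (ventricular radius 0.4 mm, outer
  radius 2 mm) meshed with bilinear quadrilaterals; symmetry conditions
  on the straight edges, fixed ventricular surface, traction-free outer
  surface with a seeded sub-element perturbation that breaks the
  rotational symmetry reproducibly.
* **Mechanics** — compressible neo-Hookean plane strain, multiplicative
  split `F = Fe·Fg`. The growth tensor
  `Fg = θ⊥(I − N⊗N) + θ∥ N⊗N` is driven by the local cell density,
  `θ = (1 + κ c)^α`, tangentially biased in the cortex and isotropic in
  the subcortex, and ratcheted so growth is irreversible. Cortical
  stiffness either scales with density between 0.69 and 2.07 kPa
  ("varying", stiffness ratio 3) or stays constant (ratio 8).
* **Cell transport** — implicit-Euler FEM for
  `∂c/∂t + c∇·v_g + ∇·(c v_m) = ∇·(d∇c) + r`, with division sources in
  the VZ and the expanding OSVZ band, stretch-modulated division rates
  (linearly down to 20% of the initial rate), threshold-gated outward
  migration, and SUPG plus residual-based artificial viscosity capped
  by the first-order upwind viscosity. Total cell number is conserved
  to round-off when sources are off.
* **Coupling** — staggered: density step on frozen mechanics, then a
  Newton solve of mechanical equilibrium with the updated growth field.
  Runs stop automatically when sulcal walls touch; self-contact is not
  modeled.
* **Morphometrics** — folding evolution (perimeter ratio), per-sulcus
  depths, primary/secondary instability times, intersulcal distances,
  normalized radial density profiles, OSVZ thickness under gyri vs
  sulci.

## Worked example

A reduced-resolution folding run (16 × 64 elements, Δt = 0.5 d, about
20 s on one CPU):

```python
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
```

Output of `python examples/02_single_folding_run.py`, which prints the
metric timeline of exactly this run:

```
 t [d]    GW fold. evol.   c_max n_sulci
   0.5  11.1      1.0009    27.0       0
   5.5  11.8      1.0116    63.6       0
  10.5  12.5      1.0270    63.5       0
  15.5  13.2      1.0479    84.9       0
  20.5  13.9      1.0721   178.4       1
  25.5  14.6      1.1021   322.4       2

primary instability (wrinkling)      : t = 22.5 d
secondary instability (period doubling): t = 27.5 d
run ended at t = 28.2 d with event 'self_contact'
```

Sweeping the OSVZ division rate (`python examples/03_osvz_rate_sweep.py`)
shows the central result — outer radial glia proliferation accelerates
cortical densification and folding:

```
G_osvz c_max(t=25)  fe(t=25) t_primary mean d [mm]
     0       128.8    1.0526      34.0       1.397
    10       206.1    1.0745      25.5       1.407
    20       304.6    1.0985      22.5       1.418
    30       428.7    1.2366      20.5       1.424
```

## Command line

```bash
cortigrow run --preset varying_g120_o20 --seed 1 --out out/ --vtk-every 10
cortigrow resume --checkpoint out/checkpoint_final.npz --t-end 40
cortigrow metrics --trajectory out/ --out metrics.csv
cortigrow profile --state out/checkpoint_final.npz --angle 45 --out profile.csv
```

Presets cover the varying/constant stiffness cases for
`G_osvz ∈ {0, 10, 20, 30}`, the VZ/OSVZ tradeoff pairs, the MST sweep
and two heterogeneous-proliferation patterns (`cortigrow run --help`;
see `src/cortigrow/io.py` for the list). YAML config files override any
preset field and are validated with exact error locations.

## Reproduction

`python scripts/acceptance.py --seed 1 --out results.json` runs the
four headline configurations at 40 × 80 resolution (about 7 min total)
and writes the main computed quantities (intersulcal distances for
`G_osvz ∈ {0, 10, 20}`, final max density and folding evolution for
`G_osvz = 30`, primary-instability times) to JSON.

The acceptance test suite (`tests/test_acceptance.py`) encodes the full
criteria set. Two documented sub-criteria fail honestly at this scale
and are analyzed in `docs/methods.md` § Limitations: the intersulcal
distance does not decrease with `G_osvz` because runs stop at sulcal
self-contact before fold insertion, and first folds nucleate in
low-rate (compliant) sectors rather than high-rate ones.

## Layout

- `src/cortigrow/` — geometry, constitutive, transport, fem, solver,
  morphometrics, io, cli
- `tests/` — unit/oracle tests plus the acceptance suite
- `examples/` — narrative scripts (constitutive curves, single run,
  rate sweep, radial profile, heterogeneity)
- `docs/methods.md` — model equations, parameters, numerical methods,
  limitations
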