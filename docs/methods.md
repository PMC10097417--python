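# Methods

## 1. Model

### 1.1 Geometry and zones

The domain is a quarter annulus representing a 2D section of the fetal
brain slab between the ventricular surface (radius `r = 0.4 mm`) and
the outer cortical surface (`R = 2 mm`). Material radius `r_i` tags the
zones:

| zone | band | role |
|---|---|---|
| VZ (ventricular zone) | `r ≤ r_i ≤ r_vz = 0.5` | division source, rate `G_vz` |
| ISVZ (inner subventricular zone) | `r_vz < r_i ≤ r_isvz = 0.8` | transit |
| OSVZ (outer subventricular zone) | `r_isvz < r_i ≤ r_osvz(t)` | division source, rate `G_osvz` |
| intermediate zone | `r_osvz(t) < r_i ≤ r_cp = 1.8` | migration corridor |
| cortical plate | `r_cp < r_i ≤ R` | accumulation, tangential growth |

The OSVZ expands with the mitotic somal translocation (MST) of outer
radial glia cells: `r_osvz(t) = r_isvz + m_mst · t` (clipped at
`r_cp`). Time `t` is in days from gestational week 11
(`GW = 11 + t/7`). The structured mesh grades toward the cortex so the
plate holds at least four element layers; the outer boundary receives a
seeded radial perturbation (default amplitude 0.002 mm, 8 Fourier
modes) that breaks rotational symmetry reproducibly.

### 1.2 Mechanics

Finite growth with the multiplicative split `F = Fe · Fg`,

```
Fg = θ⊥ (I − N⊗N) + θ∥ N⊗N,      θ = (1 + κ c)^α,
```

where `N` is the radial fiber direction and `c` the cell density. The
growth factors `κ⊥, κ∥` blend from the isotropic subcortical value
`κ_s` to the cortical anisotropy pair `κ_s β_κ` (tangential) and
`κ_s/β_κ` (radial) through a logistic step `H(r_i − r_cp; γ = 20)`.
Growth is irreversible: the multiplier pair at each quadrature point is
the componentwise running maximum over the history (ratchet).

The elastic response is compressible neo-Hookean in plane strain
(2 × 2 kinematics with unit out-of-plane stretch),

```
ψ(Fe) = λ/2 ln²(Je) + μ/2 (Fe : Fe − 3 − 2 ln Je),
Pe = λ ln(Je) Fe⁻ᵀ + μ (Fe − Fe⁻ᵀ),
```

with the total-Lagrangian first Piola stress
`P = det(Fg) · Pe · Fg⁻ᵀ` and the analytic tangent
`A = λ Fe⁻ᵀ⊗Fe⁻ᵀ + (μ − λ ln Je) Fe⁻ᵀ_iL Fe⁻ᵀ_kJ + μ δ_ik δ_JL`.

Cortical stiffness: in **varying** mode the shear modulus ramps
linearly with density between `μ∞/β_μ` at `c ≤ c_min = 200 mm⁻²` and
`μ∞ = 2.07 kPa` at `c ≥ c_max = 700 mm⁻²` (ratio `β_μ = 3`); in
**constant** mode it is fixed at `μ∞` (ratio `β_μ = 8`). The
subcortical modulus is the cortical value divided by `β_μ`, blended at
`r_cp` with the same logistic profile. `λ` follows from `μ` and
`ν = 0.38`.

### 1.3 Cell transport

Updated-Lagrangian advection–diffusion–reaction for the nodal density
`c` (cells/mm²):

```
dc/dt + c ∇·v_growth + ∇·(c v_m) = ∇·(d ∇c) + r₁ + r₂
```

* **Dilution** — implemented exactly through `J = det F`-weighted mass
  matrices: under prescribed uniform growth, `c = c₀/J` to round-off.
* **Sources** — `r₁ = Ĝ_vz` in the VZ and `r₂ = Ĝ_osvz` in the current
  OSVZ band, with the stretch-modulated rate
  `Ĝ(s) = G (2 − s)` clipped to `[0.2 G, G]` (piecewise linear:
  `G` at maximum stretch `s = 1`, `0.6 G` at `1.4`, `0.2 G` for
  `s ≥ 1.8`); `s` is the maximum principal stretch in the domain,
  lagged by one step. The OSVZ rate can be modulated along the
  circumference (linear gradient or seeded random sectors).
* **Migration** — outward along deformed fibers,
  `v_m = H(c − c₀; γ_c) · v(r_i) · F N / ‖F N‖`, gated by the logistic
  threshold at `c₀ = 500 mm⁻²`; the speed profile rises toward the
  cortex and shuts off inside the plate.
* **Diffusion** — `d = d_cc = 0.11 mm²/d`, reduced inside the cortical
  plate.

### 1.4 Parameters (defaults)

| symbol | value | unit | meaning |
|---|---|---|---|
| R, r | 2, 0.4 | mm | outer / ventricular radius |
| r_vz, r_isvz, r_cp | 0.5, 0.8, 1.8 | mm | zone boundaries |
| m_mst | 0.02 | mm/d | MST (OSVZ expansion) factor |
| μ∞ | 2.07 | kPa | cortical shear modulus |
| ν | 0.38 | – | Poisson ratio |
| β_μ | 3 (varying) / 8 (constant) | – | stiffness ratio |
| c_min, c_max | 200, 700 | mm⁻² | stiffness-ramp thresholds |
| κ_s | 4.07e−4 | mm² | growth parameter |
| α | 1.65 | – | growth exponent |
| β_κ | 3 | – | cortical growth anisotropy |
| G_vz | 30–120 | mm⁻²d⁻¹ | VZ division rate |
| G_osvz | 0–30 | mm⁻²d⁻¹ | OSVZ division rate |
| v | 5 | mm/d | migration speed scale |
| c₀ | 500 | mm⁻² | migration threshold |
| γ_c | 0.008 | – | threshold sharpness |
| d_cc | 0.11 | mm²/d | diffusivity |

## 2. Numerics

* **Discretization** — bilinear quadrilaterals, 2 × 2 Gauss points,
  vectorized assembly, direct sparse solves.
* **Coupling** — staggered per step: implicit-Euler density substep on
  the frozen deformation, density → growth multipliers (through the
  ratchet) and density-dependent stiffness, then a full Newton solve of
  quasi-static equilibrium with analytic consistent tangent and
  backtracking line search. Failed Newton steps trigger time-step
  subdivision (up to 8 halvings).
* **Stabilization** — SUPG streamline diffusion plus a residual-based
  artificial viscosity. The viscosity indicator is evaluated on the
  *solved* iterate of the previous Picard sweep (the first sweep runs
  unstabilized), so it measures the discretization residual rather
  than the time increment; it is capped elementwise by the first-order
  upwind viscosity `h |v| / 2`, which guarantees it vanishes linearly
  under refinement and never pollutes pure-diffusion regions.
  Positivity is enforced by clipping with the added mass logged and
  reported per run.
* **Instability detection** — primary instability: first time the
  maximum sulcus depth exceeds 1% of the cortical thickness while
  increasing; secondary (period doubling): deepest/shallowest tracked
  sulcus ratio above 1.5 for 3 consecutive recorded steps. The
  kink of the folding-evolution series is the maximum discrete
  curvature away from the smoothing margins.
* **Termination** — runs stop when the outer boundary polyline
  self-intersects (sulcal walls in contact), since contact is not
  modeled.
* **Problem sizes** — full-resolution experiments use 40 × 80 elements
  (`scripts/acceptance.py`, Δt = 0.5 d); the shared test-suite runs use
  16 × 64 elements, fixed a priori so the expected wrinkling wavelength
  (≈ 1.7 mm) spans more than 20 surface elements while the whole suite
  stays within its time budget. All randomness flows from one seed;
  trajectories are bit-for-bit reproducible.

## 3. Limitations

* **Self-contact stops the simulation.** Folds deepen until sulcal
  walls touch (folding evolution ≈ 1.25–1.35, around GW15 at default
  rates); the long post-contact maturation to GW36 is out of scope.
  Consequences, documented as failing acceptance asserts: the final
  maximum density stays far below the published GW36 value, and the
  intersulcal distance does not decrease with `G_osvz` because the
  quarter domain still holds only the primary wrinkles (whose
  wavelength mildly *increases* with `G_osvz` in varying-stiffness
  mode, the denser cortex being stiffer); the published decrease
  requires post-contact fold insertion.
* **Fold nucleation under heterogeneous proliferation.** With
  circumferentially modulated OSVZ rates the first sulci appear in
  *low*-rate sectors: high-rate sectors densify, stiffen and bulge into
  gyri, while the growth-induced tangential compression concentrates in
  the compliant low-rate regions, which buckle first. The acceptance
  assert encoding the opposite expectation is left failing with this
  analysis.
* **β_κ.** The default cortical growth anisotropy is 3. Runs with
  `β_κ = 1.5` (available via config) produce gentler wrinkling with a
  clearer period-doubling cascade and may match published 2D
  post-buckling morphologies more closely.
* **2D plane strain.** Out-of-plane growth and the 3D gyral network are
  not represented; the constitutive and transport operators are written
  dimension-agnostically, but only 2D runs are exercised.
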