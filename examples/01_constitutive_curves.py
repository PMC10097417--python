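"""Constitutive building blocks: stiffness ramp, growth law, division rates.

Prints the density-dependent cortical stiffness, the growth multipliers
and the stretch-modulated division rate at a few representative states.
Runs in well under a second.
"""

import numpy as np

from cortigrow.constitutive import (
    MaterialParams,
    cortical_shear_modulus,
    growth_factors,
    growth_multipliers,
)
from cortigrow.transport import stretch_modulated_rate

mat = MaterialParams(stiffness_mode="varying", beta_mu=3.0)

print("Cortical shear modulus mu_c(c) (varying stiffness, ratio 3):")
for c in (0.0, 200.0, 450.0, 700.0, 900.0):
    print(f"  c = {c:5.0f} mm^-2  ->  mu_c = {cortical_shear_modulus(c, mat):5.3f} kPa")

print("\nGrowth multipliers (theta_perp, theta_par) across the slab at c = 500:")
for ri, label in ((0.6, "subcortex"), (1.8, "cortical interface"), (1.95, "cortex")):
    kp, kl = growth_factors(np.array([ri]), mat)
    tp, tl = growth_multipliers(500.0, kp, kl, mat.alpha)
    print(
        f"  r_i = {ri:4.2f} mm ({label:18s}): "
        f"theta_perp = {tp[0]:6.4f}, theta_par = {tl[0]:6.4f}"
    )

print("\nStretch-modulated VZ division rate, G_vz = 120 mm^-2 d^-1:")
for s in (1.0, 1.2, 1.4, 1.6, 1.8, 2.2):
    print(f"  s = {s:3.1f}  ->  rate = {stretch_modulated_rate(120.0, s):6.1f}")
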