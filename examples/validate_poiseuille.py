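"""Validate the flow solver against Hagen-Poiseuille tube flow.

Solves pressure-driven flow of a blood-like fluid through a rigid tube
(R = 1 mm, L = 10 mm, 10 Pa drop) and compares centreline speed and the
axial pressure gradient with the closed-form laminar solution.
"""

import numpy as np

import tpmsflow as tf

R_MM, L_MM, DP_PA = 1.0, 10.0, 10.0

domain = tf.fixtures.make_tube(R_MM, L_MM, spacing_mm=0.1)
blood = tf.FluidProperties()  # 1060 kg/m^3, 0.005 Pa s
field = tf.solve_steady_flow(domain, blood, tf.BoundaryConditions(DP_PA, 0.0))

u_hp = DP_PA * (R_MM * 1e-3) ** 2 / (4 * blood.dynamic_viscosity * L_MM * 1e-3)
u_sim = field.speed().max()
print(f"converged in {field.iterations} iterations "
      f"(mass-flux imbalance {field.flux_imbalance:.1e})")
print(f"centreline speed: simulated {u_sim:.4f} m/s, analytic {u_hp:.4f} m/s "
      f"({100 * (u_sim / u_hp - 1):+.1f}%)")

_, _, profile = tf.wall_pressure_stats(field, domain)
slope = np.polyfit(np.arange(len(profile)), profile, 1)[0] / (domain.spacing * 1e-3)
print(f"wall-pressure gradient: {slope:.0f} Pa/m vs analytic {-DP_PA / (L_MM * 1e-3):.0f} Pa/m")
# agreement within a few percent confirms the no-slip walls, the pressure
# ports and the viscosity mapping of the lattice solver
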