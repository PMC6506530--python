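"""Solve the grip load case on one talon.

Protocol: the model is scaled to a reference surface area
(k = sqrt(SA_ref / SA_model)), fixed at the tip and the two cotyla apices,
and loaded with one digit's share of a 9.77 N grip force split over the
medial and lateral flexor-tubercle patches, acting along -z.
"""

import numpy as np

from talonmorph import TalonParams, grip_load_case, make_talon, solve_grip

_, talon, _ = make_talon(TalonParams(), (32, 16, 4))
case = grip_load_case(total_grip_force=9.77, n_digits=4)
print(f"per-digit force: {9.77 / 4:.4f} N "
      f"({9.77 / 8:.5f} N per tubercle patch, along -z)")

field, scaled = solve_grip(talon, case, reference_area=200.0)
print(f"scaled surface area: {scaled.surface_area():.4f} mm^2")
print(f"von Mises stress: max {field.vm_stress.max():.3f} MPa, "
      f"mean {field.vm_stress.mean():.3f} MPa")
residual = field.reactions.sum(axis=0) + [0, 0, -9.77 / 4]
print(f"reaction balance |sum R + F|: {np.linalg.norm(residual):.2e} N")
# The reactions at the restrained nodes balance the applied load exactly;
# stresses concentrate near the loaded tubercle and the restrained tip.
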