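"""Build one parametric talon: surface, tet mesh and 73 landmarks.

The talon is a tapered solid swept along a circular arc, with a ventral
flexor-tubercle bump and two cotyla depressions on the proximal face.
"""

from talonmorph import TalonParams, claw_curvature_angle, make_talon

params = TalonParams(arc_angle=110, length=21, tubercle_amplitude=1.5)
surface, volume, landmarks = make_talon(params, resolution=(32, 16, 4))

print(f"surface: {surface.n_vertices} vertices, {surface.n_faces} faces, "
      f"area {surface.area():.1f} mm^2, watertight={surface.is_watertight()}")
print(f"volume:  {volume.n_nodes} nodes, {volume.n_tets} tets, "
      f"min element volume {volume.tet_volumes().min():.2e} mm^3")
print(f"landmarks: {landmarks.n_points} "
      f"({sum(k == 'fixed' for k in landmarks.kind)} fixed + "
      f"{sum(k == 'semilandmark' for k in landmarks.kind)} semilandmarks)")
print(f"claw curvature (inner-curve tangent angle): "
      f"{claw_curvature_angle(landmarks):.1f} degrees")
# The curvature measure tracks the arc_angle parameter: more curved claws
# subtend a larger angle between the tangents at the inner-curve ends.
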