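"""Project the 3-D melanosome models and measure their silhouettes.

Builds the toroidal (melanoma-line) and ellipsoidal (melanocyte) particle
models, projects them face-on and edge-on, and runs the morphometry
operators on the binarised silhouettes.  The printed numbers should come
back close to the model parameters: 590 nm outer diameter, 330 nm hole and
170 nm thickness for the toroid; 710 x 280 nm for the ellipsoid.
"""

import toromorph as tm

toroid = tm.build_toroid()
face_on = tm.project_at_angle(toroid, tilt=0.0, pixel_size=4.0)
edge_on = tm.project_at_angle(toroid, tilt=90.0, pixel_size=4.0)

rec = tm.measure_particle(face_on.pixels > 0, pixel_size=4.0)
print(f"toroid face-on:  major axis {rec.major_nm:6.1f} nm (model: 590)")
print(f"toroid hole:     {tm.measure_hole(face_on.pixels > 0, 4.0):6.1f} nm (model: 330)")
rec = tm.measure_particle(edge_on.pixels > 0, pixel_size=4.0)
print(f"toroid edge-on:  thickness {rec.feret_min_nm:6.1f} nm (model: 170)")

ellipsoid = tm.build_ellipsoid()
proj = tm.project_at_angle(ellipsoid, tilt=0.0, pixel_size=8.0)
rec = tm.measure_particle(proj.pixels > 0, pixel_size=8.0)
print(f"ellipsoid:       {rec.major_nm:6.1f} x {rec.minor_nm:5.1f} nm (model: 710 x 280)")
print(f"ellipsoid circularity: {rec.circularity:.3f} (elongated, so well below 1)")
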