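"""Surface-to-volume prefactor vs aspect ratio for rods and coccoid cells.

The prefactor gamma = S/V^(2/3) is scale-free: it depends only on shape.
For a sphere it is 6^(2/3)*pi^(1/3) ~ 4.836; elongation raises it.
"""

from rodshape import geometry as geom

sphere = geom.GAMMA_SPHERE
print(f"sphere prefactor            gamma = {sphere:.4f}")

# rod-shaped cells cluster around gamma ~ 6.24 <-> aspect ratio ~ 4.1
eta = geom.eta_from_gamma_rod(6.24)
print(f"rod with gamma = 6.24  ->   eta   = {eta:.3f}   (length ~4x width)")
print(f"rod with eta = 4.14    ->   gamma = {geom.gamma_from_eta_rod(4.14):.3f}")

# coccoid cells are nearly spherical prolate spheroids
g_cocc = geom.gamma_from_eta_spheroid(1.38)
print(f"spheroid with eta = 1.38 -> gamma = {g_cocc:.3f}   (coccoid band)")

# a concrete cell: 4 um long, 1 um wide
shape = geom.RodShape(length=4.0, width=1.0)
S, V = geom.rod_surface(shape), geom.rod_volume(shape)
print(f"rod L=4, w=1 um:  S = {S:.3f} um^2,  V = {V:.3f} um^3,  "
      f"S/V^(2/3) = {S / V ** (2 / 3):.3f}")
print("Interpretation: a single dimensionless number separates rods (~6.2),")
print("coccoids (~4.9) and spheres (4.84) regardless of absolute size.")
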