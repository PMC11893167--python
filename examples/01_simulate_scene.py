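"""Build a synthetic mitochondrion scene and write it to standard formats.

Creates nested OMM/IMM meshes with three crista-junction wells, decorates
the outer membrane with 300 ribosomes (40% planted import-oriented), and
writes STL + label sidecar + a star-dialect particle table.
"""

from pathlib import Path

from mitomorph import decorate_particles, make_mitochondrion
from mitomorph.io import write_particles, write_surface

out = Path("scene_demo")
out.mkdir(exist_ok=True)

omm, imm, truth = make_mitochondrion(
    radius=3000.0,       # A; a ~0.6 um mitochondrion
    spacing=135.0,       # baseline OMM-IMM distance, A
    n_cj_wells=3,        # wells where the IMM recedes into the 18-30 nm band
    subdivisions=5,
    seed=1,
)
particles, ptruth = decorate_particles(omm, n=300, import_fraction=0.4, seed=2)

write_surface(omm, out / "omm.stl", out / "omm_labels.csv")
write_surface(imm, out / "imm.stl")
write_particles(particles, out / "particles.star", pixel_size=1.0)

print(f"OMM: {omm.n_triangles} triangles, area {omm.total_area:.3e} A^2")
print(f"IMM: {imm.n_triangles} triangles")
print(f"truth crista-associated OMM triangles: {truth.crista_triangles.sum()}")
print(f"particles: {len(particles)} "
      f"({(ptruth.particle_labels == 'import_oriented').sum()} planted import-oriented)")
print(f"wrote scene to {out}/")
# The crista count says how much of the OMM sits over planted CJ wells; the
# planted import count is the ground truth the classifier should recover.
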