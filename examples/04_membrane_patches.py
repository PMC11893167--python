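"""Membrane patches, crista overlap, and local OMM-IMM distances.

Builds co-translation-associated patches from import-oriented ribosomes,
compares their OMM-IMM distance peak with the rest of the membrane, scores
overlap with the crista-associated OMM, and checks both against a
count-matched randomized null.
"""

from mitomorph import (
    build_patches,
    compute_context,
    crista_associated_omm,
    decorate_particles,
    intermembrane_distance,
    make_mitochondrion,
    overlap_fraction,
    patch_distance_histograms,
    randomize_patches,
)

# scene: OMM-IMM spacing reduced to 110 A in three zones (135 A elsewhere),
# plus three crista-junction wells; import ribosomes planted in the zones
omm, imm, truth = make_mitochondrion(
    radius=3000.0, spacing=135.0, spacing_co=110.0, n_co_zones=3,
    n_cj_wells=3, subdivisions=5, seed=1,
)
particles, _ = decorate_particles(omm, n=80, region_mask=truth.zone_triangles, seed=2)
records = compute_context(particles, omm)
seeds = records.loc[records["orientation_class"] == "import_oriented",
                    "nearest_triangle_id"].to_numpy()

patches = build_patches(seeds, omm, radius=150.0)
rand = randomize_patches(patches, omm, seed=3)
field = intermembrane_distance(omm, imm, method="nearest-point")
hists = patch_distance_histograms(field, patches, bins=100)
rhists = patch_distance_histograms(field, rand, bins=100)

areas = patches.areas(omm)
print(f"patches: {len(patches.seed_ids)} centers, "
      f"{100 * areas['patch'] / areas['total']:.1f}% of the OMM area")
print(f"OMM-IMM peak, co-translation patches   : {hists['patch']['peak']:.1f} A")
print(f"OMM-IMM peak, rest of membrane         : {hists['complement']['peak']:.1f} A")
print(f"OMM-IMM peak, randomized patches       : {rhists['patch']['peak']:.1f} A")

crista = crista_associated_omm(omm, imm)
print(f"crista-associated OMM area fraction    : "
      f"{omm.areas[crista.member].sum() / omm.total_area:.2f}")
print(f"overlap fraction, observed patches     : "
      f"{overlap_fraction(patches, crista, omm):.2f}")
print(f"overlap fraction, randomized patches   : "
      f"{overlap_fraction(rand, crista, omm):.2f}")
# The observed patch peak should recover the planted 110 A spacing while the
# complement and randomized peaks sit near the 135 A baseline.
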