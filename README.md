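# mitomorph

Membrane-contextual morphometrics of mitochondria-associated cytoplasmic
ribosomes in cryo-electron tomograms.

A subset of nuclear-encoded mitochondrial proteins is imported
co-translationally: the cytoplasmic ribosome docks on the outer
mitochondrial membrane (OMM) with its peptide exit tunnel facing the
membrane and feeds the nascent chain into the import machinery.  Given
subtomogram-averaging particle tables (positions + ZYZ Euler angles) and
triangulated membrane surface meshes, this package answers the geometric
questions that analysis poses:

- **Which ribosomes are import-oriented?**  A ribosome whose exit-tunnel
  point lies within 95 Å of the OMM mesh is import-oriented; one whose
  center is within 250 Å without the orientation is proximal-non-import.
- **Do they cluster?**  Ripley's K with a surface-matched CSR null,
  K(r) = V/(n(n−1)) Σ_{i≠j} 1(d_ij ≤ r), read out as maxima of
  K(r)/K_CSR(r) over 10 nm radius intervals in r = 27–166 nm.
- **Do import sites prefer crista junctions?**  Crista-associated OMM is
  found from the IMM→OMM distance band 18–30 nm, projected and dilated by
  15 nm; the statistic is area(ribo ∩ crista)/area(ribo).
- **Is the membrane remodeled at import sites?**  OMM→IMM distances are
  histogrammed (100 bins) per patch class — co-translation-associated
  patches (150 Å around the triangles nearest import-oriented ribosomes),
  their complement, the whole membrane, and a count-matched randomized null
  whose centers must be >150 Å apart — and compared by histogram peak.
- **Are clusters polysomes?**  Chains are detected where a neighbor is
  within 30 nm and the 3′ mRNA entry of one ribosome sits next to the
  5′ mRNA exit of the next, and reported with 5′→3′ end-to-end distances.

Because the deposited tomography data are far beyond desk scale, the
package ships a synthetic-scene generator (`make_mitochondrion`,
`decorate_particles`) that plants every quantity of interest — nested
OMM/IMM icospheres with crista-junction wells and spacing zones, particle
decorations with known import fraction, clustering scale, or polysome
chains — so each stage is validated by parameter recovery against ground
truth.

## Worked example

```python
from mitomorph import (make_mitochondrion, decorate_particles, compute_context,
                       build_patches, intermembrane_distance,
                       patch_distance_histograms, summarize_classes)

# membrane with three 110 Å-spacing zones on a 135 Å baseline
omm, imm, truth = make_mitochondrion(radius=3000, spacing=135, spacing_co=110,
                                     n_co_zones=3, subdivisions=5, seed=1)
particles, _ = decorate_particles(omm, n=80, region_mask=truth.zone_triangles, seed=2)
records = compute_context(particles, omm)
seeds = records.loc[records.orientation_class == "import_oriented",
                    "nearest_triangle_id"]
patches = build_patches(seeds, omm, radius=150.0)
field = intermembrane_distance(omm, imm, method="nearest-point")
hists = patch_distance_histograms(field, patches, bins=100)
print(hists["patch"]["peak"], hists["complement"]["peak"])
```

prints (seed-for-seed):

```
110.09369957443843 134.844635619981
```

i.e. the OMM–IMM distance peak under co-translation-associated patches
recovers the planted 110 Å spacing, while the rest of the membrane sits at
the 135 Å baseline — the membrane-thinning readout at import sites.
Each script in `examples/` demonstrates one capability end to end
(scene simulation, classification with a cutoff sweep, clustering,
patch/crista analysis, polysomes, and the full multi-tomogram pipeline via
`run_all`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the self-contained acceptance target from scratch: it generates
closed synthetic OMM surfaces, places 300 particles per scene by
area-weighted uniform (CSR) sampling, computes K(r)/K_CSR(r) over
r = 27–166 nm against the matched surface-uniform Monte-Carlo null, and
writes the grand mean ratio (20 replicate scenes) as JSON.  For CSR input
the ratio should be 1 up to Monte-Carlo error.
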