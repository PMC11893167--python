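# Methods

## Scope and model

`mitomorph` operates downstream of subtomogram averaging and membrane
segmentation: its inputs are (a) per-tomogram particle tables with 3D
centers (Å) and ZYZ Euler triples, and (b) triangulated OMM/IMM surface
meshes.  Everything it computes is geometry on those two objects — no
densities, no averaging, no segmentation.

### Rotation convention

Particle orientations are ZYZ intrinsic Euler triples (rot, tilt, psi, in
degrees), as written by subtomogram-averaging software.  The body→tomogram
rotation used everywhere is

    R = (Rz(rot) · Ry(tilt) · Rz(psi))ᵀ

i.e. the transpose of the reference→particle matrix.  External tools
disagree about whether a renderer applies this matrix or its transpose; the
convention here is pinned internally by a dedicated consistency test: the
synthetic generator plants particles whose exit tunnel points at the
membrane under this convention, and the classifier must find 100% of them
import-oriented.  If the two halves used different conventions that test
could not pass.

### Body-frame landmarks

The peptide exit tunnel, mRNA entry and mRNA exit positions are body-frame
offsets (`BodyFrameOffsets`).  No canonical numeric coordinates exist
independent of a particular average map, so defaults are a generic
80S-scale geometry: exit tunnel at (0, 0, −120) Å along the exit axis
(0, 0, −1), mRNA entry/exit at (±80, 0, −40) Å.  All are configurable; the
analysis records which axis is the exit direction separately from the
per-axis angle records, so the record schema does not depend on the choice.

### Distances to surfaces

Point-to-surface distance is point-to-nearest-triangle-**centroid** (k-d
tree, exact tie-break to the lowest triangle index, verified against
exhaustive scans).  This matches querying "the nearest surface triangle"
of a dense mesh; an exact point-to-triangle mode exists behind
`nearest_triangle(..., exact=True)` but is not the default.  The
convention's error is bounded by the mesh granularity: the classifier
thresholds (95 Å / 250 Å) need meshes whose triangle circumradius is small
against those cutoffs.  The synthetic icosphere at subdivision 5
(20,480 triangles, ≈65 Å circumradius on a 3,000 Å mitochondrion) is the
default for classification scenes; coarser levels (3–4) are used where only
pair distances or distance bands matter.

## Classification (stage 1)

Per particle: center→OMM distance, nearest triangle id, the three angles
arccos|R·eₖ · n̂| ∈ [0°, 90°] between rotated body axes and the nearest
triangle normal, the exit-tunnel point via center + R·offset, and its own
nearest-OMM distance.  Classes: `import_oriented` if exit→OMM ≤ 95 Å, else
`proximal_non_import` if center→OMM ≤ 250 Å, else `background`.  The 95 Å
cutoff was originally a visual calibration; `sweep_exit_cutoff` reproduces
that exploration numerically over 0–120 Å.

A randomly oriented membrane-proximal particle passes the exit rule by
chance whenever its exit axis happens to dip toward the membrane — a
geometric acceptance of ≈1/3 at the default standoff (135 Å) and exit
offset (120 Å).  Planted-fraction recovery therefore compares the raw
import rate against f + (1−f)·p_chance with p_chance measured by Monte
Carlo (`chance_import_rate`), and `estimate_import_fraction` inverts that
relation.  This is a property of the classification rule itself, not of the
generator: real "proximal-non-import" populations contain the same
geometric false positives.

## Clustering (stage 2)

K(r) = V/(n(n−1)) Σ_{i≠j} 1(d_ij ≤ r), computed by k-d-tree pair counting
with no edge correction.  Membrane-bound particles live on a quasi-2D
shell, so the analytic 3D CSR expectation (4/3)πr³ is biased for them; the
default null is instead a Monte-Carlo mean of the same estimator over
area-weighted uniform placements on the same surface (50 resamples),
which cancels edge and dimensionality effects exactly.  The analytic null
is retained (`k_csr_analytic`) for comparison.  The shared volume V cancels
in the ratio and defaults to 1.

The radius grid is 140 even radii over 27–166 nm (the analysis range; grid
density is a free choice here).  Interval maxima are taken over (k·10,
(k+1)·10] nm intervals anchored at multiples of 10 nm, matching how the
clustering scale is reported, and between-class comparisons use one
interval maximum per tomogram.

`mann_whitney_u` uses midrank ties; exact enumeration of all C(n_a+n_b, n_a)
group assignments for pooled sizes ≤ 12 (valid under ties, two-sided
p = 2·min(P≤, P≥) capped at 1), scipy's normal approximation with tie and
continuity corrections otherwise; identical samples return p = 1 with a
degenerate flag.

## Patches, crista overlap, distance peaks (stages 3–4)

Patches grow by Euclidean centroid distance (≤ 150 Å) from seed triangles —
the triangles nearest import-oriented ribosomes.  Geodesic growth is a
non-goal; at these radii on near-spherical membranes the difference is
negligible.  The randomized null redraws the same number of centers
area-weighted, rejecting whole configurations until all pairwise center
distances are strictly > 150 Å (the ">" is deliberate).

OMM↔IMM distance fields offer two methods: `nearest-point` (centroid to
nearest centroid; the method used for patch distances) and `normal-cone`
(nearest centroid within a 30° half-angle cone around the inward normal,
undefined if none within 1,500 Å — the surface-morphometrics style that
ignores geometry behind the membrane).  Crista detection selects IMM
triangles with OMM distance in 18–30 nm, projects each to its nearest OMM
triangle, and dilates by 15 nm (half a crista body width).  The band
distance defaults to `nearest-point` (the choice is not pinned by the
original description; both are available and tagged in the output).  An
optional minimum-component-area filter stands in for manual clean-up of
spurious band triangles.

Histograms use 100 bins over the [min, max] of the values being binned
(per tomogram, per set); the peak is the center of the most populated bin,
ties to the lower bin.  A peak is therefore only defined to its bin width —
comparisons between physically identical sets should quantize to bin
resolution first (the acceptance suite does), otherwise rank tests amplify
sub-bin floating-point offsets into spurious significance.  All distances
equal is degenerate but well-defined (peak = the common value); fewer than
two defined values flags the peak undefined (NaN), never zero.

## Polysomes (stage 5)

Directed candidate links i→j where center distance ≤ 30 nm and
|entry_i − exit_j| ≤ 60 Å.  The adjacency cutoff operationalizes a
criterion originally applied by eye; no printed value exists, so 60 Å
(≈ three mRNA-channel radii of slack) is a package choice, exposed in the
config and reported with results.  Each particle takes at most one inbound
and one outbound link, assigned greedily in ascending adjacency distance
(mRNA threads singly through a ribosome); cycles are broken at their
largest-distance link.  Chains are maximal simple paths of ≥ 2 members,
ordered so the head's 5′ exit and the tail's 3′ entry are free;
end-to-end is the straight line between those two sites and path length is
the full zig-zag, so end_to_end ≤ path_length is structural.

## Synthetic scenes: what they emulate and what they do not

`make_mitochondrion` builds nested icospheres: OMM at radius R, IMM offset
inward by a per-vertex spacing field.  Crista-junction wells are smooth
local increases of the spacing to 240 Å (inside the 18–30 nm detection
band); co-translation zones are smooth decreases to 110 Å on a 135 Å
baseline — the 110/135 Å two-level field mirrors the reduced intermembrane
distance observed at import sites versus elsewhere.  Regions are placed
with rejection sampling to stay disjoint, and their triangle masks are the
ground truth.  Defaults: R = 3,000 Å (a ~0.6 µm organelle), baseline
spacing 135 Å, ribosome standoff 135 Å (inside the 250 Å proximity band),
import-orientation jitter ≤ 10°.

Decorations: CSR (area-weighted uniform via √-barycentric sampling),
Thomas-like clusters (parents area-uniform, offspring displaced
tangentially with 35 nm Gaussian scale, reprojected to the surface), or
geodesic-walk chains at 200 Å spacing whose entry/exit sites are adjacent
by construction.  One seeded generator per call makes scenes byte-identical
under a fixed seed.

Not emulated: voxel noise and CTF, realistic crista lamellae (wells are
radial depressions, not tubular junctions), mesh defects, segmentation
errors, particle-picking false positives, and curvature beyond the sphere.
A green recovery test therefore establishes that the geometry pipeline is
correct and internally convention-consistent — not that the biological
conclusions of any particular dataset are reproduced.

## Numerical choices

- Lengths Å and angles degrees internally; nm appears only in config fields
  that are quoted in nm (K radii, CJ band, crista expansion, neighbor rule)
  and is converted at the point of use (1 nm = 10 Å).
- Nearest-triangle ties break to the lowest index; interval maxima and
  histogram peaks break ties to the lower interval/bin.
- Zero-area triangles are dropped at mesh ingest (logged count); closed
  surfaces are re-oriented outward by signed volume.
- Undefined quantities are NaN/None and flagged (ratio with a zero null,
  cone misses, peaks with < 2 values, import fraction with an empty
  denominator) — never silently 0.
- Randomization and direction-placement rejection loops raise informative
  errors at a configurable attempt cap rather than degrading constraints.

## Known limitations

- Centroid distances overestimate near coarse meshes; classification needs
  mesh granularity well below the 95 Å cutoff (see above).
- The surface-projection used by clustered/chain decoration assumes a
  star-shaped surface about the origin; it is exact on the bundled
  icosphere scenes but would need a general projection for folded
  membranes.
- `randomize_patches` uses full-configuration rejection; extremely dense
  center packings near the geometric limit may be slow or fail, by design
  with an explicit error.
- The adjacency cutoff (60 Å) cannot be validated against the original
  manual selections; sensitivity to it should be reported alongside any
  polysome counts.
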