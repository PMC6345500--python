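# Methods

## The partition

The Brain-Grid is a deterministic partition of stereotaxic world space into
48 axis-aligned boxes. Eight planes — three of constant Y, two of constant Z,
three of constant X — are anchored on anatomical landmarks of an average
brain: the anterior and posterior insular points and the parieto-occipital
junction on the sagittal axis (MNI Y = 28, −23, −68), the callosal-cingulate
cistern and the inferior insular point on the axial axis (Z = 33, −13), and
the external-capsule lines plus the midline laterally (X = 33, 0, −33). The
Talairach-space constants (X = ±32, 0; Y = 25, −24, −66; Z = 31, −7) are
shipped as printed; no coordinate conversion between the two spaces is
computed, since the original conversion came from an external tool. For
patient-specific work the same eight planes can be supplied from individually
identified landmarks (JSON override); the defaults are the average-brain
constants.

Cells are indexed A (1–4, right→left), C (1–3, cranial→caudal), S (1–4,
anterior→posterior), with the radiological convention A1 = patient right =
largest world x in RAS+. The integer cell ID is fixed as
`(a−1)·12 + (c−1)·4 + s` so exported labelmaps are bit-stable across
versions.

**Tie-break.** A point exactly on a plane belongs to the lower-index slab
(anterior / cranial / right). The source material never addresses boundary
voxels; any consistent rule works, and this one makes every slab a half-open
interval `[low, high)` so the 48 boxes tile space exactly. One consequence,
covered by tests: mirror symmetry across the midline is exact except for
points lying precisely on a lateral plane, where the tie rule is
direction-dependent.

## Mask classification

Cell membership is decided by the **voxel center's** world coordinate mapped
through the image affine. There is no partial-volume splitting and no
resampling: masks are classified in their native geometry, which avoids
interpolation artifacts and makes per-cell volumes sum to the total mask
volume exactly (a tested invariant). Images are reoriented to canonical RAS
axis order on load — a permutation/flip of the array with a matching affine
update, which leaves every voxel-center world coordinate unchanged.

A cell counts as infiltrated when its overlap volume strictly exceeds
`min_overlap_mm3`. The default is 0 (any overlapping voxel counts), matching
the reading that a cell touched by any delineated hyperintensity is involved;
the threshold exists for robustness against segmentation noise. Plane
distances are the minimum over foreground voxel centers of the unsigned
offset to each plane, zero when the foreground spans the plane; sub-voxel
surface interpolation is deliberately not attempted (the measurement emulates
reading distances off a displayed grid line), so distances are accurate to
the voxel pitch. Laterality is derived from the infiltrated cells (A1/A2
right, A3/A4 left, both → bilateral), independent of any side annotation in
cohort files.

## Tract table

The shipped table holds 34 structures: corpus callosum split into genu, body
and splenium, plus anterior commissure and fornix at the midline (5);
fourteen bilateral tract names (internal and external capsule, cingulum,
inferior/middle longitudinal, inferior fronto-occipital, uncinate, frontal
aslant, cortico-spinal, optic radiation, anterior thalamic radiation,
vertical occipital, horizontal SLF, arcuate — 28 entries); and the vertical
SLF segment encoded once with hemisphere-pooled cells. That last entry is a
bookkeeping device: the published inventory counts 34 structures while its
enumeration (two SLF segments per side) would give 35, and the
reconciliation is recorded in the table's provenance column rather than
silently resolved.

Per-entry cell sets have two provenance classes. Entries tagged `reported`
carry at least one cell association stated in the source study's results or
case narratives (e.g. the genu of the corpus callosum spanning the two
fronto-medial cells A2C2S1/A3C2S1); the remaining cells of those entries, and
all cells of `geometric-estimate` entries, are estimates from standard MNI
tract anatomy intersected with the grid geometry. The table is data, not
code: users with their own atlas can regenerate it with
`build_table_from_masks`, which reduces each tract mask to the cells whose
overlap exceeds a threshold and records the threshold in the provenance.

## Longitudinal comparison

Reports, not raw masks, are the unit of comparison: serial studies of one
patient are first classified, then diffed. The delta carries gained, lost and
stable cell sets, the volume change, and per-cell volume changes for stable
cells. Spread routes are proposed only along **face adjacency** in the
4×3×4 lattice (±1 on exactly one axis), which includes the trans-callosal
A2↔A3 step; 26-connectivity would multiply spurious routes through edge- and
corner-touching cells that share no anatomical pathway. Each route lists the
structures whose cell sets contain both endpoints; a gained cell with no
infiltrated face-neighbor is flagged as a non-contiguous appearance rather
than forced onto a route. Series longer than two studies are compared
pairwise; no smoothing is applied to cells that flicker in and out.

## Cohort tools

The cohort schema mirrors the source study's per-patient table (gender, age,
histology A/O, WHO grade 2/3, side R/L/B, free-text local anatomy, margin
phenotype B/D, volume in cm³, infiltrated-cell count, onset, procedure,
number of MRIs), with an optional `cells` column whose length must equal the
stated count. Lobar topography and the bulky/diffuse margin call are carried
as input annotations, never computed — both are radiologist judgments.
Summaries keep raw means alongside one-decimal display values.

The shipped transcription reproduces the published table exactly. Where the
publication's running text disagrees with its own table — printed overall
mean of 7.4 infiltrated cells vs the table's 7.33, printed volume-range
minimum 5.5 cm³ vs the table's 5.1, printed bulky-subgroup mean 5.1 vs the
table's 4.8, printed mean age 46.9 vs the table's 46.4, printed mean volume
54.4 cm³ vs the table's 51.7, and a stated denominator of 288 infiltrated
cells vs the table total of 286 — computation follows the table.

Frequency maps report, per cell, the share of records in a stratum whose
cell sets contain it. The published color scale anchors only three points
(white ≤5%, "high frequency" ≥50%, dark red >80%); the full edges are fixed
at [0,5], (5,25], (25,50), [50,80], (80,100] percent — monotone, covering
the anchors. Because per-patient cell sets behind the published frequency
figure were not released, frequency-map correctness is established by
construction and by a law-of-large-numbers test (RMS deviation of recovered
frequencies from known generative probabilities < 0.05 at n = 500), not by
value-matching the published figure.

## Synthetic lesions

The generator emulates the two margin phenotypes seen on T2-FLAIR: *bulky*
lesions are ellipsoids (voxel-center membership), *diffuse* lesions add
capsule-shaped digitations — cylinders with hemispherical caps along given
unit directions — as a simple, parameterizable stand-in for finger-like
growth along white-matter fibers. Optional boundary noise flips a seeded
random subset of single-voxel surface layers (both erosion and accretion),
so identical specs give identical masks and different seeds differ only at
the boundary.

Growth series emulate slow continuous progression: step *k* translates the
lesion by *k*·growth-vector and dilates the radii by *k*·radius-growth
(default 1 mm/step), and each study's mask is the **cumulative union** of
all steps so far. The union construction is what guarantees the nesting
invariant — a translated ellipsoid alone is not a superset of its
predecessor — and is anatomically the right picture, since hyperintensity
rarely recedes during untreated growth.

What the phantoms do **not** model: MRI intensity and noise, peritumoral
edema vs tumor signal, mass effect and landmark dislocation, and
tract-following curvature of real infiltration. Passing tests therefore
demonstrate the correctness of the geometry, counting, distance and
comparison machinery — not segmentation robustness on clinical images.

## Problem sizes and numerics

The default test geometry is 2 mm isotropic, 91×109×91 (MNI-like FOV with
the world origin at the volume center); fine-resolution checks (analytic
sphere volume to 5%, single-cell recovery of a 5 mm ball) run at 1 mm over a
local 61³ FOV, and coarse property sweeps at 4 mm. Labeling is exact integer
arithmetic on comparisons, with no tolerances anywhere in the partition; the
only approximation in the pipeline is voxelization itself, which bounds
volume error by the surface-voxel count and distance error by the voxel
pitch. The brute-force interval oracle used in the tests and in the
acceptance script enumerates all 48 cells' interval memberships
independently of the labeling implementation.

## Limitations

- Counting assumes the affine is correct; no registration is performed or
  validated here (spatial normalization is upstream of this package).
- Equivalence between affine-based counting and slice-wise visual counting
  on AC–PC-oriented reconstructions is assumed, not proven.
- The `geometric-estimate` entries of the tract table are approximations
  from standard atlas anatomy; users needing exact per-tract cell lists
  should rebuild the table from their own tract masks.
- Route proposal is combinatorial (shared cells + adjacency), not a growth
  model; it suggests candidate pathways, it does not rank their likelihood.
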