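# braingrid

A radiological classification toolkit for cerebral gliomas based on the
**Brain-Grid**: a fixed 48-cell partition of the whole brain defined by eight
anatomical landmark planes in stereotaxic space. It is aimed at
neurosurgeons, neuro-oncologists and imaging researchers who want a
standardized, landmark-anchored way to describe where a glioma sits, which
white-matter pathways it threatens, and how it progresses across serial MRI —
without requiring patient-specific tractography.

## The grid

Eight planes partition RAS+ world space (MNI millimetres):

- three sagittal-axis planes at **Y = 28, −23, −68** (anterior insular point,
  posterior insular point, parieto-occipital junction),
- two axial-axis planes at **Z = 33, −13** (callosal-cingulate cistern,
  inferior insular point),
- three lateral planes at **X = 33, 0, −33** (right external-capsule line,
  midline, left line).

Their intersection yields 4 × 3 × 4 = 48 cells named `A{1–4}C{1–3}S{1–4}`:
A runs right→left (radiological convention), C cranio→caudal, S
anterior→posterior. A tumor mask is classified by mapping every foreground
voxel center through the image affine and labeling it with the half-open slab
intervals (points on a plane go to the lower-index slab), so per-cell overlap
volumes sum to the total lesion volume exactly. The Talairach-space plane
constants are shipped alongside the MNI set, and per-subject landmark
overrides can be supplied as JSON.

On top of the geometry the package provides:

- **Infiltration reports** — infiltrated cells, per-cell volumes, total
  volume, distance from the lesion border to each grid plane, laterality;
- **Tract association** — a shipped 34-structure white-matter table
  (commissural, projection and associative pathways with the grid cells each
  traverses) answering "which tracts are at risk in these cells", plus a
  builder that derives such a table from any per-tract mask atlas;
- **Longitudinal comparison** — gained/lost/stable cells between serial
  studies and candidate spread routes along face-adjacent cells sharing a
  tract (including trans-callosal A2↔A3 steps);
- **Cohort tools** — validated per-patient tables, summary statistics, and
  per-cell infiltration frequency maps on the white→dark-red color scale;
- **Synthetic lesions** — ellipsoidal "bulky" and digitated "diffuse"
  phantoms and nested growth series, so every pipeline stage is testable
  without patient data.

## Worked example

```python
import braingrid as bg

grid = bg.build_default_grid("MNI")
geom = bg.make_reference_geometry((91, 109, 91), 2.0)   # 2 mm MNI-like FOV

# a 5 mm ball in the left sub-insular/basal-ganglia region
lesion = bg.make_ellipsoid_lesion(
    bg.LesionSpec(center=(-10, 0, 0), radii=(5, 5, 5)), geom)
report = bg.classify_mask(lesion, grid, study_id="demo")
print(report.n_cells, [str(c) for c in report.cells], report.laterality)
# 1 ['A3C2S2'] left

for entry, shared in bg.tracts_in_cells(report.cells)[:4]:
    print(entry.display_name, shared)
# AC 1
# ATR-L 1
# CC-body 1
# CC-genu 1
```

The single infiltrated cell is `A3C2S2` — the left sub-insular/basal-ganglia
cell — and the table lookup lists the structures traversing it (the full
ranked list continues with CST-L, Ci-L, ExC-L, Fo, IC-L, IFOF-L, UF-L: the
inferior fronto-occipital and uncinate fasciculi, external capsule and
anterior thalamic radiation are exactly the pathways most often associated
with tumors in this region). The same objects drive the CLI:

```bash
braingrid grid-export --space MNI --out grid.nii.gz
braingrid classify --mask tumor.nii.gz --out report.json
braingrid tracts --cells A3C2S2,A4C2S2
braingrid compare early.json late.json --out delta.json
braingrid cohort --table cohort.csv --out summary.json
```

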