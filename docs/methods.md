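# Methods

## Setting and model

The pipeline quantifies femorotibial kinematics from labeled 3D volumes of
a knee imaged in an unloaded (δ0) and an anteriorly loaded (δ1)
configuration, in each of three ACL conditions (intact, partial deficiency,
complete deficiency). All quantities are rigid-body measures: loading is
treated as a rigid displacement of the tibia relative to the femur, which
is what the measures are designed to detect. Soft-tissue deformation,
cartilage compression and bone bending are outside the model.

Every measure is expressed in a canonical anatomical frame of a right
knee: x = +lateral, y = +posterior, z = +proximal. Left knees are mirrored
across the sagittal plane during canonicalization, so one sign convention
serves both sides: positive x/y/z components of a femur-minus-tibia vector
read as a more lateral/posterior/proximal femoral point, and anterior
tibial translation under load appears as an *increase* of the y
projections. Whether the acquisition frame is scanner-fixed or anatomically
aligned per specimen is not recoverable from a label map; the canonical
frame (declared through per-volume `axis_semantics` metadata) is this
package's convention.

## Coordinates and voxel geometry

Voxel indices are 0-based and refer to voxel centers. In-plane coordinates
scale by the in-plane spacing (default 0.36 mm); the through-plane
coordinate scales by the slice *pitch* — slice thickness plus inter-slice
gap (3.0 + 0.3 = 3.3 mm by default). Pitch is the only conversion that
accounts for the gap, and it places each slice's coordinate at its center.
The anisotropy matters: through-plane quantization (3.3 mm) dominates the
error budget of every through-plane measure, which is why the axis–bone
intersection is refined to sub-voxel precision (below).

## Bone frames

**Central axis.** The central bone axis is estimated as the principal
component of the diaphyseal voxel cloud in mm coordinates. The bone's long
extent comes from a PCA over all its voxels; the joint-facing end is the
extreme nearest the other bone's centroid (no anatomical prior needed);
the shaft region is the `shaft_fraction` (default 0.5) of the long extent
farthest from the joint. Restricting the fit to the diaphysis avoids bias
from the condylar/plateau masses. A voxel cloud whose first two principal
variances differ by less than a factor of 1.2 has no defensible axis and
raises an error (a sphere is the canonical case). Fewer than 100 labeled
voxels raises an insufficient-mask error. The direction is oriented
joint → shaft (femoral axis points proximal, tibial distal); this
orientation is what gives the projected angles their
"extension ≈ 180°" semantics.

Manually digitised axes can be supplied per cell in annotation files and
are then used verbatim (`annotated` mode); the estimator is an algorithmic
surrogate for that manual workflow, not a reimplementation of it — how
manual axes are drawn (endpoints, slice set) is reader-dependent.

**Axis–bone intersection (ABI).** The ABI is the sub-voxel point where the
axis exits the bone mask on the joint-facing side. The implementation
marches along the axis toward the joint at a step of half the smallest
spacing and takes the midpoint of the last inside → first outside step
(linear interpolation of a binary indicator). This stabilizes the measure
against the coarse 3.3 mm pitch: on capped-cylinder phantoms the ABI is
recovered well within half a pitch.

**Landmarks** (femoral trochlear apex, tibial tuberosity centre) always
come from annotation files, as in a manual workflow; automatic landmark
detection is out of scope.

On rasterized phantoms the estimated frames agree with ground truth within
1° (axis direction) and 1.7 mm (ABI) — the package's reproducibility
envelope, of the same order as manual re-digitisation scatter on real data.

## 3D measures

Two vectors, each femoral point minus tibial point: vector_ABI between the
ABIs and vector_landmarks between the landmarks. Each yields a length and
three signed axis projections (8 measures). The three projected angles
compare the *oriented* axis directions after orthogonal projection onto
the coronal (xz), sagittal (yz) and axial (xy) planes:

* yz (sagittal): 180° = antiparallel projections = near-full extension;
  90° = perpendicular axes; decreasing values = increasing flexion.
* xz (coronal): reported as the unsigned medial-sided magnitude, plus a
  varus/valgus sign bit from the signed angle (projected tibial →
  projected femoral direction about +y). Which handedness "medial-sided"
  denotes is a convention; the sign bit preserves the information either
  way.
* xy (axial): 0° = parallel projections; changes indicate axial rotation.

Using oriented directions rather than undirected lines is a declared
convention (for the xy angle both are consistent with typical values);
it keeps all three angles on one footing. A projected direction whose
in-plane magnitude falls below ε = 0.1 makes the angle ill-conditioned
(cross-plane effects); the angle is still reported but flagged, keeping
the pipeline total. Angles and distances carry full floating precision
internally; rounding (0.1 mm / 1°) is applied only in display contexts.

## 2D reference measures

On the mid-sagittal slice of each compartment (the sagittal slice through
the mediolateral centroid of that compartment's meniscus label, ties to
the lower index, manual overrides honored), "tangential lines"
perpendicular to the anteroposterior axis are dropped at posterior
margins, and anteroposterior distances between tangents are reported:

* LMD/MMD = plateau tangent − tangent at the meniscus posterior horn base
  (posterior third of the meniscus extent, inferior half); positive =
  horn anterior to the plateau margin.
* LTP/LFC and MTP/MFC = plateau tangent − condyle tangent; positive =
  condyle anterior to the plateau margin. Anterior tibial translation by
  t therefore decreases these by exactly t.

Tangents are placed at the posterior-most labeled voxel (no sub-voxel
refinement), matching the resolution of a manual ruler construction. The
plateau tangent is restricted to the superior 10 mm of the tibia in the
slice and the condylar tangent to the inferior 25 mm of the femur, so
diaphyseal voxels cannot masquerade as articular margins. "Horizontal" is
the canonical anteroposterior axis, also when the joint is flexed — a
recorded convention. A two-reader emulation jitters each tangent placement
with a configurable SD (default 0.3 mm, roughly half an in-plane voxel)
to generate paired reader data for the agreement analysis.

## Statistics

* **Δ referencing:** Δx[status] = x[status] − x[intact, δ0], specimen-
  matched; per-condition δ0 referencing is available as an alternative.
  The mean Δ over specimens equals the difference of cell means exactly.
* **RM-ANOVA:** one-way with the six condition × configuration cells
  flattened into a single within-subject factor (specimen repeated), so
  the Tukey family covers all pairwise cell contrasts. No sphericity
  correction by default; Greenhouse–Geisser via a flag. Because Δ
  referencing subtracts a per-specimen constant, the ANOVA is identical
  on raw and Δ values. The fit is delegated to `pingouin.rm_anova` and
  cross-checked in the tests against a hand-written sum-of-squares
  decomposition.
* **Tukey HSD:** q = |Δmeans| / √(MS_error/n) against the studentized
  range with the RM error degrees of freedom — the post-hoc formulation
  declared here, since "Tukey after RM-ANOVA" admits several.
* **Significance:** p ≤ 0.01 per measure, with *no* multiplicity
  correction across the fifteen measures — a deliberately strict single
  threshold instead of formal correction, trading a reduced
  false-positive count against preserved power.
* **ICC:** two-way random effects, single measures, absolute agreement —
  ICC(2,1) — the closest reading of "single scorings, not adjusted";
  other readings (consistency, averaged) would differ and remain an open
  interpretation.
* **Power:** smallest integer per-group n of a two-sample two-tailed
  t-test reaching the target power, via the noncentral t distribution
  (normal limit at extreme noncentrality). With (0.8, 0.05, d = 1.6) this
  gives n = 8. The two-sample design is a declared reading; a paired
  design would give a different n.
* **Units:** 1 kilopond = 9.80665 N (standard gravity), so the 15 kp
  load is 147.1 N; used as a configuration sanity check.

## Synthetic phantom

The generator emulates the study layout — by default 10 specimens (5
right, 5 left, alternating) × 3 ACL conditions × 2 loading states, voxel
grid 224 × 288 × 48 at (0.36, 0.36, 3.3) mm — with analytic solids:

* tibia: shaft cylinder tilted ~12° off vertical (so its axial projection
  is well-conditioned), an elliptic plateau slab whose top carries the
  tibial ABI, an anterior tuberosity bump (its centre is the landmark);
* femur: shaft cylinder tilted posteriorly ~67° (sagittal inter-axis
  angle ≈ 113°, a flexed-knee value), two condylar half-ellipsoids, an
  anterior trochlear apex landmark; the femoral ABI is the distal shaft
  cap centre;
* menisci: two posterior crescent wedges on the plateau, riding with the
  tibia by default (they attach to the plateau); attachment to the femur
  is available for property testing.

Loading (δ1) applies a rigid tibial transform: anterior translation drawn
per condition from N(mean, SD) with defaults 2.5 / 8.1 / 12.6 mm
(intact / partial / complete — the physiological-laxity to
complete-deficiency regime the method must resolve) and SDs 1 / 3 / 3 mm,
plus an axial rotation about the craniocaudal line *through the tibial
ABI*. The pivot choice keeps translation and rotation effects decoupled
(the ABI is on the rotation line), and rotating about a vertical line —
rather than the tibia's own tilted axis, which would leave the axis
direction unchanged — makes the imposed rotation observable in the xy
angle. Rotation magnitudes default to small values (≤ 4°, SD ≤ 1.5°),
consistent with axial effects being secondary. δ0 cells receive only
positional jitter (SD `noise_sd_mm`, default 0.5 mm), which also models
landmark digitization noise in the annotation files. Per-specimen
morphology (radii, plateau size, tilts) is jittered ~5% and clamped to
valid geometry. One study seed drives everything through spawned
per-specimen, per-cell generators; with all SDs zero, regeneration is
bit-identical.

Rasterization labels a voxel iff its center lies inside a solid (no
anti-aliasing) — trivially testable by counting — and raises a
field-of-view error naming any solid that leaves the grid.

**What the phantom does not emulate:** realistic bone and meniscus
anatomy, MRI intensities, partial-volume effects, segmentation errors
(label maps are exact), soft-tissue constraint and specimen-specific
laxity, or flexion-angle drift under load. Passing tests therefore
demonstrate that the *measurement and statistics machinery* is correct
and well-calibrated under known rigid motion at the study's voxel
geometry — not that segmentation-derived measures on real knees reach the
same accuracy. One visible consequence: because phantom menisci ride
rigidly with the tibia, LMD/MMD barely change across cells, so their
between-target variance is small and their simulated two-reader ICC
understates the near-perfect agreement regime; the condylar measures,
with study-scale spread, show ICC ≈ 0.99.

## Numerical choices

* ABI march step: min(spacing)/2; crossing refined to the step midpoint.
* Axis-degeneracy threshold: first/second principal-variance ratio < 1.2.
* Angle conditioning threshold ε = 0.1 on projected magnitude (flag, not
  refusal).
* Ties in mid-sagittal slice selection break to the lower index.
* All-equal RM-ANOVA input takes a degenerate path (p = 1, no significant
  pairs) instead of a 0/0 F; per-cell-constant but unequal cells raise a
  degenerate-data error.
* Extreme noncentrality in the power computation falls back to the normal
  limit (scipy's noncentral t returns NaN there).
* Default problem sizes (10 specimens, 224 × 288 × 48 grid, 1000
  null-simulation replicates, 200 detection replicates) keep a full
  validation run in the minutes range on one CPU while leaving Monte
  Carlo error well below the decision margins.

## Limitations

Beyond the phantom's idealizations above: the projected angles remain
susceptible to cross-plane effects (flagged, not corrected); compartment-
specific 3D measures are not computed (the vector measures assess global
joint motion); the 2D tangent constructions operate at voxel resolution;
and the choice of which 3D/2D measure pairs to correlate is exposed as
configuration rather than fixed.
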