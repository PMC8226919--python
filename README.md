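# kneestress

Quantifying knee-joint stability from stress MRI: femorotibial kinematics
as a function of anterior cruciate ligament (ACL) integrity and loading.

## The problem

Morphologic MRI identifies complete ACL tears well but is unreliable for
partial tears, while stress radiography measures anterior tibial
translation (ATT) with poor precision. Stress MRI — imaging the knee
before (δ0) and after (δ1) a controlled anterior load is applied to the
proximal calf — makes joint *function* measurable: with labeled femur,
tibia and meniscus volumes, the loading-induced displacement of the tibia
relative to the femur can be quantified in 3D and compared across graded
ACL states (intact, partially deficient, completely deficient).

`kneestress` implements that measurement pipeline for researchers working
with segmented stress-MRI knee series:

* **3D measures** — per configuration, a femoral and a tibial bone frame
  are built from the central bone axis (diaphyseal principal axis), its
  intersection with the articulating surface (axis–bone intersection,
  ABI), and an anatomic landmark (trochlear apex / tibial tuberosity
  centre). Two vectors, each femoral point − tibial point,

  v_ABI = p_ABI^fem − p_ABI^tib,   v_lm = p_lm^fem − p_lm^tib,

  are quantified by their lengths ‖v‖ and signed projections v_x, v_y,
  v_z (canonical right-knee frame: x = +lateral, y = +posterior,
  z = +proximal; a positive y means a more posterior femoral point, so
  anterior tibial translation under load *increases* y_ABI). The femoral
  and tibial axis directions are compared through the angles between
  their orthogonal projections onto the coronal (xz), sagittal (yz) and
  axial (xy) planes — eleven measures in all.
* **2D reference measures** — automated tangent-line constructions on the
  mid-sagittal slice of each femorotibial compartment: meniscus
  displacement distances (LMD, MMD) and tibial-plateau vs femoral-condyle
  displacements (LTP/LFC, MTP/MFC), with an optional two-reader emulation
  for agreement analysis.
* **Statistics** — every measure x is referenced against the ACL-intact
  unloaded cell of the same specimen, Δx[status] = x[status] − x[intact, δ0];
  the six condition × loading cells are compared by one-way
  repeated-measures ANOVA with Tukey HSD post-hoc (studentized range on
  the RM error term) at p ≤ 0.01, two-reader agreement by ICC(2,1), 3D/2D
  concordance by Pearson r, and the a-priori sample size by inverting the
  noncentral-t power curve of a two-sample t-test.
* **Synthetic phantoms** — a first-class generator of voxelized
  femur/tibia/meniscus label volumes under known rigid tibial transforms
  (condition-dependent anterior translation + axial rotation), with exact
  ground-truth axes, landmarks and ABIs, so the whole pipeline is
  validated end-to-end against known truth.

## Worked example

Run a complete synthetic study — 10 specimens × 3 ACL conditions × 2
loading configurations, 0.36 × 0.36 mm in-plane voxels with a 3.3 mm
slice pitch — from a single seed:

```bash
kneestress run-study --outdir scratch/demo --seed 1 --no-figures
```

or in Python:

```python
import kneestress as ks

cfg = ks.PipelineConfig(outdir="scratch/demo", seed=1)
report = ks.run_study(cfg, make_figures=False)

d1 = report.deltas.query("measure == 'y_ABI' and configuration == 'd1'")
print(d1.groupby("condition")["value"].mean().round(2))
```

prints (seed 1):

```
condition
complete    12.32
intact       2.18
partial      8.13
Name: value, dtype: float64
```

These are the recovered loading-induced anterior-translation deltas
Δ(y_ABI) in mm: the configured effects were 2.5 / 8.1 / 12.6 mm for the
intact / partial / complete conditions, and the rasterized pipeline
recovers them within a fraction of a voxel, preserving the clinically
decisive ordering intact < partial < complete. The same report carries
the per-measure RM-ANOVA (`report.report["anova"]["y_ABI"]["p"]` ≈ 4e-26),
the two-reader ICC of the condyle displacement (0.994) and the Pearson
correlation between y_ABI and LTP/LFC (−0.994 — both track the imposed
translation, with opposite sign conventions). Utility computations:

```python
>>> ks.required_sample_size(power=0.8, alpha=0.05, effect_size_d=1.6, tails="two")
8
>>> round(ks.kilopond_to_newton(15.0), 1)   # the applied 15 kp load
147.1
```

CLI verbs `generate`, `frames`, `measure3d`, `measure2d`, `stats`,
`run-study` and `selfcheck` expose the individual stages over a study
manifest (NIfTI label volumes + JSON annotations); see
`kneestress --help`.

## Documentation

`docs/methods.md` describes the model, the measurement conventions, the
phantom geometry, the statistical procedures and their numerical choices,
and the known limitations.
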