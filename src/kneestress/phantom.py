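"""Synthetic knee phantom generator.

Produces voxelized femur/tibia/meniscus label volumes under known rigid
tibial transforms per ACL condition (intact / partial / complete) and
loading state (d0 unloaded / d1 loaded), together with exact ground-truth
axes, landmarks and axis-bone intersections (ABIs).  The phantoms stand in
for cadaveric stress-MRI data: loading is modeled as a rigid anterior
tibial translation (plus a small axial rotation), with condition-dependent
magnitudes, so the downstream measurement and statistics stages can be
validated against known truth.

Geometry (canonical right-knee frame, x=+lateral, y=+posterior, z=+proximal):

* tibia — shaft cylinder tilted ~12 deg off vertical, an elliptic plateau
  slab whose top surface carries the tibial ABI, and an anterior tuberosity
  bump whose centre is the tibial landmark;
* femur — shaft cylinder tilted posteriorly so the sagittal (yz) inter-axis
  angle sits near the flexed-knee value of ~113 deg, two condylar
  half-ellipsoids, and an anterior trochlear apex landmark; the femoral ABI
  is the centre of the distal shaft cap;
* menisci — two posterior crescent wedges resting on the plateau, medial
  and lateral.

Loading (d1) translates the tibia anteriorly (toward -y) by a draw from the
condition's distribution and rotates it about the craniocaudal (+z) line
through the tibial ABI; the femur stays fixed.  Rotating about a vertical
line (rather than the tibia's own, slightly tilted axis) changes the tibial
axis direction's axial projection by exactly the drawn angle, so the
imposed rotation is observable in the axial inter-axis (xy) angle, while
the pivot through the ABI keeps the translation and rotation effects
decoupled.  Unloaded (d0) cells receive only positional jitter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FieldOfViewError
from .volume_io import (
    CONDITIONS,
    CONFIGURATIONS,
    LABEL_FEMUR,
    LABEL_MENISCUS_LATERAL,
    LABEL_MENISCUS_MEDIAL,
    LABEL_TIBIA,
    LabeledVolume,
    ManifestRecord,
    write_annotations,
    write_manifest,
    write_volume,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Analytic solids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Solid:
    """Rigid analytic solid: local-frame membership test behind (center, R)."""

    name: str
    center: np.ndarray
    R: np.ndarray  # world <- local, orthogonal

    def _local(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.center) @ self.R

    def contains(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def local_half_extents(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Conservative world-frame AABB."""
        half = np.abs(self.R) @ self.local_half_extents()
        return self.center - half, self.center + half

    def transformed(self, Rm: np.ndarray, t: np.ndarray) -> "Solid":
        return replace(self, center=Rm @ self.center + t, R=Rm @ self.R)


@dataclass(frozen=True)
class Cylinder(Solid):
    radius: float = 1.0
    half_length: float = 1.0

    def contains(self, pts):
        q = self._local(pts)
        return (q[:, 0] ** 2 + q[:, 1] ** 2 <= self.radius ** 2) & (
            np.abs(q[:, 2]) <= self.half_length)

    def local_half_extents(self):
        return np.array([self.radius, self.radius, self.half_length])


@dataclass(frozen=True)
class Ellipsoid(Solid):
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    half: str | None = None  # "lower" keeps local z <= 0

    def contains(self, pts):
        q = self._local(pts) / np.asarray(self.semi_axes)
        inside = (q ** 2).sum(axis=1) <= 1.0
        if self.half == "lower":
            inside &= self._local(pts)[:, 2] <= 0.0
        return inside

    def local_half_extents(self):
        return np.asarray(self.semi_axes, dtype=float)


@dataclass(frozen=True)
class Sphere(Solid):
    radius: float = 1.0

    def contains(self, pts):
        d = np.atleast_2d(pts) - self.center
        return (d ** 2).sum(axis=1) <= self.radius ** 2

    def local_half_extents(self):
        return np.full(3, self.radius)


@dataclass(frozen=True)
class EllipticSlab(Solid):
    a: float = 1.0
    b: float = 1.0
    half_height: float = 1.0

    def contains(self, pts):
        q = self._local(pts)
        return ((q[:, 0] / self.a) ** 2 + (q[:, 1] / self.b) ** 2 <= 1.0) & (
            np.abs(q[:, 2]) <= self.half_height)

    def local_half_extents(self):
        return np.array([self.a, self.b, self.half_height])


@dataclass(frozen=True)
class PosteriorCrescent(Solid):
    """Posterior half-annulus wedge (local +y = posterior at build time)."""

    r_inner: float = 1.0
    r_outer: float = 2.0
    half_height: float = 1.0

    def contains(self, pts):
        q = self._local(pts)
        r2 = q[:, 0] ** 2 + q[:, 1] ** 2
        return ((r2 >= self.r_inner ** 2) & (r2 <= self.r_outer ** 2)
                & (np.abs(q[:, 2]) <= self.half_height) & (q[:, 1] >= 0.0))

    def local_half_extents(self):
        return np.array([self.r_outer, self.r_outer, self.half_height])


def _frame_from_z(direction: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose local z maps to ``direction``."""
    z = np.asarray(direction, dtype=float)
    z = z / np.linalg.norm(z)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionEffect:
    """Loading-induced tibial motion for one ACL condition."""

    loaded_translation_mean_mm: float
    loaded_translation_sd_mm: float
    rotation_mean_deg: float
    rotation_sd_deg: float


#: Loading effects calibrated to the anterior-translation regime the method
#: is designed to detect: ~2-3 mm physiological laxity for the intact ACL,
#: ~8 mm after partial and ~12.6 mm after complete transection.
DEFAULT_CONDITION_EFFECTS: dict[str, ConditionEffect] = {
    "intact": ConditionEffect(2.5, 1.0, 0.0, 1.0),
    "partial": ConditionEffect(8.1, 3.0, 4.0, 1.5),
    "complete": ConditionEffect(12.6, 3.0, 2.0, 1.5),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic specimen series.

    Defaults emulate the study conditions: 10 specimens, 0.36 x 0.36 mm
    in-plane voxels with a 3.3 mm slice pitch (3.0 mm thickness + 0.3 mm
    gap), three ACL conditions x two loading states each.
    """

    n_specimens: int = 10
    spacing_mm: tuple[float, float, float] = (0.36, 0.36, 3.3)
    volume_shape: tuple[int, int, int] = (224, 288, 48)
    condition_effects: dict[str, ConditionEffect] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS))
    noise_sd_mm: float = 0.5
    slice_gap_mm: float = 0.3
    seed: int = 0
    size_jitter_sd: float = 0.05
    meniscus_attachment: str = "tibia"  # or "femur" (for property testing)
    sides: tuple[str, ...] | None = None  # default: alternating right/left

    def __post_init__(self):
        if self.n_specimens < 1:
            raise ConfigurationError("n_specimens must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing components must be positive")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be >= 0")
        if not 0 <= self.slice_gap_mm < self.spacing_mm[2]:
            raise ConfigurationError("slice_gap_mm must be in [0, slice pitch)")
        for name, eff in self.condition_effects.items():
            if name not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {name!r}")
            if eff.loaded_translation_sd_mm < 0 or eff.rotation_sd_deg < 0:
                raise ConfigurationError("effect SDs must be >= 0")
        if self.meniscus_attachment not in ("tibia", "femur"):
            raise ConfigurationError("meniscus_attachment must be 'tibia' or 'femur'")

    def side_of(self, specimen_index: int) -> str:
        if self.sides is not None:
            return self.sides[specimen_index]
        return "right" if specimen_index % 2 == 0 else "left"


@dataclass
class BoneModels:
    """Analytic bone pair for one specimen (canonical right-knee frame)."""

    femur_solids: list[Solid]
    tibia_solids: list[Solid]
    meniscus_medial: list[Solid]
    meniscus_lateral: list[Solid]
    femoral_axis_point: np.ndarray
    femoral_axis_direction: np.ndarray  # unit, oriented joint -> shaft
    tibial_axis_point: np.ndarray
    tibial_axis_direction: np.ndarray  # unit, oriented joint -> shaft
    femoral_abi: np.ndarray
    tibial_abi: np.ndarray
    femoral_landmark: np.ndarray  # trochlear apex
    tibial_landmark: np.ndarray  # tuberosity centre


def build_bone_models(spec: PhantomSpec, specimen_index: int) -> BoneModels:
    """Construct the analytic solids, axes and landmarks for one specimen.

    Sizes and alignment angles receive per-specimen jitter from the seeded
    generator; out-of-range draws are clamped to valid geometry (logged).
    """
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(specimen_index, 0))
    rng = np.random.default_rng(ss)

    nx, ny, nz = spec.volume_shape
    sx, sy, sz = spec.spacing_mm
    xc = (nx - 1) / 2 * sx
    yc = 0.425 * (ny - 1) * sy  # joint centre sits anterior of the volume midline:
    # the flexed femoral shaft runs posteriorly and needs the larger margin
    zj = 0.62 * (nz - 1) * sz  # joint line height

    def jittered(value: float, rel_sd: float | None = None) -> float:
        rel = spec.size_jitter_sd if rel_sd is None else rel_sd
        f = rng.normal(1.0, rel)
        if not 0.85 <= f <= 1.15:
            log.info("clamping size jitter factor %.3f for specimen %d", f, specimen_index)
            f = float(np.clip(f, 0.85, 1.15))
        return value * f

    # per-specimen morphology
    r_tibia = jittered(13.0)
    r_femur = jittered(12.0)
    plateau_a, plateau_b = jittered(30.0), jittered(20.0)
    condyle_semi = (jittered(10.0), jittered(14.0), jittered(12.0))
    meniscus_r_out = jittered(9.5)
    flexion_tilt = float(np.clip(67.0 + rng.normal(0.0, 2.0), 60.0, 72.0))
    tibia_tilt = float(np.clip(12.0 + rng.normal(0.0, 1.5), 8.0, 16.0))
    tibia_azimuth = 120.0 + rng.normal(0.0, 6.0)

    # tibia: axis through the plateau-top centre (= tibial ABI), tilted off
    # vertical so its axial projection is well conditioned
    t_abi = np.array([xc, yc, zj])
    az = np.deg2rad(tibia_azimuth)
    tb = np.deg2rad(tibia_tilt)
    t_dir = np.array([np.sin(tb) * np.cos(az), np.sin(tb) * np.sin(az), -np.cos(tb)])
    t_dir /= np.linalg.norm(t_dir)

    shaft_lo, shaft_hi = 4.0, 85.0
    tibia_shaft = Cylinder(
        name="tibial shaft", center=t_abi + 0.5 * (shaft_lo + shaft_hi) * t_dir,
        R=_frame_from_z(t_dir), radius=r_tibia, half_length=0.5 * (shaft_hi - shaft_lo))
    plateau = EllipticSlab(
        name="tibial plateau", center=np.array([xc, yc, zj - 4.0]), R=np.eye(3),
        a=plateau_a, b=plateau_b, half_height=4.0)
    tuberosity_s = 18.0
    tub_center = t_abi + tuberosity_s * t_dir + np.array([0.0, -r_tibia, 0.0])
    tuberosity = Sphere(name="tibial tuberosity", center=tub_center, R=np.eye(3), radius=5.0)

    # femur: shaft tilted posteriorly by the flexion angle; ABI = distal cap
    fx = np.deg2rad(flexion_tilt)
    f_dir = np.array([0.0, np.sin(fx), np.cos(fx)])
    f_abi = np.array([xc, yc + 2.0, zj + 14.0])
    femur_len = 55.0
    femur_shaft = Cylinder(
        name="femoral shaft", center=f_abi + 0.5 * femur_len * f_dir,
        R=_frame_from_z(f_dir), radius=r_femur, half_length=0.5 * femur_len)
    condyle_y = yc + plateau_b * np.sqrt(max(0.0, 1.0 - (22.0 / plateau_a) ** 2)) \
        + 3.0 - condyle_semi[1]
    condyles = [
        Ellipsoid(name=f"{name} femoral condyle",
                  center=np.array([xc + dx, condyle_y, zj + 16.0]), R=np.eye(3),
                  semi_axes=condyle_semi, half="lower")
        for name, dx in (("medial", -22.0), ("lateral", 22.0))]
    trochlea = f_abi + 12.0 * f_dir + np.array([0.0, -12.0, 0.0])

    menisci = {}
    for name, dx in (("medial", -22.0), ("lateral", 22.0)):
        menisci[name] = PosteriorCrescent(
            name=f"{name} meniscus", center=np.array([xc + dx, yc, zj + 1.8]),
            R=np.eye(3), r_inner=4.5, r_outer=meniscus_r_out, half_height=1.8)

    return BoneModels(
        femur_solids=[femur_shaft] + condyles,
        tibia_solids=[tibia_shaft, plateau, tuberosity],
        meniscus_medial=[menisci["medial"]],
        meniscus_lateral=[menisci["lateral"]],
        femoral_axis_point=f_abi.copy(),
        femoral_axis_direction=f_dir,
        tibial_axis_point=t_abi.copy(),
        tibial_axis_direction=t_dir,
        femoral_abi=f_abi.copy(),
        tibial_abi=t_abi.copy(),
        femoral_landmark=trochlea,
        tibial_landmark=tub_center.copy(),
    )


# ---------------------------------------------------------------------------
# Condition / loading transforms
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthCell:
    """Exact per-cell truth: imposed transform, axes, landmarks, ABIs."""

    specimen: str
    condition: str
    configuration: str
    side: str
    translation_mm: np.ndarray
    rotation_deg: float
    femoral_axis_point: np.ndarray
    femoral_axis_direction: np.ndarray
    tibial_axis_point: np.ndarray
    tibial_axis_direction: np.ndarray
    femoral_abi: np.ndarray
    tibial_abi: np.ndarray
    femoral_landmark: np.ndarray
    tibial_landmark: np.ndarray

    def to_dict(self) -> dict:
        out = {}
        for k, v in vars(self).items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def apply_condition_transform(
    bones: BoneModels,
    condition: str,
    configuration: str,
    effects: dict[str, ConditionEffect],
    rng: np.random.Generator,
    noise_sd_mm: float = 0.0,
    meniscus_attachment: str = "tibia",
    specimen: str = "S00",
    side: str = "right",
) -> tuple[BoneModels, GroundTruthCell]:
    """Rigidly displace the tibia for one study cell; the femur stays fixed.

    d0: positional jitter only.  d1: anterior translation drawn from the
    condition's distribution plus an axial rotation about the vertical line
    through the tibial ABI, plus jitter.  The returned ground truth records
    the exact transform.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown ACL condition {condition!r}")
    if configuration not in CONFIGURATIONS:
        raise ConfigurationError(f"unknown loading configuration {configuration!r}")

    eff = effects[condition]
    jitter = rng.normal(0.0, noise_sd_mm, size=3) if noise_sd_mm > 0 else np.zeros(3)
    if configuration == "d1":
        t_mag = float(rng.normal(eff.loaded_translation_mean_mm, eff.loaded_translation_sd_mm))
        rot_deg = float(rng.normal(eff.rotation_mean_deg, eff.rotation_sd_deg))
        translation = np.array([0.0, -t_mag, 0.0]) + jitter
    else:
        translation = jitter
        rot_deg = 0.0

    pivot = bones.tibial_abi
    Rm = rotation_about_z(rot_deg)
    t_vec = pivot - Rm @ pivot + translation

    def move_point(p: np.ndarray) -> np.ndarray:
        return Rm @ p + t_vec

    def move_solids(solids: list[Solid]) -> list[Solid]:
        return [s.transformed(Rm, t_vec) for s in solids]

    tibia_solids = move_solids(bones.tibia_solids)
    if meniscus_attachment == "tibia":
        men_med = move_solids(bones.meniscus_medial)
        men_lat = move_solids(bones.meniscus_lateral)
    else:
        men_med = list(bones.meniscus_medial)
        men_lat = list(bones.meniscus_lateral)

    moved = BoneModels(
        femur_solids=list(bones.femur_solids),
        tibia_solids=tibia_solids,
        meniscus_medial=men_med,
        meniscus_lateral=men_lat,
        femoral_axis_point=bones.femoral_axis_point.copy(),
        femoral_axis_direction=bones.femoral_axis_direction.copy(),
        tibial_axis_point=move_point(bones.tibial_axis_point),
        tibial_axis_direction=Rm @ bones.tibial_axis_direction,
        femoral_abi=bones.femoral_abi.copy(),
        tibial_abi=move_point(bones.tibial_abi),
        femoral_landmark=bones.femoral_landmark.copy(),
        tibial_landmark=move_point(bones.tibial_landmark),
    )
    gt = GroundTruthCell(
        specimen=specimen, condition=condition, configuration=configuration, side=side,
        translation_mm=translation, rotation_deg=rot_deg,
        femoral_axis_point=moved.femoral_axis_point,
        femoral_axis_direction=moved.femoral_axis_direction,
        tibial_axis_point=moved.tibial_axis_point,
        tibial_axis_direction=moved.tibial_axis_direction,
        femoral_abi=moved.femoral_abi, tibial_abi=moved.tibial_abi,
        femoral_landmark=moved.femoral_landmark, tibial_landmark=moved.tibial_landmark,
    )
    return moved, gt


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(
    solids_with_labels: list[tuple[Solid, int]],
    spacing_mm: tuple[float, float, float],
    volume_shape: tuple[int, int, int],
    slice_gap_mm: float = 0.0,
) -> LabeledVolume:
    """Voxelize analytic solids: a voxel is labeled iff its center is inside.

    Later entries overwrite earlier ones where solids overlap.  A solid
    whose bounding box leaves the field of view raises
    :class:`FieldOfViewError` naming the solid.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    shape = tuple(int(n) for n in volume_shape)
    labels = np.zeros(shape, dtype=np.uint8)
    fov_lo = -spacing / 2
    fov_hi = (np.asarray(shape) - 1) * spacing + spacing / 2

    for solid, label in solids_with_labels:
        lo, hi = solid.bounds()
        if np.any(lo < fov_lo - 1e-9) or np.any(hi > fov_hi + 1e-9):
            raise FieldOfViewError(
                f"solid '{solid.name}' (bounds {lo.round(2).tolist()}..{hi.round(2).tolist()}) "
                f"exceeds the field of view {fov_lo.round(2).tolist()}..{fov_hi.round(2).tolist()}")
        i_lo = np.maximum(np.floor(lo / spacing).astype(int), 0)
        i_hi = np.minimum(np.ceil(hi / spacing).astype(int), np.asarray(shape) - 1)
        axes = [np.arange(i_lo[d], i_hi[d] + 1) for d in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        pts = grid.reshape(-1, 3) * spacing
        inside = solid.contains(pts).reshape(grid.shape[:-1])
        sub = labels[i_lo[0]:i_hi[0] + 1, i_lo[1]:i_hi[1] + 1, i_lo[2]:i_hi[2] + 1]
        sub[inside] = label

    # the third spacing component is the slice pitch = thickness + gap
    return LabeledVolume(
        labels=labels,
        in_plane_spacing_mm=(float(spacing[0]), float(spacing[1])),
        slice_thickness_mm=float(spacing[2]) - slice_gap_mm,
        slice_gap_mm=slice_gap_mm,
        slice_axis=2,
    )


def bones_to_labeled_solids(bones: BoneModels) -> list[tuple[Solid, int]]:
    out = [(s, LABEL_FEMUR) for s in bones.femur_solids]
    out += [(s, LABEL_TIBIA) for s in bones.tibia_solids]
    out += [(s, LABEL_MENISCUS_MEDIAL) for s in bones.meniscus_medial]
    out += [(s, LABEL_MENISCUS_LATERAL) for s in bones.meniscus_lateral]
    return out


# ---------------------------------------------------------------------------
# Study synthesis
# ---------------------------------------------------------------------------

def synthesize_cell(
    spec: PhantomSpec,
    specimen_index: int,
    condition: str,
    configuration: str,
) -> tuple[LabeledVolume, dict, GroundTruthCell]:
    """Generate one study cell: label volume, annotations, ground truth.

    Annotation landmarks carry digitization noise of SD ``noise_sd_mm``;
    annotation axes/ABIs are the exact ground truth (they are consumed only
    in 'annotated' mode, emulating the manual workflow).  Left-side
    specimens are mirrored across the sagittal plane at the voxel level.
    """
    bones = build_bone_models(spec, specimen_index)
    cell_idx = CONDITIONS.index(condition) * 2 + CONFIGURATIONS.index(configuration)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(specimen_index, 1 + cell_idx)))
    side = spec.side_of(specimen_index)
    name = f"S{specimen_index:02d}"

    moved, gt = apply_condition_transform(
        bones, condition, configuration, spec.condition_effects, rng,
        noise_sd_mm=spec.noise_sd_mm, meniscus_attachment=spec.meniscus_attachment,
        specimen=name, side=side)

    volume = rasterize(bones_to_labeled_solids(moved), spec.spacing_mm, spec.volume_shape,
                       slice_gap_mm=spec.slice_gap_mm)
    if side == "left":
        # a left knee is the sagittal mirror image of the canonical right-knee
        # construction; its axis semantics stay patient-relative (+lateral),
        # and canonicalize(volume, "left") undoes the mirror exactly
        volume = LabeledVolume(
            labels=np.ascontiguousarray(np.flip(volume.labels, axis=0)),
            in_plane_spacing_mm=volume.in_plane_spacing_mm,
            slice_thickness_mm=volume.slice_thickness_mm,
            slice_gap_mm=volume.slice_gap_mm,
            slice_axis=volume.slice_axis,
        )

    lm_noise = rng.normal(0.0, spec.noise_sd_mm, size=(2, 3)) if spec.noise_sd_mm > 0 \
        else np.zeros((2, 3))
    annotations = {
        "side": side,
        "femur": {
            "landmark": (gt.femoral_landmark + lm_noise[0]).tolist(),
            "axis": {"point": gt.femoral_axis_point.tolist(),
                     "direction": gt.femoral_axis_direction.tolist()},
            "abi": gt.femoral_abi.tolist(),
        },
        "tibia": {
            "landmark": (gt.tibial_landmark + lm_noise[1]).tolist(),
            "axis": {"point": gt.tibial_axis_point.tolist(),
                     "direction": gt.tibial_axis_direction.tolist()},
            "abi": gt.tibial_abi.tolist(),
        },
    }
    return volume, annotations, gt


def iter_cells(spec: PhantomSpec):
    """Yield (specimen_index, condition, configuration) in generation order."""
    for i in range(spec.n_specimens):
        for condition in CONDITIONS:
            for configuration in CONFIGURATIONS:
                yield i, condition, configuration


def generate_study(spec: PhantomSpec, outdir) -> tuple[list[ManifestRecord], dict]:
    """Write the full synthetic study to ``outdir``.

    Emits one NIfTI label volume (+ JSON sidecar) and one annotation JSON
    per cell, a study manifest, and the ground-truth JSON.  Returns the
    manifest records and the ground-truth dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    gt_all: dict = {"seed": spec.seed, "cells": []}
    for i, condition, configuration in iter_cells(spec):
        volume, annotations, gt = synthesize_cell(spec, i, condition, configuration)
        stem = f"S{i:02d}_{condition}_{configuration}"
        vol_path = outdir / f"{stem}.nii"
        ann_path = outdir / f"{stem}_annotations.json"
        write_volume(volume, vol_path)
        write_annotations(annotations, ann_path)
        records.append(ManifestRecord(
            volume_path=str(vol_path), annotation_path=str(ann_path),
            specimen=gt.specimen, condition=condition, configuration=configuration,
            side=gt.side))
        gt_all["cells"].append(gt.to_dict())
    write_manifest(records, outdir / "manifest.json")
    (outdir / "ground_truth.json").write_text(json.dumps(gt_all, indent=2))
    return records, gt_all
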