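"""Per-bone geometric frame: central axis, axis-bone intersection, landmark.

The central bone axis is estimated as the principal component of the
diaphyseal (shaft) voxel cloud in mm coordinates, where the shaft region is
the fraction of the bone's long extent farthest from the joint.  This is an
algorithmic surrogate for manually digitised axes: restricting the fit to
the diaphysis avoids bias from the condylar/plateau masses, and a principal
axis is reproducible where manual endpoint placement is not.

The axis-bone intersection (ABI) is the sub-voxel point where the central
axis exits the bone mask on the joint-facing side, found by marching along
the axis at a step of half the smallest voxel spacing and refining the
final inside->outside crossing by linear interpolation.

Axis directions are oriented joint -> shaft (femoral axis points proximal,
tibial axis distal) so that downstream projected inter-axis angles carry
the extension ~ 180 deg semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AnnotationError,
    AxisUndefinedError,
    InsufficientMaskError,
    NoIntersectionError,
)
from .volume_io import LABEL_FEMUR, LABEL_TIBIA, LabeledVolume, voxel_to_mm

BONE_LABELS = {"femur": LABEL_FEMUR, "tibia": LABEL_TIBIA}

#: minimum voxel count for axis estimation
MIN_MASK_VOXELS = 100
#: reject axis fits whose first/second principal-variance ratio is below this
ISOTROPY_RATIO = 1.2


@dataclass
class AxisLine:
    point: np.ndarray  # a point on the axis, mm
    direction: np.ndarray  # unit, oriented joint -> shaft

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise AxisUndefinedError("axis direction must be non-zero")
        self.direction = d / n


@dataclass
class BoneFrame:
    """Central axis, ABI and anatomic landmark of one bone in canonical mm."""

    bone: str  # "femur" | "tibia"
    axis_point: np.ndarray
    axis_direction: np.ndarray  # unit, joint -> shaft
    abi: np.ndarray
    landmark: np.ndarray
    provenance: str  # "estimated" | "annotated"

    def __post_init__(self):
        for name in ("axis_point", "axis_direction", "abi", "landmark"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = np.linalg.norm(self.axis_direction)
        if abs(n - 1.0) > 1e-9:
            self.axis_direction = self.axis_direction / n


def _bone_coords_mm(volume: LabeledVolume, bone: str) -> np.ndarray:
    label = BONE_LABELS[bone]
    idx = np.argwhere(volume.labels == label)
    if len(idx) < MIN_MASK_VOXELS:
        raise InsufficientMaskError(
            f"{bone}: {len(idx)} labeled voxels (< {MIN_MASK_VOXELS})")
    return idx * volume.grid_spacing_mm


def _other_bone_centroid(volume: LabeledVolume, bone: str) -> np.ndarray:
    other = "tibia" if bone == "femur" else "femur"
    return _bone_coords_mm(volume, other).mean(axis=0)


def estimate_central_axis(
    volume: LabeledVolume, bone: str, shaft_fraction: float = 0.5
) -> AxisLine:
    """Principal-axis fit to the shaft region of a bone mask.

    The bone's long extent is found by a PCA over all bone voxels; the
    joint-facing end is the extreme nearest the other bone's centroid, and
    the shaft region is the ``shaft_fraction`` of the extent farthest from
    it.  The returned direction is oriented joint -> shaft.
    """
    if not 0 < shaft_fraction <= 1:
        raise ValueError("shaft_fraction must be in (0, 1]")
    coords = _bone_coords_mm(volume, bone)

    def principal(c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        centroid = c.mean(axis=0)
        cov = np.cov((c - centroid).T)
        evals, evecs = np.linalg.eigh(cov)
        return centroid, evals[::-1], evecs[:, ::-1]

    centroid, evals, evecs = principal(coords)
    if evals[0] < ISOTROPY_RATIO * max(evals[1], 1e-12):
        raise AxisUndefinedError(
            f"{bone}: near-isotropic voxel cloud (variance ratio "
            f"{evals[0] / max(evals[1], 1e-12):.3f} < {ISOTROPY_RATIO})")
    long_dir = evecs[:, 0]

    proj = (coords - centroid) @ long_dir
    other = _other_bone_centroid(volume, bone)
    other_proj = (other - centroid) @ long_dir
    # joint end = extreme of the long extent nearest the other bone
    joint_at_max = abs(proj.max() - other_proj) < abs(proj.min() - other_proj)
    span = proj.max() - proj.min()
    # shaft region: the shaft_fraction of the long extent farthest from the joint
    if joint_at_max:
        shaft_sel = proj <= proj.min() + shaft_fraction * span
    else:
        shaft_sel = proj >= proj.max() - shaft_fraction * span
    shaft = coords[shaft_sel] if shaft_sel.sum() >= MIN_MASK_VOXELS else coords

    s_centroid, s_evals, s_evecs = principal(shaft)
    if s_evals[0] < ISOTROPY_RATIO * max(s_evals[1], 1e-12):
        raise AxisUndefinedError(f"{bone}: shaft voxel cloud has no principal elongation")
    direction = s_evecs[:, 0]
    # orient joint -> shaft: shaft centroid lies opposite the joint end
    joint_point = centroid + (proj.max() if joint_at_max else proj.min()) * long_dir
    if np.dot(direction, s_centroid - joint_point) < 0:
        direction = -direction
    return AxisLine(point=s_centroid, direction=direction)


def _inside_mask(volume: LabeledVolume, label: int, pts_mm: np.ndarray) -> np.ndarray:
    """Nearest-voxel membership of mm points in a label mask."""
    idx = np.rint(pts_mm / volume.grid_spacing_mm).astype(int)
    shape = np.asarray(volume.labels.shape)
    valid = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(pts_mm), dtype=bool)
    if valid.any():
        v = idx[valid]
        out[valid] = volume.labels[v[:, 0], v[:, 1], v[:, 2]] == label
    return out


def compute_abi(volume: LabeledVolume, bone: str, axis: AxisLine) -> np.ndarray:
    """Sub-voxel axis-bone intersection on the joint-facing side.

    Marches from the shaft along -direction (toward the joint) at a step of
    half the smallest spacing; the ABI is the midpoint of the last
    inside -> first outside step (linear interpolation of the binary
    inside/outside samples).
    """
    label = BONE_LABELS[bone]
    step = float(volume.grid_spacing_mm.min()) / 2.0
    extent = float(np.linalg.norm(np.asarray(volume.labels.shape) * volume.grid_spacing_mm))
    # sample the whole axis chord through the volume, walking toward the joint
    s = np.arange(-extent, extent + step, step)
    pts = axis.point[None, :] - s[:, None] * axis.direction[None, :]
    inside = _inside_mask(volume, label, pts)
    if not inside.any():
        raise NoIntersectionError(f"{bone}: axis never enters the bone mask")
    last_in = np.max(np.nonzero(inside)[0])
    if last_in == len(s) - 1:
        raise NoIntersectionError(
            f"{bone}: axis does not exit the mask toward the joint within the volume")
    return (pts[last_in] + pts[last_in + 1]) / 2.0


def assemble_frames(
    volume: LabeledVolume,
    annotations: dict,
    mode: str = "estimated",
    shaft_fraction: float = 0.5,
) -> tuple[BoneFrame, BoneFrame]:
    """Build the femoral and tibial frames for one study cell.

    ``annotated`` mode consumes manually digitised axes (and, when present,
    ABIs) verbatim, emulating the manual workflow; ``estimated`` mode fits
    axes from the masks.  Landmarks always come from the annotation file.
    """
    if mode not in ("estimated", "annotated"):
        raise ValueError(f"mode must be 'estimated' or 'annotated', got {mode!r}")
    frames = []
    for bone in ("femur", "tibia"):
        entry = annotations.get(bone) or {}
        if "landmark" not in entry:
            raise AnnotationError(f"{bone}: missing landmark annotation")
        landmark = np.asarray(entry["landmark"], dtype=float)
        if mode == "annotated":
            if "axis" not in entry or entry["axis"] is None:
                raise AnnotationError(f"{bone}: annotated mode requires an axis annotation")
            axis = AxisLine(point=entry["axis"]["point"], direction=entry["axis"]["direction"])
            abi = (np.asarray(entry["abi"], dtype=float) if entry.get("abi") is not None
                   else compute_abi(volume, bone, axis))
        else:
            axis = estimate_central_axis(volume, bone, shaft_fraction=shaft_fraction)
            abi = compute_abi(volume, bone, axis)
        frames.append(BoneFrame(
            bone=bone, axis_point=axis.point, axis_direction=axis.direction,
            abi=abi, landmark=landmark, provenance=mode))
    return frames[0], frames[1]
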