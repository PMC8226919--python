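"""Labeled-volume, annotation and manifest I/O plus voxel→mm conversion.

Conventions
-----------
* Voxel indices are 0-based and refer to voxel *centers*; fractional indices
  are allowed for sub-voxel positions.
* The through-plane coordinate advances by the slice *pitch*, i.e. slice
  thickness plus inter-slice gap (3.0 + 0.3 = 3.3 mm for the default
  acquisition geometry), which places each slice's coordinate at its center.
* The canonical anatomical frame is that of a right knee:
  x = +lateral, y = +posterior, z = +proximal.  Left knees are mirrored
  across the sagittal (x) plane so that all downstream measures share one
  sign convention: positive x/y/z components of a femur-minus-tibia vector
  mean a more lateral/posterior/proximal femoral point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AnnotationError, MetadataError

VALID_LABELS = frozenset({0, 1, 2, 3, 4})
LABEL_BACKGROUND = 0
LABEL_FEMUR = 1
LABEL_TIBIA = 2
LABEL_MENISCUS_MEDIAL = 3
LABEL_MENISCUS_LATERAL = 4

CONDITIONS = ("intact", "partial", "complete")
CONFIGURATIONS = ("d0", "d1")  # unloaded / loaded
SIDES = ("left", "right")

# direction of increasing grid index, one entry per grid axis
_DIRECTION_FAMILY = {
    "lateral": "ml", "medial": "ml",
    "posterior": "ap", "anterior": "ap",
    "proximal": "si", "distal": "si",
}
CANONICAL_SEMANTICS = ("lateral", "posterior", "proximal")


@dataclass
class LabeledVolume:
    """A 3D label map with acquisition-geometry metadata.

    ``labels`` holds integer labels {0 background, 1 femur, 2 tibia,
    3 medial meniscus, 4 lateral meniscus}.  ``axis_semantics`` names the
    anatomical direction of increasing index for each grid axis.
    """

    labels: np.ndarray
    in_plane_spacing_mm: tuple[float, float] = (0.36, 0.36)
    slice_thickness_mm: float = 3.0
    slice_gap_mm: float = 0.3
    slice_axis: int = 2
    axis_semantics: tuple[str, str, str] = CANONICAL_SEMANTICS
    applied_flips: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise MetadataError("labels must be a 3D array")
        if any(s <= 0 for s in self.in_plane_spacing_mm) or self.slice_thickness_mm <= 0:
            raise MetadataError("voxel spacing components must be positive")
        if self.slice_gap_mm < 0:
            raise MetadataError("inter-slice gap must be non-negative")
        if self.slice_axis not in (0, 1, 2):
            raise MetadataError("slice_axis must be 0, 1 or 2")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise MetadataError(f"unknown labels present: {sorted(present - VALID_LABELS)}")
        fams = [_DIRECTION_FAMILY.get(s) for s in self.axis_semantics]
        if None in fams or len(set(fams)) != 3:
            raise MetadataError(
                f"axis_semantics {self.axis_semantics!r} must map the three grid axes "
                "bijectively onto mediolateral/anteroposterior/craniocaudal directions"
            )

    @property
    def slice_pitch_mm(self) -> float:
        """Through-plane sampling distance: slice thickness + inter-slice gap."""
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def grid_spacing_mm(self) -> np.ndarray:
        """Per-grid-axis sampling distance (slice axis carries the pitch)."""
        spacing = np.empty(3)
        in_plane = iter(self.in_plane_spacing_mm)
        for ax in range(3):
            spacing[ax] = self.slice_pitch_mm if ax == self.slice_axis else next(in_plane)
        return spacing

    def is_canonical(self) -> bool:
        return tuple(self.axis_semantics) == CANONICAL_SEMANTICS


def voxel_to_mm(index, volume: LabeledVolume) -> np.ndarray:
    """Convert a (possibly fractional) 0-based voxel index to mm coordinates.

    In-plane axes scale by the in-plane spacing; the through-plane axis
    scales by the slice pitch (thickness + gap).
    """
    spacing = volume.grid_spacing_mm
    if np.any(spacing <= 0):
        raise MetadataError("voxel spacing must be positive")
    return np.asarray(index, dtype=float) * spacing


def mm_to_voxel(coords_mm, volume: LabeledVolume) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm` (fractional indices)."""
    return np.asarray(coords_mm, dtype=float) / volume.grid_spacing_mm


def canonicalize(volume: LabeledVolume, side: str) -> LabeledVolume:
    """Reorder/flip the grid into the canonical right-knee frame.

    After canonicalization axis 0 = +lateral, 1 = +posterior, 2 = +proximal.
    Left knees are additionally mirrored across the sagittal plane, which
    makes them geometrically right-knee-like; the applied flips are recorded
    in ``applied_flips``.
    """
    if side not in SIDES:
        raise MetadataError(f"side must be one of {SIDES}, got {side!r}")
    fams = [_DIRECTION_FAMILY[s] for s in volume.axis_semantics]
    target_fams = [_DIRECTION_FAMILY[s] for s in CANONICAL_SEMANTICS]
    try:
        perm = [fams.index(tf) for tf in target_fams]
    except ValueError as exc:  # pragma: no cover - __post_init__ guards this
        raise MetadataError("axis_semantics do not cover all anatomical directions") from exc

    labels = np.transpose(volume.labels, perm)
    spacing = volume.grid_spacing_mm[perm]
    semantics = [volume.axis_semantics[p] for p in perm]
    slice_axis = perm.index(volume.slice_axis)
    flips: list[str] = list(volume.applied_flips)

    for ax in range(3):
        if semantics[ax] != CANONICAL_SEMANTICS[ax]:
            labels = np.flip(labels, axis=ax)
            semantics[ax] = CANONICAL_SEMANTICS[ax]
            flips.append(f"polarity:{ax}")
    if side == "left":
        labels = np.flip(labels, axis=0)
        flips.append("mirror:sagittal")

    in_plane = tuple(spacing[ax] for ax in range(3) if ax != slice_axis)
    return LabeledVolume(
        labels=np.ascontiguousarray(labels),
        in_plane_spacing_mm=in_plane,  # type: ignore[arg-type]
        slice_thickness_mm=volume.slice_thickness_mm,
        slice_gap_mm=volume.slice_gap_mm,
        slice_axis=slice_axis,
        axis_semantics=tuple(semantics),  # type: ignore[arg-type]
        applied_flips=flips,
    )


# ---------------------------------------------------------------------------
# NIfTI label volumes (spacing in the header, gap in a JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: LabeledVolume, path) -> Path:
    """Write the label map as NIfTI; metadata the header cannot carry
    (inter-slice gap, axis semantics) goes to a JSON sidecar."""
    path = Path(path)
    affine = np.diag(list(volume.grid_spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.labels.astype(np.uint8), affine)
    img.header.set_zooms(tuple(volume.grid_spacing_mm))
    nib.save(img, str(path))
    sidecar = {
        "slice_thickness_mm": volume.slice_thickness_mm,
        "slice_gap_mm": volume.slice_gap_mm,
        "slice_axis": volume.slice_axis,
        "axis_semantics": list(volume.axis_semantics),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path) -> LabeledVolume:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    slice_axis = int(meta["slice_axis"])
    pitch = float(meta["slice_thickness_mm"]) + float(meta["slice_gap_mm"])
    if not np.isclose(zooms[slice_axis], pitch, atol=1e-4):
        raise MetadataError(
            f"header through-plane spacing {zooms[slice_axis]} does not equal "
            f"thickness+gap {pitch}"
        )
    in_plane = tuple(zooms[ax] for ax in range(3) if ax != slice_axis)
    return LabeledVolume(
        labels=labels,
        in_plane_spacing_mm=in_plane,  # type: ignore[arg-type]
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        slice_gap_mm=float(meta["slice_gap_mm"]),
        slice_axis=slice_axis,
        axis_semantics=tuple(meta["axis_semantics"]),
    )


# ---------------------------------------------------------------------------
# Annotations: canonical-frame mm coordinates per bone
# ---------------------------------------------------------------------------

def _check_triple(value, where: str) -> list[float]:
    if (not isinstance(value, (list, tuple))) or len(value) != 3:
        raise AnnotationError(f"{where}: expected a 3-element coordinate, got {value!r}")
    try:
        return [float(v) for v in value]
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"{where}: non-numeric coordinate {value!r}") from exc


def validate_annotations(ann: dict, source: str = "<annotations>") -> dict:
    """Schema check for an annotation record.

    Per bone: required ``landmark`` [x, y, z] in canonical mm; optional
    ``axis`` {point, direction}; optional ``abi``.  Optional top-level
    ``side`` and ``slice_overrides`` {medial, lateral}.
    """
    if not isinstance(ann, dict):
        raise AnnotationError(f"{source}: annotation root must be an object")
    out: dict = {}
    for bone in ("femur", "tibia"):
        entry = ann.get(bone)
        if entry is None:
            raise AnnotationError(f"{source}: missing '{bone}' entry")
        if "landmark" not in entry:
            raise AnnotationError(f"{source}: {bone}: missing required 'landmark'")
        rec = {"landmark": _check_triple(entry["landmark"], f"{source}: {bone}.landmark")}
        if entry.get("axis") is not None:
            axis = entry["axis"]
            for key in ("point", "direction"):
                if key not in axis:
                    raise AnnotationError(f"{source}: {bone}.axis: missing '{key}'")
            rec["axis"] = {
                "point": _check_triple(axis["point"], f"{source}: {bone}.axis.point"),
                "direction": _check_triple(axis["direction"], f"{source}: {bone}.axis.direction"),
            }
            if np.linalg.norm(rec["axis"]["direction"]) == 0:
                raise AnnotationError(f"{source}: {bone}.axis.direction must be non-zero")
        if entry.get("abi") is not None:
            rec["abi"] = _check_triple(entry["abi"], f"{source}: {bone}.abi")
        out[bone] = rec
    if "side" in ann:
        if ann["side"] not in SIDES:
            raise AnnotationError(f"{source}: side must be one of {SIDES}")
        out["side"] = ann["side"]
    if "slice_overrides" in ann:
        so = ann["slice_overrides"]
        if not isinstance(so, dict) or not set(so) <= {"medial", "lateral"}:
            raise AnnotationError(f"{source}: slice_overrides keys must be medial/lateral")
        out["slice_overrides"] = {k: int(v) for k, v in so.items()}
    return out


def read_annotations(path) -> dict:
    path = Path(path)
    return validate_annotations(json.loads(path.read_text()), source=str(path))


def write_annotations(ann: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ann, indent=2))
    return path


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    volume_path: str
    annotation_path: str
    specimen: str
    condition: str
    configuration: str
    side: str


def validate_manifest(records: list[dict], source: str = "<manifest>") -> list[ManifestRecord]:
    out: list[ManifestRecord] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(records):
        where = f"{source}: record {i}"
        for key in ("volume_path", "annotation_path", "specimen", "condition",
                    "configuration", "side"):
            if key not in rec:
                raise AnnotationError(f"{where}: missing field '{key}'")
        if rec["condition"] not in CONDITIONS:
            raise AnnotationError(
                f"{where}: condition {rec['condition']!r} not in {CONDITIONS}")
        if rec["configuration"] not in CONFIGURATIONS:
            raise AnnotationError(
                f"{where}: configuration {rec['configuration']!r} not in {CONFIGURATIONS}")
        if rec["side"] not in SIDES:
            raise AnnotationError(f"{where}: side {rec['side']!r} not in {SIDES}")
        key = (rec["specimen"], rec["condition"], rec["configuration"])
        if key in seen:
            raise AnnotationError(f"{where}: duplicate study cell {key}")
        seen.add(key)
        out.append(ManifestRecord(
            volume_path=str(rec["volume_path"]),
            annotation_path=str(rec["annotation_path"]),
            specimen=str(rec["specimen"]),
            condition=rec["condition"],
            configuration=rec["configuration"],
            side=rec["side"],
        ))
    return out


def read_manifest(path) -> list[ManifestRecord]:
    path = Path(path)
    return validate_manifest(json.loads(path.read_text()), source=str(path))


def write_manifest(records: list[ManifestRecord], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([vars(r) for r in records], indent=2))
    return path
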