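"""Automated 2D reference measures from mid-sagittal compartment slices.

Emulates the manual PACS-ruler protocol: on the mid-sagittal slice of each
femorotibial compartment, vertical tangent lines are dropped at the
posterior margins of three structures, and horizontal (anteroposterior)
distances between tangents are reported:

* LMD / MMD - distance between the tangent at the base of the lateral /
  medial meniscus posterior horn and the tangent at the posterior margin of
  the tibial plateau; positive = horn anterior to the plateau margin.
* LTP/LFC and MTP/MFC - distance between the tangents at the posterior
  margins of the femoral condyle and the tibial plateau; positive =
  condyle anterior to the plateau margin.

"Tangential line" is operationalized as the line perpendicular to the
anteroposterior axis through the structure's posterior-most labeled voxel
(no sub-voxel refinement), matching the resolution of the manual ruler
construction.  The posterior horn's base is the inferior half of the
posterior third of the meniscus extent.  The tibial plateau's articular
surface is restricted to the superior 10 mm of the tibia within the slice,
and the femoral condyle to the inferior 25 mm of the femur within the
slice, so diaphyseal voxels can never masquerade as articular margins.

An optional two-reader emulation jitters each tangent placement with a
configurable reader-noise SD to generate paired reader datasets for the
inter-reader agreement (ICC) stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingStructureError
from .volume_io import (
    LABEL_FEMUR,
    LABEL_MENISCUS_LATERAL,
    LABEL_MENISCUS_MEDIAL,
    LABEL_TIBIA,
    LabeledVolume,
    canonicalize,
)

MEASURES_2D = ("LMD", "MMD", "LTP_LFC", "MTP_MFC")

_MENISCUS_LABEL = {"medial": LABEL_MENISCUS_MEDIAL, "lateral": LABEL_MENISCUS_LATERAL}

#: depth of the plateau articular region below the tibia's top, mm
PLATEAU_DEPTH_MM = 10.0
#: height of the condylar region above the femur's bottom, mm
CONDYLE_DEPTH_MM = 25.0


@dataclass
class Reference2D:
    """The four manual-style 2D measures for one study cell (mm)."""

    LMD: float
    MMD: float
    LTP_LFC: float
    MTP_MFC: float
    slice_medial: int
    slice_lateral: int

    def to_dict(self) -> dict:
        return {m: getattr(self, m) for m in MEASURES_2D}


def select_midsagittal_slice(volume: LabeledVolume, compartment: str) -> int:
    """Sagittal slice through the mediolateral centroid of the compartment's
    meniscus; ties between equidistant slices break to the lower index."""
    label = _MENISCUS_LABEL[compartment]
    idx = np.argwhere(volume.labels == label)
    if len(idx) == 0:
        raise MissingStructureError(f"no {compartment} meniscus label in volume")
    centroid = idx[:, 0].mean()
    lo = int(np.floor(centroid))
    return lo if (centroid - lo) <= 0.5 else lo + 1


def _slice_coords_mm(volume: LabeledVolume, slice_index: int, label: int):
    """(y, z) mm coordinates of labeled voxel centers in a sagittal slice."""
    if not 0 <= slice_index < volume.labels.shape[0]:
        raise MissingStructureError(f"slice index {slice_index} outside the grid")
    sl = volume.labels[slice_index]
    iy, iz = np.nonzero(sl == label)
    spacing = volume.grid_spacing_mm
    return iy * spacing[1], iz * spacing[2]


def _posterior_tangent_plateau(volume: LabeledVolume, slice_index: int) -> float:
    y, z = _slice_coords_mm(volume, slice_index, LABEL_TIBIA)
    if len(y) == 0:
        raise MissingStructureError(f"no tibia label in sagittal slice {slice_index}")
    articular = z >= z.max() - PLATEAU_DEPTH_MM
    return float(y[articular].max())


def meniscus_displacement(
    volume: LabeledVolume, slice_index: int, compartment: str,
    reader_noise_sd: float = 0.0, rng: np.random.Generator | None = None,
) -> float:
    """LMD or MMD: plateau posterior tangent minus posterior-horn-base tangent."""
    y, z = _slice_coords_mm(volume, slice_index, _MENISCUS_LABEL[compartment])
    if len(y) == 0:
        raise MissingStructureError(
            f"no {compartment} meniscus label in sagittal slice {slice_index}")
    horn = y >= y.min() + (2.0 / 3.0) * (y.max() - y.min())
    hy, hz = y[horn], z[horn]
    base = hz <= hz.min() + 0.5 * (hz.max() - hz.min())
    if not base.any():
        raise MissingStructureError(f"{compartment} posterior horn base region is empty")
    tangent_horn = float(hy[base].max())
    tangent_plateau = _posterior_tangent_plateau(volume, slice_index)
    if reader_noise_sd > 0 and rng is not None:
        tangent_horn += rng.normal(0.0, reader_noise_sd)
        tangent_plateau += rng.normal(0.0, reader_noise_sd)
    return tangent_plateau - tangent_horn


def condyle_displacement(
    volume: LabeledVolume, slice_index: int, compartment: str,
    reader_noise_sd: float = 0.0, rng: np.random.Generator | None = None,
) -> float:
    """LTP/LFC or MTP/MFC: plateau posterior tangent minus condylar posterior tangent."""
    y, z = _slice_coords_mm(volume, slice_index, LABEL_FEMUR)
    if len(y) == 0:
        raise MissingStructureError(f"no femur label in sagittal slice {slice_index}")
    condylar = z <= z.min() + CONDYLE_DEPTH_MM
    tangent_condyle = float(y[condylar].max())
    tangent_plateau = _posterior_tangent_plateau(volume, slice_index)
    if reader_noise_sd > 0 and rng is not None:
        tangent_condyle += rng.normal(0.0, reader_noise_sd)
        tangent_plateau += rng.normal(0.0, reader_noise_sd)
    return tangent_plateau - tangent_condyle


def compute_cell_2d(
    volume: LabeledVolume,
    side: str = "right",
    annotations: dict | None = None,
    reader_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Reference2D:
    """All four 2D measures for one cell.

    Slice indices come from the meniscus centroids unless the annotation
    file carries manual overrides.  ``reader_noise_sd`` > 0 jitters each
    tangent placement (a simulated reader)."""
    canon = volume if (volume.is_canonical() and side == "right") else canonicalize(volume, side)
    overrides = (annotations or {}).get("slice_overrides", {})
    slices = {}
    for compartment in ("medial", "lateral"):
        if compartment in overrides:
            slices[compartment] = int(overrides[compartment])
        else:
            slices[compartment] = select_midsagittal_slice(canon, compartment)
    return Reference2D(
        LMD=meniscus_displacement(canon, slices["lateral"], "lateral",
                                  reader_noise_sd, rng),
        MMD=meniscus_displacement(canon, slices["medial"], "medial",
                                  reader_noise_sd, rng),
        LTP_LFC=condyle_displacement(canon, slices["lateral"], "lateral",
                                     reader_noise_sd, rng),
        MTP_MFC=condyle_displacement(canon, slices["medial"], "medial",
                                     reader_noise_sd, rng),
        slice_medial=slices["medial"],
        slice_lateral=slices["lateral"],
    )
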