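"""The eleven computed 3D measures for one study cell.

Two 3D Euclidean vectors are formed, each as femoral point minus tibial
point: vector_ABI between the axis-bone intersections and vector_landmarks
between the anatomic landmarks (trochlear apex, tuberosity centre).  In
the canonical right-knee frame a positive x/y/z component therefore reads
as a more lateral/posterior/proximal femoral point.  Each vector is
quantified by its length and its signed projections on the x, y and z
axes (8 measures), and the femoral and tibial central bone axes are
compared through the angles between their orthogonal projections onto the
coronal (xz), sagittal (yz) and axial (xy) planes (3 measures).

Angle conventions (oriented joint -> shaft direction vectors, not
undirected lines):

* yz-angle: sagittal alignment; 180 deg = antiparallel projections =
  nearly full extension, 90 deg = perpendicular axes.
* xz-angle: coronal alignment, reported as the unsigned (medial-sided)
  magnitude together with a varus/valgus sign bit taken from the signed
  angle from the projected tibial to the projected femoral direction about
  the +y axis.
* xy-angle: axial alignment (rotation); 0 deg = parallel projections.

A projection whose in-plane magnitude falls below ``DEGENERACY_EPS`` is
flagged ill-conditioned rather than rejected: projective angles are prone
to cross-plane effects and the flag keeps the pipeline total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import BoneFrame

#: minimum in-plane magnitude of a projected axis direction before its
#: angles are flagged ill-conditioned
DEGENERACY_EPS = 0.1

MEASURES_3D = (
    "length_ABI", "x_ABI", "y_ABI", "z_ABI",
    "length_landmarks", "x_landmarks", "y_landmarks", "z_landmarks",
    "xz_angle", "yz_angle", "xy_angle",
)

# plane -> indices of the retained coordinates
_PLANES = {"xz_angle": (0, 2), "yz_angle": (1, 2), "xy_angle": (0, 1)}


@dataclass
class Kinematics3D:
    """The eleven computed 3D measures for one (specimen, condition, configuration)."""

    length_ABI: float
    x_ABI: float
    y_ABI: float
    z_ABI: float
    length_landmarks: float
    x_landmarks: float
    y_landmarks: float
    z_landmarks: float
    xz_angle: float
    yz_angle: float
    xy_angle: float
    xz_varus_sign: int = 0
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {m: getattr(self, m) for m in MEASURES_3D}


def compute_vectors(femoral: BoneFrame, tibial: BoneFrame) -> tuple[np.ndarray, np.ndarray]:
    """vector_ABI and vector_landmarks, each femoral point - tibial point."""
    vector_abi = femoral.abi - tibial.abi
    vector_landmarks = femoral.landmark - tibial.landmark
    return vector_abi, vector_landmarks


def project_components(vector) -> tuple[float, float, float, float]:
    """Signed x/y/z projections and Euclidean length of a vector."""
    v = np.asarray(vector, dtype=float)
    return float(v[0]), float(v[1]), float(v[2]), float(np.linalg.norm(v))


def projected_angles(
    femoral_direction,
    tibial_direction,
    side: str = "right",
    eps: float = DEGENERACY_EPS,
) -> tuple[float, float, float, int, dict]:
    """Inter-axis angles after orthogonal projection onto the three planes.

    Inputs are unit joint->shaft direction vectors in the canonical
    right-knee frame (left knees are mirrored upstream, so ``side`` only
    documents provenance).  Returns (xz, yz, xy) in degrees, the xz
    varus/valgus sign bit, and per-angle ill-conditioning flags.
    """
    f = np.asarray(femoral_direction, dtype=float)
    t = np.asarray(tibial_direction, dtype=float)
    if np.linalg.norm(f) == 0 or np.linalg.norm(t) == 0:
        raise GeometryError("axis directions must be non-zero")
    f = f / np.linalg.norm(f)
    t = t / np.linalg.norm(t)

    angles: dict[str, float] = {}
    flags: dict[str, bool] = {}
    xz_sign = 0
    for name, (i, j) in _PLANES.items():
        fp = np.array([f[i], f[j]])
        tp = np.array([t[i], t[j]])
        nf, nt = np.linalg.norm(fp), np.linalg.norm(tp)
        flags[name] = bool(nf < eps or nt < eps)
        if nf == 0 or nt == 0:
            angles[name] = float("nan")
            continue
        fp, tp = fp / nf, tp / nt
        cos_a = float(np.clip(fp @ tp, -1.0, 1.0))
        angles[name] = float(np.degrees(np.arccos(cos_a)))
        if name == "xz_angle":
            # signed angle from projected tibial to projected femoral
            # direction about +y: in-plane coords are (x, z)
            signed = np.degrees(np.arctan2(tp[1] * fp[0] - tp[0] * fp[1], cos_a))
            xz_sign = int(np.sign(signed)) if abs(signed) > 1e-12 else 0
    return angles["xz_angle"], angles["yz_angle"], angles["xy_angle"], xz_sign, flags


def measures_from_frames(femoral: BoneFrame, tibial: BoneFrame,
                         side: str = "right", eps: float = DEGENERACY_EPS) -> Kinematics3D:
    """Assemble the full 3D measure record from two bone frames."""
    v_abi, v_lm = compute_vectors(femoral, tibial)
    x_a, y_a, z_a, len_a = project_components(v_abi)
    x_l, y_l, z_l, len_l = project_components(v_lm)
    xz, yz, xy, xz_sign, flags = projected_angles(
        femoral.axis_direction, tibial.axis_direction, side=side, eps=eps)
    return Kinematics3D(
        length_ABI=len_a, x_ABI=x_a, y_ABI=y_a, z_ABI=z_a,
        length_landmarks=len_l, x_landmarks=x_l, y_landmarks=y_l, z_landmarks=z_l,
        xz_angle=xz, yz_angle=yz, xy_angle=xy, xz_varus_sign=xz_sign, flags=flags)


def compute_cell(volume, annotations: dict, side: str = "right",
                 mode: str = "estimated", shaft_fraction: float = 0.5,
                 eps: float = DEGENERACY_EPS) -> Kinematics3D:
    """Full per-cell evaluation: canonicalize -> frames -> measures."""
    from .geometry import assemble_frames
    from .volume_io import canonicalize

    canon = volume if (volume.is_canonical() and side == "right") else canonicalize(volume, side)
    femoral, tibial = assemble_frames(canon, annotations, mode=mode,
                                      shaft_fraction=shaft_fraction)
    return measures_from_frames(femoral, tibial, side=side, eps=eps)
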