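"""Shared domain types, frame conventions, and anthropometric defaults.

Conventions used throughout the package:

* angles are **degrees** at every public boundary (radians only internally);
* lengths in metres, forces in newtons, masses in kilograms;
* the **cab frame** is right-handed with its origin at the seat H-point,
  x forward, y to the driver's left, z up;
* the **eye frame** has z along the neutral line of sight, y up;
* the **shoulder frame** matches the arm chain model: x forward in the
  sagittal plane, y up, z lateral (to the driver's right for the right arm);
* the **hip frame** is the 2-D sagittal leg frame: x forward, y downward.

Every scorer works in its own local frame; a :class:`CockpitLayout` carries
the three rigid transforms that map the cab frame into them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AnthropometricProfile",
    "PostureSample",
    "ControlPoint",
    "Occluder",
    "CockpitLayout",
    "RigidTransform",
    "default_profile",
    "transform_point",
    "standard_frames",
    "PHYSIO_LIMITS",
    "CA_JOINTS",
    "DEFAULT_ANTHROPOMETRY",
    "INTENSIVE_OPS_PER_MINUTE",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2, converts load mass to load force

#: a control operated at or above this rate is "intensive" and must sit in
#: the single-joint comfortable envelope; below it, "secondary" (two-joint
#: maximum envelope).
INTENSIVE_OPS_PER_MINUTE = 4.0

CONTROL_COLORS = ("none", "red", "green", "yellow", "blue", "other")
LIMBS = ("upper", "lower")


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p_local = R @ p_parent + t``.

    ``rotation`` must be orthonormal with determinant +1 (checked on
    construction within 1e-9).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with det = +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotation part only (for directions / normals)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def shifted(self, parent_offset: np.ndarray) -> "RigidTransform":
        """Same transform with the parent-frame origin moved by ``parent_offset``.

        Used to adapt nominal eye/shoulder/hip frames to an individual
        participant (e.g. a taller operator's eye point).
        """
        off = np.asarray(parent_offset, dtype=float).reshape(3)
        return RigidTransform(self.rotation, self.translation - self.rotation @ off)


def transform_point(point: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Map ``point`` through a rigid transform (rotation then translation)."""
    if not isinstance(transform, RigidTransform):
        raise ValueError("transform must be a RigidTransform")
    return transform.apply(point)


# Local-frame axes expressed as rows (p_local = R @ p_cab):
#   eye:      x = cab +y (left), y = cab +z (up),    z = cab +x (forward)
#   shoulder: x = cab +x,        y = cab +z (up),    z = cab -y (right)
#   hip:      x = cab +x,        y = cab -z (down),  z = cab +y
_R_EYE = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
_R_SHOULDER = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
_R_HIP = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


def standard_frames(
    eye_pos=(0.05, 0.0, 0.70),
    shoulder_pos=(0.0, -0.20, 0.55),
    hip_pos=(0.0, 0.0, 0.0),
) -> dict[str, RigidTransform]:
    """Nominal seated-operator frames from cab-frame landmark positions.

    Defaults place the H-point at the cab origin, the right shoulder 0.55 m
    above it, and the eye point 0.70 m above and slightly forward.
    """

    def frame(R: np.ndarray, pos) -> RigidTransform:
        p = np.asarray(pos, dtype=float)
        return RigidTransform(R, -R @ p)

    return {
        "eye_from_cab": frame(_R_EYE, eye_pos),
        "shoulder_from_cab": frame(_R_SHOULDER, shoulder_pos),
        "hip_from_cab": frame(_R_HIP, hip_pos),
    }


# ---------------------------------------------------------------------------
# anthropometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnthropometricProfile:
    """Segment lengths and body-weight parameters of one operator.

    Parameters
    ----------
    upper_arm_len, forearm_len, trunk_len, thigh_len, shank_len
        Segment lengths in metres (all strictly positive).
    body_weight_force
        Body weight in newtons (>= 0).
    upper_body_fraction
        Fraction ``a`` of body weight carried above L5/S1, typically 0.40-0.60.
    extensor_lever
        Spinal-extensor lever arm ``d_muscle`` in metres, typically 0.05-0.07.
    percentile_label
        One of ``P5``, ``P50``, ``P95`` or ``custom``.
    """

    upper_arm_len: float
    forearm_len: float
    trunk_len: float
    thigh_len: float
    shank_len: float
    body_weight_force: float
    upper_body_fraction: float = 0.5
    extensor_lever: float = 0.06
    percentile_label: str = "custom"

    def __post_init__(self) -> None:
        lengths = {
            "upper_arm_len": self.upper_arm_len,
            "forearm_len": self.forearm_len,
            "trunk_len": self.trunk_len,
            "thigh_len": self.thigh_len,
            "shank_len": self.shank_len,
        }
        for name, v in lengths.items():
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.body_weight_force < 0:
            raise ValueError("body_weight_force must be >= 0")
        if not 0.40 <= self.upper_body_fraction <= 0.60:
            warnings.warn(
                "upper_body_fraction outside the typical 0.40-0.60 range",
                stacklevel=2,
            )
        if not 0.05 <= self.extensor_lever <= 0.07:
            warnings.warn(
                "extensor_lever outside the typical 0.05-0.07 m range",
                stacklevel=2,
            )

    def scaled(self, factor: float) -> "AnthropometricProfile":
        """All segment lengths multiplied by ``factor`` (weight unchanged)."""
        return replace(
            self,
            upper_arm_len=self.upper_arm_len * factor,
            forearm_len=self.forearm_len * factor,
            trunk_len=self.trunk_len * factor,
            thigh_len=self.thigh_len * factor,
            shank_len=self.shank_len * factor,
            percentile_label="custom",
        )


# Adult-male convenience defaults (metres / newtons).  These are shipped
# configuration, not constants: substitute any published anthropometric
# source for a given population via files.load_anthropometry().
DEFAULT_ANTHROPOMETRY: dict[str, dict[str, float]] = {
    "P5": {
        "upper_arm_len": 0.289,
        "forearm_len": 0.216,
        "trunk_len": 0.520,
        "thigh_len": 0.413,
        "shank_len": 0.344,
        "body_weight_force": 560.0,
    },
    "P50": {
        "upper_arm_len": 0.313,
        "forearm_len": 0.237,
        "trunk_len": 0.560,
        "thigh_len": 0.465,
        "shank_len": 0.369,
        "body_weight_force": 660.0,
    },
    "P95": {
        "upper_arm_len": 0.338,
        "forearm_len": 0.258,
        "trunk_len": 0.600,
        "thigh_len": 0.505,
        "shank_len": 0.396,
        "body_weight_force": 785.0,
    },
}


def default_profile(percentile_label: str) -> AnthropometricProfile:
    """Built-in male P5/P50/P95 manikin profile.

    ``upper_body_fraction`` defaults to 0.5 and ``extensor_lever`` to 0.06 m,
    the midpoints of their typical ranges.
    """
    if percentile_label not in DEFAULT_ANTHROPOMETRY:
        raise ValueError(
            f"unknown percentile label {percentile_label!r}; expected one of "
            f"{sorted(DEFAULT_ANTHROPOMETRY)}"
        )
    return AnthropometricProfile(
        percentile_label=percentile_label,
        **DEFAULT_ANTHROPOMETRY[percentile_label],
    )


# ---------------------------------------------------------------------------
# posture samples
# ---------------------------------------------------------------------------

#: joints of the comfort-assessment (Krist-style) deviation table
CA_JOINTS = ("shoulder_abduction", "elbow_flexion", "lumbar_flexion", "knee_flexion")

#: physiological joint limits in degrees (signed conventions: shoulder
#: extension / adduction / pronation and leftward head or trunk motion are
#: negative).  Used by validation — out-of-range values are flagged, never
#: silently clamped.
PHYSIO_LIMITS: dict[str, tuple[float, float]] = {
    "shoulder_flexion": (-60.0, 180.0),
    "shoulder_abduction": (-20.0, 180.0),
    "elbow_flexion": (0.0, 150.0),
    "forearm_rotation": (-80.0, 90.0),
    "trunk_flexion": (0.0, 60.0),
    "trunk_lateral": (-30.0, 30.0),
    "head_yaw": (-90.0, 90.0),
    "head_pitch": (-70.0, 50.0),
}


@dataclass
class PostureSample:
    """One participant-task joint-angle record (degrees).

    ``joint_angles`` is the per-joint table used by the comfort assessment;
    when omitted it is derived from the named fields.
    """

    participant_id: str
    task_label: str = ""
    shoulder_flexion: float = 0.0
    shoulder_abduction: float = 0.0
    elbow_flexion: float = 90.0
    forearm_rotation: float = 0.0
    trunk_flexion: float = 0.0
    trunk_lateral: float = 0.0
    hip_angle: float = 90.0
    knee_angle: float = 100.0
    head_yaw: float = 0.0
    head_pitch: float = 0.0
    neck_flexion: float = 0.0
    wrist_flexion: float = 0.0
    wrist_twisted: bool = False
    external_load_mass: float = 0.0
    static_or_repetitive: bool = False
    repeat_rate: float = 0.0
    seated: bool = True
    joint_angles: dict[str, float] | None = field(default=None)

    def ca_joint_angles(self) -> dict[str, float]:
        """Joint-angle table for the comfort assessment."""
        if self.joint_angles is not None:
            return dict(self.joint_angles)
        return {
            "shoulder_abduction": self.shoulder_abduction,
            "elbow_flexion": self.elbow_flexion,
            "lumbar_flexion": self.trunk_flexion,
            "knee_flexion": self.knee_angle,
        }


# ---------------------------------------------------------------------------
# cockpit layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlPoint:
    """A control in the cab frame."""

    id: str
    position: np.ndarray
    limb: str = "upper"
    ops_per_minute: float = 1.0
    color: str = "none"
    safety_critical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.limb not in LIMBS:
            raise ValueError(f"limb must be one of {LIMBS}, got {self.limb!r}")
        if self.color not in CONTROL_COLORS:
            raise ValueError(f"color must be one of {CONTROL_COLORS}")
        if self.ops_per_minute < 0:
            raise ValueError("ops_per_minute must be >= 0")

    @property
    def intensive(self) -> bool:
        return self.ops_per_minute >= INTENSIVE_OPS_PER_MINUTE


@dataclass(frozen=True)
class Occluder:
    """A bounded planar occluder (centre, unit normal, two half-extents)."""

    id: str
    center: np.ndarray
    normal: np.ndarray
    half_extents: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        h = np.asarray(self.half_extents, dtype=float).reshape(2)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("occluder normal must have unit norm (within 1e-9)")
        if not np.all(h > 0):
            raise ValueError("half_extents must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "half_extents", h)

    def in_plane_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Natural in-plane orthonormal axes of the bounded rectangle."""
        n = self.normal
        up = np.array([0.0, 0.0, 1.0])
        u = np.cross(n, up)
        if np.linalg.norm(u) < 1e-9:  # normal parallel to z: use x instead
            u = np.cross(n, np.array([1.0, 0.0, 0.0]))
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class CockpitLayout:
    """Controls and occluders in the cab frame, plus the landmark transforms."""

    controls: list[ControlPoint]
    occluders: list[Occluder] = field(default_factory=list)
    eye_from_cab: RigidTransform = field(default_factory=RigidTransform.identity)
    shoulder_from_cab: RigidTransform = field(default_factory=RigidTransform.identity)
    hip_from_cab: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.controls]
        if len(set(ids)) != len(ids):
            raise ValueError("control ids must be unique")

    def with_frames(self, **frames: RigidTransform) -> "CockpitLayout":
        """Copy with some landmark transforms replaced."""
        out = CockpitLayout(
            controls=list(self.controls),
            occluders=list(self.occluders),
            eye_from_cab=frames.get("eye_from_cab", self.eye_from_cab),
            shoulder_from_cab=frames.get("shoulder_from_cab", self.shoulder_from_cab),
            hip_from_cab=frames.get("hip_from_cab", self.hip_from_cab),
        )
        return out

    def for_participant(self, landmark_offset: np.ndarray) -> "CockpitLayout":
        """Layout with all landmark frames shifted by one cab-frame offset.

        Models seat/stature differences between operators: the offset moves
        the eye, shoulder, and hip origins together.
        """
        return self.with_frames(
            eye_from_cab=self.eye_from_cab.shifted(landmark_offset),
            shoulder_from_cab=self.shoulder_from_cab.shifted(landmark_offset),
            hip_from_cab=self.hip_from_cab.shifted(landmark_offset),
        )
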