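"""Posture data input: columnar joint-angle tables, orientation conversion,
an optional BVH reader, and biomechanical validity checking.

Motion-capture exports arrive either as quaternions/Euler angles per body
segment or as already-extracted joint angles.  This module converts the
former (scalar-first quaternions, configurable intrinsic Euler sequence,
Z-Y-X by default) and checks every sample against physiological joint
limits before it reaches a scorer.  Validation reports violations; it never
clamps or imputes.
"""

from __future__ import annotations

from dataclasses import MISSING, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import PHYSIO_LIMITS, AnthropometricProfile, PostureSample

__all__ = [
    "ValidationReport",
    "euler_from_quaternion",
    "quaternion_from_euler",
    "load_posture_table",
    "save_posture_table",
    "validate_biomechanics",
    "read_bvh",
    "posture_from_bvh",
]

DEFAULT_EULER_SEQ = "ZYX"  # intrinsic

_QUAT_NORM_TOL = 1e-6


@dataclass(frozen=True)
class ValidationReport:
    """Biomechanical-validity report for one posture sample.

    ``violations`` lists ``(joint_name, value_deg, (lo_deg, hi_deg))``;
    an empty list means the sample passes.
    """

    sample_id: str
    violations: list[tuple[str, float, tuple[float, float]]] = field(
        default_factory=list
    )

    @property
    def ok(self) -> bool:
        return not self.violations


def _check_unit_quaternion(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float).reshape(4)
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > _QUAT_NORM_TOL:
        raise ValueError(f"quaternion norm {norm:.8f} deviates from 1 beyond 1e-6")
    return q / norm


def euler_from_quaternion(q, seq: str = DEFAULT_EULER_SEQ) -> np.ndarray:
    """Euler angles (deg) of a scalar-first unit quaternion.

    ``seq`` is an intrinsic axis sequence (uppercase, e.g. ``"ZYX"``).
    ``q`` and ``-q`` give identical output (rotation double cover).
    """
    q = _check_unit_quaternion(q)
    # scipy uses scalar-last ordering
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]])
    return rot.as_euler(seq, degrees=True)


def quaternion_from_euler(euler_deg, seq: str = DEFAULT_EULER_SEQ) -> np.ndarray:
    """Scalar-first unit quaternion from Euler angles (deg)."""
    rot = Rotation.from_euler(seq, np.asarray(euler_deg, dtype=float), degrees=True)
    x, y, z, w = rot.as_quat()
    return np.array([w, x, y, z])


# ---------------------------------------------------------------------------
# columnar posture tables
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ("participant_id",)

_ANGLE_COLUMNS = (
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "forearm_rotation",
    "trunk_flexion",
    "trunk_lateral",
    "hip_angle",
    "knee_angle",
    "head_yaw",
    "head_pitch",
    "neck_flexion",
    "wrist_flexion",
)

_BOOL_COLUMNS = ("wrist_twisted", "static_or_repetitive", "seated")


def _sample_defaults() -> dict:
    return {
        f.name: f.default
        for f in dc_fields(PostureSample)
        if f.default is not MISSING  # skip required / factory fields
    }


def load_posture_table(path) -> list[PostureSample]:
    """Read a comma-separated posture table into samples.

    One header row, one data row per (participant, task); column names are
    the :class:`~ergocab.core.PostureSample` field names.  Missing optional
    columns take the documented field defaults (e.g. ``wrist_twisted`` =
    false); a missing mandatory column or a non-numeric / absent angle cell
    is an error naming the column or row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"posture table {path} is missing mandatory column {col!r}")
    defaults = _sample_defaults()
    samples: list[PostureSample] = []
    for i, row in df.iterrows():
        kwargs: dict = {"participant_id": str(row["participant_id"])}
        if "task_label" in df.columns:
            kwargs["task_label"] = str(row["task_label"])
        for col in _ANGLE_COLUMNS:
            if col not in df.columns:
                continue
            value = row[col]
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric angle in column {col!r} at row {i} of {path}"
                ) from None
            if np.isnan(value):
                raise ValueError(f"missing angle in column {col!r} at row {i} of {path}")
            kwargs[col] = value
        for col in _BOOL_COLUMNS:
            if col in df.columns:
                kwargs[col] = bool(row[col])
        for col in ("external_load_mass", "repeat_rate"):
            if col in df.columns:
                kwargs[col] = float(row[col])
        # fill remaining optional fields from dataclass defaults
        for name, default in defaults.items():
            kwargs.setdefault(name, default)
        samples.append(PostureSample(**kwargs))
    return samples


def save_posture_table(samples: list[PostureSample], path) -> None:
    """Write samples to the comma-separated format ``load_posture_table`` reads."""
    cols = (
        ["participant_id", "task_label"]
        + list(_ANGLE_COLUMNS)
        + list(_BOOL_COLUMNS)
        + ["external_load_mass", "repeat_rate"]
    )
    rows = [{c: getattr(s, c) for c in cols} for s in samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# biomechanical validation
# ---------------------------------------------------------------------------

def validate_biomechanics(
    sample: PostureSample, profile: AnthropometricProfile | None = None
) -> ValidationReport:
    """Check every named joint angle against its physiological limits.

    Pure reporting: the sample is never mutated or clamped.  The profile
    argument is accepted for API symmetry with the scorers (limits are
    angular and profile-independent).
    """
    violations = []
    for joint, (lo, hi) in PHYSIO_LIMITS.items():
        value = float(getattr(sample, joint))
        if not np.isfinite(value) or not (lo <= value <= hi):
            violations.append((joint, value, (lo, hi)))
    return ValidationReport(sample_id=sample.participant_id, violations=violations)


# ---------------------------------------------------------------------------
# minimal read-only BVH support
# ---------------------------------------------------------------------------

def read_bvh(path) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Parse a BVH file's HIERARCHY and MOTION sections.

    Returns ``(channels, motion)`` where ``channels`` maps joint name to its
    channel labels and ``motion`` is a frame-indexed table with columns
    ``"<joint>.<channel>"``.  Rotation channels are degrees, as in the file.
    """
    text = Path(path).read_text().split()
    pos = 0

    def next_tok() -> str:
        nonlocal pos
        tok = text[pos]
        pos += 1
        return tok

    channels: dict[str, list[str]] = {}
    order: list[tuple[str, str]] = []  # flattened (joint, channel) in file order
    stack: list[str] = []
    if next_tok().upper() != "HIERARCHY":
        raise ValueError("not a BVH file: missing HIERARCHY")
    while pos < len(text):
        tok = next_tok()
        up = tok.upper()
        if up in ("ROOT", "JOINT"):
            stack.append(next_tok())
        elif up == "END":  # "End Site"
            next_tok()
            stack.append("__end__")
        elif tok == "}":
            stack.pop()
        elif up == "CHANNELS":
            n = int(next_tok())
            labels = [next_tok() for _ in range(n)]
            joint = stack[-1]
            channels[joint] = labels
            order.extend((joint, lab) for lab in labels)
        elif up == "MOTION":
            break
    if next_tok().upper() != "FRAMES:":
        raise ValueError("malformed BVH MOTION section")
    n_frames = int(next_tok())
    # "Frame Time: <dt>"
    next_tok(), next_tok()
    frame_dt = float(next_tok())
    values = np.array([float(next_tok()) for _ in range(n_frames * len(order))])
    motion = pd.DataFrame(
        values.reshape(n_frames, len(order)),
        columns=[f"{j}.{c}" for j, c in order],
    )
    motion.attrs["frame_time"] = frame_dt
    return channels, motion


def posture_from_bvh(
    path,
    joint_map: dict[str, str],
    participant_id: str,
    task_label: str = "",
    frame: int = 0,
) -> PostureSample:
    """Build a posture sample from one BVH frame.

    ``joint_map`` maps :class:`PostureSample` angle fields to BVH motion
    columns (``"<joint>.<channel>"``); capture rigs name joints freely, so
    the mapping is user-supplied.
    """
    _, motion = read_bvh(path)
    if not 0 <= frame < len(motion):
        raise ValueError(f"frame {frame} out of range (0..{len(motion) - 1})")
    kwargs: dict = {"participant_id": participant_id, "task_label": task_label}
    for field_name, column in joint_map.items():
        if field_name not in {f.name for f in dc_fields(PostureSample)}:
            raise ValueError(f"unknown posture field {field_name!r} in joint map")
        if column not in motion.columns:
            raise ValueError(f"BVH file has no channel column {column!r}")
        kwargs[field_name] = float(motion.iloc[frame][column])
    return PostureSample(**kwargs)
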