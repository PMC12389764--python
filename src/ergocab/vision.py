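"""View-frustum, head-rotation field of view, colour recognition zones,
occlusion testing, and the three vision leaf scores.

The visible volume is an asymmetric frustum in the eye frame (z forward):
near/far clipping planes at ``n``/``f``, horizontal half-angle ``theta_h/2``
on each side, and vertical half-angles ``theta_v_up/2`` upward and
``theta_v_down/2`` downward.  Head rotation widens the effective half-angles
to ``(theta + rotation)/2``; because that expression reaches 90 deg within
the physiological head range, effective half-angles are clamped at
``clamp_half_angle`` (89 deg by default).

Leaf scores (all "bad fraction" ratios in [0, 1], higher = worse):

* P1 - controls outside the head-swept field of view / all controls;
* P2 - coloured controls whose colour is not recognizable / coloured controls;
* P3 - controls occluded by any planar occluder / all controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import CockpitLayout, Occluder, PostureSample

__all__ = [
    "VisionParams",
    "VisionScores",
    "frustum_contains",
    "fov_contains",
    "occlusion_test",
    "color_recognizable",
    "score_vision",
]

DEFAULT_COLOR_HALF_ANGLES = {
    "red": 30.0,
    "green": 30.0,
    "yellow": 40.0,
    "blue": 40.0,
    "other": 60.0,
}


@dataclass(frozen=True)
class VisionParams:
    """Frustum geometry and head-rotation limits (angles in degrees)."""

    near: float = 0.3
    far: float = 2.0
    horizontal_fov: float = 120.0
    vertical_fov_up: float = 60.0
    vertical_fov_down: float = 70.0
    yaw_limits: tuple[float, float] = (-90.0, 90.0)
    pitch_limits: tuple[float, float] = (-70.0, 50.0)
    yaw_comfort: tuple[float, float] = (-60.0, 60.0)
    pitch_comfort: tuple[float, float] = (-30.0, 30.0)
    color_half_angles: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_HALF_ANGLES)
    )
    clamp_half_angle: float = 89.0

    def __post_init__(self) -> None:
        if not 0 < self.near < self.far:
            raise ValueError("need 0 < near < far")
        for name in ("horizontal_fov", "vertical_fov_up", "vertical_fov_down"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise ValueError(f"{name} must lie in (0, 180) deg")
        if not self.clamp_half_angle < 90:
            raise ValueError("clamp_half_angle must be < 90 deg")


def _half_tangents(
    params: VisionParams, yaw: float = 0.0, pitch: float = 0.0
) -> tuple[float, float, float]:
    """(tan horizontal, tan up, tan down) half-angle tangents, clamped."""
    cap = params.clamp_half_angle

    def t(theta_plus_rot: float) -> float:
        return math.tan(math.radians(min(theta_plus_rot / 2.0, cap)))

    return (
        t(params.horizontal_fov + yaw),
        t(params.vertical_fov_up + pitch),
        t(params.vertical_fov_down + pitch),
    )


def _contains(points: np.ndarray, params: VisionParams, yaw: float, pitch: float):
    p = np.asarray(points, dtype=float)
    th, tu, td = _half_tangents(params, yaw, pitch)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    return (
        (z >= params.near)
        & (z <= params.far)
        & (np.abs(x) <= z * th)
        & (y <= z * tu)
        & (y >= -z * td)
    )


def frustum_contains(point_eye_frame, params: VisionParams) -> bool | np.ndarray:
    """Is the point (eye frame, z forward) inside the neutral-head frustum?

    Accepts a single point or an ``(..., 3)`` array.
    """
    result = _contains(point_eye_frame, params, 0.0, 0.0)
    return bool(result) if np.ndim(result) == 0 else result


def fov_contains(
    point_eye_frame, yaw: float, pitch: float, params: VisionParams
) -> bool | np.ndarray:
    """Frustum test with half-angles widened by head rotation.

    ``yaw`` / ``pitch`` must lie within the physiological head-rotation
    limits; outside them the posture itself is invalid.
    """
    if not params.yaw_limits[0] <= yaw <= params.yaw_limits[1]:
        raise ValueError(
            f"head yaw {yaw} deg outside physiological range {params.yaw_limits}"
        )
    if not params.pitch_limits[0] <= pitch <= params.pitch_limits[1]:
        raise ValueError(
            f"head pitch {pitch} deg outside physiological range {params.pitch_limits}"
        )
    result = _contains(point_eye_frame, params, yaw, pitch)
    return bool(result) if np.ndim(result) == 0 else result


def occlusion_test(
    target_eye_frame,
    occluder: Occluder,
    params: VisionParams | None = None,
    yaw: float = 0.0,
    pitch: float = 0.0,
) -> bool:
    """Is the sight line from the eye to the target blocked by the occluder?

    The occluder (centre ``S``, unit normal, bounded rectangular extent) is
    expressed in the eye frame.  The sight line is ``r(t) = t * P``; its
    plane intersection parameter is ``t0 = (n . S) / (n . P)``.  The target
    is occluded iff all three hold: ``0 < t0 < 1``, the intersection lies
    within the occluder's bounded extent, and it lies within the field of
    view.  A sight line parallel to the plane never intersects (no division
    by zero).
    """
    p = np.asarray(target_eye_frame, dtype=float).reshape(3)
    n = occluder.normal
    denom = float(n @ p)
    if abs(denom) < 1e-12:
        return False
    t0 = float(n @ occluder.center) / denom
    if not 0.0 < t0 < 1.0:
        return False
    q = t0 * p
    u, v = occluder.in_plane_axes()
    d = q - occluder.center
    if abs(float(d @ u)) > occluder.half_extents[0] or abs(float(d @ v)) > occluder.half_extents[1]:
        return False
    if params is not None:
        return bool(_contains(q, params, yaw, pitch))
    return True


def color_recognizable(
    point_eye_frame,
    color: str,
    params: VisionParams,
    yaw: float = 0.0,
    pitch: float = 0.0,
) -> bool:
    """Is the control close enough to the line of sight to read its colour?

    A colour counts as recognizable when the control lies inside the field
    of view *and* within a central cone about the forward axis whose
    half-angle depends on the colour (chromatic discrimination narrows away
    from the fovea; red/green narrower than yellow/blue).
    """
    p = np.asarray(point_eye_frame, dtype=float).reshape(3)
    if not _contains(p, params, yaw, pitch):
        return False
    half = params.color_half_angles.get(color, params.color_half_angles.get("other", 60.0))
    r = np.linalg.norm(p)
    if r == 0.0:
        return False
    off_axis = math.degrees(math.acos(np.clip(p[2] / r, -1.0, 1.0)))
    return off_axis <= half


@dataclass(frozen=True)
class VisionScores:
    """(P1, P2, P3); ``None`` marks a not-applicable score (empty class)."""

    p1: float | None
    p2: float | None
    p3: float | None


def score_vision(
    layout: CockpitLayout,
    sample: PostureSample | None = None,
    params: VisionParams | None = None,
    sweep: str = "comfort",
) -> VisionScores:
    """Vision leaf scores for a layout.

    ``sweep`` selects the head poses whose views are united into the field
    of view: ``"comfort"`` (default) or ``"maximum"`` use the corresponding
    head-rotation range of the parameters, ``"sample"`` uses the single
    recorded head pose of ``sample``.  Because containment is monotone in
    the effective half-angle, the union over a rotation interval equals the
    view at its positive extreme.
    """
    params = params or VisionParams()
    if sweep == "comfort":
        yaw, pitch = params.yaw_comfort[1], params.pitch_comfort[1]
    elif sweep == "maximum":
        yaw, pitch = params.yaw_limits[1], params.pitch_limits[1]
    elif sweep == "sample":
        if sample is None:
            raise ValueError("sweep='sample' requires a posture sample")
        yaw, pitch = sample.head_yaw, sample.head_pitch
    else:
        raise ValueError(f"unknown sweep mode {sweep!r}")

    if not layout.controls:
        raise ValueError("layout has no controls")

    eye = layout.eye_from_cab
    pts = {c.id: eye.apply(c.position) for c in layout.controls}
    occs = [
        Occluder(
            id=o.id,
            center=eye.apply(o.center),
            normal=eye.rotate(o.normal),
            half_extents=o.half_extents,
        )
        for o in layout.occluders
    ]

    n_total = len(layout.controls)
    n_in_fov = sum(
        bool(fov_contains(pts[c.id], yaw, pitch, params)) for c in layout.controls
    )
    p1 = (n_total - n_in_fov) / n_total

    colored = [c for c in layout.controls if c.color != "none"]
    if colored:
        n_ok = sum(
            color_recognizable(pts[c.id], c.color, params, yaw, pitch) for c in colored
        )
        p2 = (len(colored) - n_ok) / len(colored)
    else:
        p2 = None

    if occs:
        n_occluded = sum(
            any(occlusion_test(pts[c.id], o, params, yaw, pitch) for o in occs)
            for c in layout.controls
        )
        p3 = n_occluded / n_total
    else:
        p3 = 0.0

    return VisionScores(p1=p1, p2=p2, p3=p3)
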