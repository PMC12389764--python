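"""Upper- and lower-limb reach envelopes and the four reach leaf scores.

Upper limb
----------
The comfortable envelope is the image of the shoulder-elbow chain

    x = L1 cos(t1) cos(p1) + L2 cos(t1 + t2) cos(p1 + p2)
    y = L1 sin(t1) + L2 sin(t1 + t2)
    z = L1 cos(t1) sin(p1) + L2 cos(t1 + t2) sin(p1 + p2)

over the comfort joint ranges (shoulder frame: x forward, y up, z lateral).
The maximum envelope adds trunk flexion/lateral bend, which displaces the
shoulder origin by (Lt sin t3, Lt sin p3) and contributes Lt cos t3 cos p3
to z.  Membership of a point is decided by a coarse grid search over the
admissible joint box refined by bounded quasi-Newton minimisation of the
squared endpoint distance, with tolerance ``eps`` (5 mm by default).

Lower limb
----------
The sagittal hip frame has x forward and y downward.  With hip angle ``th``
(from vertical) and the chain parameter ``tk``:

    xf = Lthigh sin(th) - Lshank sin(th + tk)
    yf = Lthigh cos(th) - Lshank cos(th + tk)

``tk`` = 180 deg is the straight leg; knee *flexion* from full extension is
``180 - tk``.  Knee-only (comfortable) reach is an arc of the circle centred
at the knee (radius Lshank); knee-hip (maximum) reach is the region enclosed
by four boundary curves: straight-leg outer arc, maximum-flexion inner
curve, and the two fixed-hip sweeps.

Leaf scores (bad fractions, higher = worse):

* P4 - intensive upper-limb controls outside the comfortable envelope;
* P5 - secondary upper-limb controls outside the maximum envelope;
* P6 - intensive lower-limb controls off the knee-drive arc;
* P7 - secondary lower-limb controls outside the knee-hip region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from shapely.geometry import Point, Polygon

from .core import AnthropometricProfile, CockpitLayout

__all__ = [
    "ArmAngles",
    "TrunkAngles",
    "LegAngles",
    "ReachOptions",
    "ReachScores",
    "COMFORT_ARM_RANGES",
    "PHYSIO_ARM_RANGES",
    "TRUNK_REACH_RANGES",
    "arm_endpoint",
    "trunk_offset",
    "arm_max_endpoint",
    "foot_endpoint",
    "knee_arc_contains",
    "leg_region_boundary",
    "reachable",
    "score_reach",
]

# Signed joint ranges (deg).  theta1 < 0 is shoulder extension, phi1 < 0
# adduction, phi2 < 0 pronation.
COMFORT_ARM_RANGES = {
    "theta1": (-20.0, 120.0),
    "phi1": (-10.0, 90.0),
    "theta2": (30.0, 130.0),
    "phi2": (-60.0, 60.0),
}
PHYSIO_ARM_RANGES = {
    "theta1": (-60.0, 180.0),
    "phi1": (-20.0, 180.0),
    "theta2": (0.0, 150.0),
    "phi2": (-80.0, 90.0),
}
TRUNK_REACH_RANGES = {"theta3": (0.0, 30.0), "phi3": (0.0, 15.0)}

MODES = ("upper_comfort", "upper_max", "lower_knee", "lower_knee_hip")


@dataclass(frozen=True)
class ArmAngles:
    """Shoulder/elbow joint angles (deg)."""

    theta1: float  # shoulder flexion(+) / extension(-)
    phi1: float = 0.0  # shoulder abduction(+) / adduction(-)
    theta2: float = 0.0  # elbow flexion
    phi2: float = 0.0  # forearm supination(+) / pronation(-)


@dataclass(frozen=True)
class TrunkAngles:
    theta3: float = 0.0  # trunk flexion
    phi3: float = 0.0  # trunk lateral bend


@dataclass(frozen=True)
class LegAngles:
    theta_hip: float  # hip angle from vertical
    theta_knee: float  # chain parameter tk (180 deg = straight leg)
    theta_h0: float = 90.0  # fixed hip for knee-only drive


@dataclass(frozen=True)
class ReachOptions:
    """Membership-search settings (lengths in metres, angles in degrees)."""

    eps: float = 0.005  # endpoint tolerance for upper-limb membership
    arc_tol: float = 0.03  # knee-arc thickness (pedal contact patch)
    coarse_step_comfort: float = 10.0
    coarse_step_max: float = 20.0
    n_starts: int = 4
    hip_limits: tuple[float, float] = (0.0, 90.0)
    knee_flexion_max: float = 135.0  # flexion from full extension
    knee_fixed_hip: float = 90.0  # seated thigh roughly horizontal
    boundary_step: float = 2.0


_D = math.pi / 180.0


def _arm_xyz(t1, p1, t2, p2, L1: float, L2: float):
    """Vectorised arm chain (radians in)."""
    ce = np.cos(t1 + t2)
    x = L1 * np.cos(t1) * np.cos(p1) + L2 * ce * np.cos(p1 + p2)
    y = L1 * np.sin(t1) + L2 * np.sin(t1 + t2)
    z = L1 * np.cos(t1) * np.sin(p1) + L2 * ce * np.sin(p1 + p2)
    return x, y, z


def arm_endpoint(angles: ArmAngles, profile: AnthropometricProfile) -> np.ndarray:
    """Hand position in the shoulder frame for given joint angles (deg)."""
    x, y, z = _arm_xyz(
        angles.theta1 * _D,
        angles.phi1 * _D,
        angles.theta2 * _D,
        angles.phi2 * _D,
        profile.upper_arm_len,
        profile.forearm_len,
    )
    return np.array([x, y, z])


def trunk_offset(trunk: TrunkAngles, profile: AnthropometricProfile) -> tuple[float, float]:
    """Forward / lateral shoulder-origin displacement from trunk bending."""
    return (
        profile.trunk_len * math.sin(trunk.theta3 * _D),
        profile.trunk_len * math.sin(trunk.phi3 * _D),
    )


def arm_max_endpoint(
    angles: ArmAngles, trunk: TrunkAngles, profile: AnthropometricProfile
) -> np.ndarray:
    """Hand position of the shoulder-elbow-waist chain (as printed).

    With a neutral trunk this equals :func:`arm_endpoint` plus the trunk
    length contribution ``(0, 0, Lt)``.
    """
    dx, dy = trunk_offset(trunk, profile)
    arm = arm_endpoint(angles, profile)
    zt = profile.trunk_len * math.cos(trunk.theta3 * _D) * math.cos(trunk.phi3 * _D)
    return np.array([dx + arm[0], dy + arm[1], zt + arm[2]])


def foot_endpoint(leg: LegAngles, profile: AnthropometricProfile) -> np.ndarray:
    """Foot position (hip sagittal frame) for hip/knee chain parameters (deg)."""
    th = leg.theta_hip * _D
    tk = leg.theta_knee * _D
    return np.array(
        [
            profile.thigh_len * math.sin(th) - profile.shank_len * math.sin(th + tk),
            profile.thigh_len * math.cos(th) - profile.shank_len * math.cos(th + tk),
        ]
    )


def knee_arc_contains(
    point,
    theta_h0: float,
    profile: AnthropometricProfile,
    tol: float = 0.03,
    knee_range: tuple[float, float] | None = None,
) -> bool:
    """Does the point lie on the knee-drive arc (within ``tol``)?

    The arc is part of the circle centred at the knee
    ``(Lthigh sin th0, Lthigh cos th0)`` with radius ``Lshank``.  When
    ``knee_range`` is given it restricts the arc to chain parameters
    ``tk`` within that interval (deg); ``None`` admits the full circle.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    p = np.asarray(point, dtype=float).reshape(2)
    center = np.array(
        [
            profile.thigh_len * math.sin(theta_h0 * _D),
            profile.thigh_len * math.cos(theta_h0 * _D),
        ]
    )
    d = p - center
    r = float(np.linalg.norm(d))
    if abs(r - profile.shank_len) > tol:
        return False
    if knee_range is None:
        return True
    # foot - center = -Lshank (sin(th0+tk), cos(th0+tk))
    tk = (math.degrees(math.atan2(-d[0], -d[1])) - theta_h0) % 360.0
    lo, hi = knee_range
    return (lo % 360.0) - 1e-9 <= tk <= (hi % 360.0) + 1e-9 if lo % 360.0 <= hi % 360.0 else (
        tk >= lo % 360.0 or tk <= hi % 360.0
    )


def _flexion_to_tk(flexion_deg):
    """Knee flexion from full extension -> Eq-style chain parameter."""
    return 180.0 - np.asarray(flexion_deg, dtype=float)


def leg_region_boundary(
    profile: AnthropometricProfile,
    hip_limits: tuple[float, float] = (0.0, 90.0),
    knee_flexion_max: float = 135.0,
    step: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed boundary polyline of the knee-hip reach region.

    Four concatenated curves: straight-leg outer arc (flexion 0), the
    maximum-flexion inner curve, and the fixed-hip sweeps at both hip
    limits.  Returns ``(vertices, params)`` where ``params[i]`` is the
    generating ``(theta_hip, tk)`` pair (deg) of ``vertices[i]``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    h_lo, h_hi = hip_limits
    if not h_lo < h_hi:
        raise ValueError("degenerate hip limits: need theta_h_min < theta_h_max")
    if not knee_flexion_max > 0:
        raise ValueError("knee_flexion_max must be positive")

    def sweep(lo, hi):
        n = max(2, int(math.ceil((hi - lo) / step)) + 1)
        return np.linspace(lo, hi, n)

    hs = sweep(h_lo, h_hi)
    ks = sweep(0.0, knee_flexion_max)  # flexion from straight

    segments = [
        (hs, np.full_like(hs, 0.0)),  # outer: straight leg
        (np.full_like(ks, h_hi), ks),  # right: hip at max, flexing
        (hs[::-1], np.full_like(hs, knee_flexion_max)),  # inner, reversed
        (np.full_like(ks, h_lo), ks[::-1]),  # left: hip at min, extending
    ]
    params = []
    for h_arr, k_arr in segments:
        params.extend(zip(h_arr, _flexion_to_tk(k_arr)))
    params = np.array(params)
    verts = np.array(
        [foot_endpoint(LegAngles(h, tk), profile) for h, tk in params]
    )
    return verts, params


def _region_polygon(profile: AnthropometricProfile, opts: ReachOptions) -> Polygon:
    verts, _ = leg_region_boundary(
        profile, opts.hip_limits, opts.knee_flexion_max, opts.boundary_step
    )
    return Polygon(verts).buffer(0)  # buffer(0) heals self-touching corners


def _angle_grid(ranges: list[tuple[float, float]], step: float) -> np.ndarray:
    axes = []
    for lo, hi in ranges:
        n = max(2, int(round((hi - lo) / step)) + 1)
        axes.append(np.linspace(lo, hi, n) * _D)
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _min_distance_upper(
    point: np.ndarray,
    profile: AnthropometricProfile,
    mode: str,
    opts: ReachOptions,
) -> float:
    """Approximate min distance from ``point`` to the envelope surface.

    ``upper_max`` membership is queried in the shoulder frame: the chain
    endpoint is compared after removing the neutral trunk rise (0, 0, Lt),
    which makes the comfortable set a subset of the maximum set.
    """
    L1, L2, Lt = profile.upper_arm_len, profile.forearm_len, profile.trunk_len

    if mode == "upper_comfort":
        ranges = [COMFORT_ARM_RANGES[k] for k in ("theta1", "phi1", "theta2", "phi2")]
        step = opts.coarse_step_comfort

        def endpoint(a):
            x, y, z = _arm_xyz(a[..., 0], a[..., 1], a[..., 2], a[..., 3], L1, L2)
            return np.stack([x, y, z], axis=-1)

    else:  # upper_max
        ranges = [PHYSIO_ARM_RANGES[k] for k in ("theta1", "phi1", "theta2", "phi2")]
        ranges += [TRUNK_REACH_RANGES["theta3"], TRUNK_REACH_RANGES["phi3"]]
        step = opts.coarse_step_max

        def endpoint(a):
            x, y, z = _arm_xyz(a[..., 0], a[..., 1], a[..., 2], a[..., 3], L1, L2)
            t3, p3 = a[..., 4], a[..., 5]
            x = x + Lt * np.sin(t3)
            y = y + Lt * np.sin(p3)
            z = z + Lt * (np.cos(t3) * np.cos(p3) - 1.0)
            return np.stack([x, y, z], axis=-1)

    grid = _angle_grid(ranges, step)
    d = np.linalg.norm(endpoint(grid) - point, axis=1)
    best = np.argsort(d)[: opts.n_starts]
    best_dist = float(d[best[0]])
    if best_dist <= opts.eps:
        return best_dist

    bounds = [(lo * _D, hi * _D) for lo, hi in ranges]

    # squared distance is smooth everywhere (the norm is not at 0), which
    # lets the bounded quasi-Newton refinement converge reliably
    def objective(a):
        return float(np.sum((endpoint(np.asarray(a)) - point) ** 2))

    for idx in best:
        res = minimize(objective, grid[idx], method="L-BFGS-B", bounds=bounds)
        best_dist = min(best_dist, math.sqrt(float(res.fun)))
        if best_dist <= opts.eps:
            break
    return best_dist


def reachable(
    point,
    profile: AnthropometricProfile,
    mode: str,
    options: ReachOptions | None = None,
) -> bool:
    """Can some admissible joint combination place the limb at ``point``?

    ``point`` is in the mode's local frame: shoulder frame (3-vector) for
    the upper modes, hip sagittal frame (2-vector) for the lower modes.
    """
    opts = options or ReachOptions()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")

    if mode in ("upper_comfort", "upper_max"):
        p = np.asarray(point, dtype=float).reshape(3)
        L1, L2, Lt = profile.upper_arm_len, profile.forearm_len, profile.trunk_len
        outer = (L1 + L2) if mode == "upper_comfort" else (Lt + L1 + L2)
        if np.linalg.norm(p) > outer + opts.eps:
            return False
        return _min_distance_upper(p, profile, mode, opts) <= opts.eps

    p2 = np.asarray(point, dtype=float).reshape(-1)[:2]
    if mode == "lower_knee":
        tk_range = (
            float(_flexion_to_tk(opts.knee_flexion_max)),
            180.0,
        )
        return knee_arc_contains(
            p2, opts.knee_fixed_hip, profile, tol=opts.arc_tol, knee_range=tk_range
        )
    poly = _region_polygon(profile, opts)
    return bool(poly.buffer(opts.eps).covers(Point(p2)))


@dataclass(frozen=True)
class ReachScores:
    """(P4, P5, P6, P7); ``None`` marks an empty control class."""

    p4: float | None
    p5: float | None
    p6: float | None
    p7: float | None


def score_reach(
    layout: CockpitLayout,
    profile: AnthropometricProfile,
    options: ReachOptions | None = None,
) -> ReachScores:
    """Reach leaf scores: fraction of each control class outside its envelope.

    Upper-limb controls are mapped through ``shoulder_from_cab``; lower-limb
    controls through ``hip_from_cab`` and projected onto the sagittal plane.
    Controls operated >= 4 times/min are intensive (single-joint comfortable
    envelope); the rest are secondary (two-joint maximum envelope).
    """
    opts = options or ReachOptions()
    region_poly: Polygon | None = None

    def frac_out(controls, mode) -> float | None:
        nonlocal region_poly
        if not controls:
            return None
        n_out = 0
        for c in controls:
            if c.limb == "upper":
                p = layout.shoulder_from_cab.apply(c.position)
                ok = reachable(p, profile, mode, opts)
            else:
                p = layout.hip_from_cab.apply(c.position)[:2]
                if mode == "lower_knee_hip":
                    if region_poly is None:
                        region_poly = _region_polygon(profile, opts)
                    ok = bool(region_poly.buffer(opts.eps).covers(Point(p)))
                else:
                    ok = reachable(p, profile, mode, opts)
            n_out += not ok
        return n_out / len(controls)

    upper = [c for c in layout.controls if c.limb == "upper"]
    lower = [c for c in layout.controls if c.limb == "lower"]
    return ReachScores(
        p4=frac_out([c for c in upper if c.intensive], "upper_comfort"),
        p5=frac_out([c for c in upper if not c.intensive], "upper_max"),
        p6=frac_out([c for c in lower if c.intensive], "lower_knee"),
        p7=frac_out([c for c in lower if not c.intensive], "lower_knee_hip"),
    )
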