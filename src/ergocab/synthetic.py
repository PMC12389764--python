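"""Seeded synthetic cockpits and posture cohorts with known ground truth.

Everything the evaluation pipeline consumes can be generated here, so the
full method is testable without any capture hardware or CAD data:

* :func:`generate_layout` places controls by rejection sampling against
  the package's own geometric predicates, so each control's intended
  class membership (visible / colour-recognizable / occluded / reachable)
  is recorded and the leaf scores are checkable by exact counting;
* :func:`generate_cohort` jitters named task templates (driving, parking,
  emergency braking) with truncated per-joint Gaussian noise over a mix of
  anthropometric percentiles, emulating a 30-participant study;
* :func:`paperlike_fixture` builds a defective/clean layout pair - the
  defective one plants the classic faults (an out-of-reach emergency stop,
  an occluded indicator, pedals off the reach envelopes) - plus a shared
  cohort, for end-to-end comparisons.

Identical seeds give identical outputs everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    PHYSIO_LIMITS,
    AnthropometricProfile,
    CockpitLayout,
    ControlPoint,
    Occluder,
    PostureSample,
    default_profile,
    standard_frames,
)
from .pipeline import Participant
from .reach import (
    COMFORT_ARM_RANGES,
    ArmAngles,
    ReachOptions,
    arm_endpoint,
    reachable,
)
from .vision import VisionParams, color_recognizable, fov_contains, occlusion_test

__all__ = [
    "GenerationError",
    "CohortSpec",
    "LayoutSpec",
    "GroundTruth",
    "TASK_TEMPLATES",
    "NEUTRAL_TEMPLATE",
    "generate_layout",
    "generate_cohort",
    "paperlike_fixture",
]

_EYE_POS = (0.05, 0.0, 0.68)
_SHOULDER_POS = (0.0, -0.20, 0.52)
_HIP_POS = (0.0, 0.0, 0.0)


class GenerationError(RuntimeError):
    """A placement request could not be satisfied in bounded attempts."""


# ---------------------------------------------------------------------------
# posture templates and cohorts
# ---------------------------------------------------------------------------

def _template(**kw) -> PostureSample:
    return PostureSample(participant_id="template", **kw)


#: nominal postures of the three evaluated work tasks
TASK_TEMPLATES: dict[str, PostureSample] = {
    "driving": _template(
        task_label="driving",
        shoulder_flexion=35.0,
        shoulder_abduction=10.0,
        elbow_flexion=95.0,
        forearm_rotation=10.0,
        trunk_flexion=8.0,
        trunk_lateral=0.0,
        hip_angle=90.0,
        knee_angle=100.0,
        head_pitch=-5.0,
        neck_flexion=5.0,
        wrist_flexion=5.0,
        repeat_rate=6.0,
    ),
    "parking": _template(
        task_label="parking",
        shoulder_flexion=50.0,
        shoulder_abduction=25.0,
        elbow_flexion=70.0,
        forearm_rotation=-20.0,
        trunk_flexion=18.0,
        trunk_lateral=5.0,
        hip_angle=90.0,
        knee_angle=95.0,
        head_yaw=25.0,
        neck_flexion=12.0,
        wrist_flexion=10.0,
        static_or_repetitive=True,
    ),
    "emergency_braking": _template(
        task_label="emergency_braking",
        shoulder_flexion=70.0,
        shoulder_abduction=5.0,
        elbow_flexion=40.0,
        forearm_rotation=0.0,
        trunk_flexion=25.0,
        trunk_lateral=0.0,
        hip_angle=75.0,
        knee_angle=60.0,
        neck_flexion=8.0,
        wrist_flexion=18.0,
        repeat_rate=1.0,
    ),
}

#: fully relaxed seated posture (every scorer at its neutral band)
NEUTRAL_TEMPLATE: PostureSample = _template(task_label="neutral")

# jitter clipping bounds: printed physiological limits plus pragmatic
# bounds for the joints without a printed table
_CLIP_LIMITS: dict[str, tuple[float, float]] = PHYSIO_LIMITS | {
    "hip_angle": (0.0, 120.0),
    "knee_angle": (0.0, 150.0),
    "neck_flexion": (-60.0, 60.0),
    "wrist_flexion": (-90.0, 90.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort description (defaults emulate a 30-operator experiment
    over three work tasks with a P5/P50/P95 male anthropometry mix)."""

    n_participants: int = 30
    tasks: tuple[str, ...] = ("driving", "parking", "emergency_braking")
    templates: dict[str, PostureSample] = field(
        default_factory=lambda: dict(TASK_TEMPLATES)
    )
    angle_noise_sd: float = 3.0  # deg, per joint
    percentile_mix: dict[str, float] = field(
        default_factory=lambda: {"P5": 0.2, "P50": 0.6, "P95": 0.2}
    )
    length_jitter_sd: float = 0.01  # relative segment-length scatter
    landmark_jitter_sd: float = 0.005  # m, eye/shoulder/hip placement scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be >= 0")


def _jitter_sample(
    template: PostureSample, rng: np.random.Generator, sd: float
) -> dict[str, float]:
    out = {}
    for joint, (lo, hi) in _CLIP_LIMITS.items():
        v = getattr(template, joint) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        out[joint] = float(min(hi, max(lo, v)))
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Participant], list[PostureSample]]:
    """Participants and per-task jittered posture samples.

    Noise is an independent truncated Gaussian per joint (truncation at the
    physiological limits, never silent clamping of the *template* itself -
    templates must be valid).  Anthropometry mixes the configured
    percentiles with a mild relative length scatter; landmark offsets model
    seat/stature placement differences.
    """
    rng = np.random.default_rng(spec.seed)
    for name in spec.tasks:
        if name not in spec.templates:
            raise ValueError(f"no template for task {name!r}")

    labels = sorted(spec.percentile_mix)
    probs = np.array([spec.percentile_mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()

    participants: list[Participant] = []
    samples: list[PostureSample] = []
    for i in range(spec.n_participants):
        pid = f"S{i + 1:02d}"
        label = str(rng.choice(labels, p=probs))
        profile = default_profile(label)
        if spec.length_jitter_sd > 0:
            profile = profile.scaled(1.0 + rng.normal(0.0, spec.length_jitter_sd))
        offset = tuple(rng.normal(0.0, spec.landmark_jitter_sd, 3)) if (
            spec.landmark_jitter_sd > 0
        ) else (0.0, 0.0, 0.0)
        participants.append(Participant(pid, profile, offset))
        for task in spec.tasks:
            tpl = spec.templates[task]
            angles = _jitter_sample(tpl, rng, spec.angle_noise_sd)
            samples.append(
                replace(tpl, participant_id=pid, task_label=task, **angles)
            )
    return participants, samples


# ---------------------------------------------------------------------------
# layout generation with ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutSpec:
    """Requested control counts per class and planted defect counts.

    The good/defective split is by construction: every generated control's
    intended membership is verified with the package's own predicates
    (rejection sampling) and recorded in the ground truth.
    ``robust_percentiles`` lists the anthropometric profiles whose reach
    envelopes every *good* control must satisfy simultaneously.
    """

    n_intensive_upper: int = 3
    n_secondary_upper: int = 4
    n_intensive_lower: int = 2
    n_secondary_lower: int = 1
    colors: tuple[str, ...] = ("red", "green", "blue", "yellow")
    n_unreachable_intensive_upper: int = 0
    n_unreachable_secondary_upper: int = 0
    n_lower_off_envelope: int = 0  # split over intensive (arc) / secondary (region)
    n_occluded: int = 0
    n_invisible: int = 0
    n_color_unrecognizable: int = 0
    n_marginal_reach_upper: int = 0  # on the P50 comfort boundary
    n_marginal_visible: int = 0  # on the swept-FOV lower edge
    robust_percentiles: tuple[str, ...] = ("P50",)
    require_visible: bool = True
    max_attempts: int = 400


@dataclass
class GroundTruth:
    """Per-control intended memberships, recorded at generation time."""

    records: dict[str, dict] = field(default_factory=dict)

    def expected_leaf_scores(self) -> dict[str, float | None]:
        """Leaf scores P1-P7 implied by the recorded memberships (Eq-style
        bad-fraction counting)."""
        recs = list(self.records.values())

        def frac(pop, bad_key, good=False):
            if not pop:
                return None
            n_bad = sum((not r[bad_key]) if good else r[bad_key] for r in pop)
            return n_bad / len(pop)

        upper = [r for r in recs if r["limb"] == "upper"]
        lower = [r for r in recs if r["limb"] == "lower"]
        colored = [r for r in recs if r["color"] != "none"]
        return {
            "P1": frac(recs, "visible", good=True),
            "P2": frac(colored, "color_ok", good=True),
            "P3": frac(recs, "occluded"),
            "P4": frac([r for r in upper if r["intensive"]], "reachable", good=True),
            "P5": frac([r for r in upper if not r["intensive"]], "reachable", good=True),
            "P6": frac([r for r in lower if r["intensive"]], "reachable", good=True),
            "P7": frac([r for r in lower if not r["intensive"]], "reachable", good=True),
        }


def _sample_interior(rng: np.random.Generator, ranges: dict, shrink: float = 0.25):
    vals = []
    for lo, hi in ranges.values():
        span = hi - lo
        vals.append(rng.uniform(lo + shrink * span, hi - shrink * span))
    return vals


class _Placer:
    """Rejection-sampling placement machinery for one layout build."""

    def __init__(self, spec: LayoutSpec, seed: int):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.frames = standard_frames(_EYE_POS, _SHOULDER_POS, _HIP_POS)
        self.vision = VisionParams()
        self.reach_opts = ReachOptions()
        self.profiles = [default_profile(p) for p in spec.robust_percentiles]
        self.p50 = default_profile("P50")
        self.yaw, self.pitch = self.vision.yaw_comfort[1], self.vision.pitch_comfort[1]

    # -- geometric predicates in cab coordinates --------------------------
    def eye_frame(self, cab_pos):
        return self.frames["eye_from_cab"].apply(cab_pos)

    def visible(self, cab_pos, margin_deg: float = 3.0) -> bool:
        p = self.eye_frame(cab_pos)
        shrunk = replace(
            self.vision,
            near=self.vision.near + 0.03,
            far=self.vision.far - 0.05,
            horizontal_fov=self.vision.horizontal_fov - 2 * margin_deg,
            vertical_fov_up=self.vision.vertical_fov_up - 2 * margin_deg,
            vertical_fov_down=self.vision.vertical_fov_down - 2 * margin_deg,
        )
        return bool(fov_contains(p, self.yaw, self.pitch, shrunk))

    def visible_nominal(self, cab_pos) -> bool:
        return bool(fov_contains(self.eye_frame(cab_pos), self.yaw, self.pitch, self.vision))

    def color_ok(self, cab_pos, color) -> bool:
        return color_recognizable(self.eye_frame(cab_pos), color, self.vision, self.yaw, self.pitch)

    def upper_reach(self, cab_pos, mode, profiles=None) -> bool:
        pt = self.frames["shoulder_from_cab"].apply(cab_pos)
        return all(
            reachable(pt, pr, mode, self.reach_opts)
            for pr in (profiles or self.profiles)
        )

    def lower_reach(self, cab_pos, mode, profiles=None) -> bool:
        pt = self.frames["hip_from_cab"].apply(cab_pos)[:2]
        return all(
            reachable(pt, pr, mode, self.reach_opts)
            for pr in (profiles or self.profiles)
        )

    # -- placement samplers ------------------------------------------------
    def place(self, predicate, sampler, what: str):
        for _ in range(self.spec.max_attempts):
            pos = sampler()
            if predicate(pos):
                return np.asarray(pos)
        raise GenerationError(f"could not place a control satisfying: {what}")

    def good_upper(self, mode: str, color: str = "none"):
        """Reachable (all robust profiles), visible, colour-recognizable."""
        shoulder_inv = self.frames["shoulder_from_cab"].inverse()

        def sampler():
            if mode == "upper_comfort":
                # forward-biased comfort postures (low shoulder flexion,
                # part-bent elbow) so the hand lands ahead of the eye plane
                angles = [
                    self.rng.uniform(0.0, 40.0),
                    self.rng.uniform(-5.0, 45.0),
                    self.rng.uniform(30.0, 90.0),
                    self.rng.uniform(-40.0, 40.0),
                ]
                p_sh = arm_endpoint(ArmAngles(*angles), self.p50)
            else:
                # forward hemisphere shell inside the two-joint envelope
                r = self.rng.uniform(0.45, 0.75)
                az = self.rng.uniform(-0.6, 0.6)  # rad, about forward axis
                el = self.rng.uniform(-0.2, 0.5)
                p_sh = r * np.array(
                    [math.cos(el) * math.cos(az), math.sin(el), math.cos(el) * math.sin(az)]
                )
            return shoulder_inv.apply(p_sh)

        def predicate(pos):
            if not self.upper_reach(pos, mode):
                return False
            if self.spec.require_visible and not self.visible(pos):
                return False
            if color != "none" and not self.color_ok(pos, color):
                return False
            if color == "none" and self.spec.require_visible:
                return True
            return True

        return self.place(predicate, sampler, f"good upper ({mode}, {color})")

    def good_lower(self, mode: str):
        hip_inv = self.frames["hip_from_cab"].inverse()
        profiles = self.profiles

        multi = len(profiles) > 1

        def foot_p50(theta_h: float, flexion: float) -> np.ndarray:
            from .reach import LegAngles, foot_endpoint

            return foot_endpoint(LegAngles(theta_h, 180.0 - flexion), self.p50)

        def sampler():
            if mode == "lower_knee":
                # on the P50 knee arc: shallow flexion keeps pedals forward
                # and visible; the deep-flexion window is where the P5/P50/
                # P95 arcs nearly intersect (percentile-robust placements)
                flex = (
                    self.rng.uniform(118.0, 130.0) if multi else self.rng.uniform(8.0, 18.0)
                )
                p2 = foot_p50(self.reach_opts.knee_fixed_hip, flex)
            elif multi:
                # deep mid-flexion points sit inside every percentile's
                # knee-hip region simultaneously
                p2 = foot_p50(self.rng.uniform(50.0, 70.0), self.rng.uniform(75.0, 105.0))
            else:
                # shallow-flexion forward points near the hip limit are both
                # inside the region and high enough to be seen
                p2 = foot_p50(self.rng.uniform(82.0, 89.0), self.rng.uniform(10.0, 22.0))
            return hip_inv.apply([p2[0], p2[1], 0.0])

        def predicate(pos):
            if not self.lower_reach(pos, mode):
                return False
            if self.spec.require_visible and len(profiles) == 1:
                return self.visible(pos)
            return True

        return self.place(predicate, sampler, f"good lower ({mode})")

    def bad_upper(self, mode: str):
        """Beyond the envelope for every robust profile, still in the cab."""
        shoulder_inv = self.frames["shoulder_from_cab"].inverse()

        def sampler():
            r = self.rng.uniform(1.25, 1.6)
            az = self.rng.uniform(-0.8, 0.8)
            el = self.rng.uniform(-0.1, 0.4)
            p_sh = r * np.array(
                [math.cos(el) * math.cos(az), math.sin(el), math.cos(el) * math.sin(az)]
            )
            return shoulder_inv.apply(p_sh)

        def predicate(pos):
            if any(self.upper_reach(pos, mode, [pr]) for pr in self.profiles):
                return False
            return self.visible(pos) if self.spec.require_visible else True

        return self.place(predicate, sampler, f"unreachable upper ({mode})")

    def bad_lower(self, mode: str):
        hip_inv = self.frames["hip_from_cab"].inverse()

        def sampler():
            direction = math.radians(self.rng.uniform(55.0, 80.0))
            r = self.rng.uniform(0.95, 1.15)
            p2 = r * np.array([math.sin(direction), math.cos(direction)])
            return hip_inv.apply([p2[0], p2[1], 0.0])

        def predicate(pos):
            return not any(self.lower_reach(pos, mode, [pr]) for pr in self.profiles)

        return self.place(predicate, sampler, f"off-envelope lower ({mode})")

    def marginal_comfort_point(self):
        """Exactly on the P50 comfortable-envelope boundary (elbow at its
        comfort-flexion limit): membership flips with limb-length scatter."""
        shoulder_inv = self.frames["shoulder_from_cab"].inverse()

        def sampler():
            angles = ArmAngles(
                self.rng.uniform(5.0, 25.0),
                self.rng.uniform(10.0, 40.0),
                COMFORT_ARM_RANGES["theta2"][0],
                self.rng.uniform(-10.0, 10.0),
            )
            return shoulder_inv.apply(arm_endpoint(angles, self.p50))

        def predicate(pos):
            return self.visible(pos) if self.spec.require_visible else True

        return self.place(predicate, sampler, "marginal comfort-boundary control")

    def marginal_visible_point(self):
        """On the head-swept lower field-of-view edge: visibility flips with
        eye-placement scatter."""
        z = self.rng.uniform(0.7, 1.0)
        down = z * math.tan(
            math.radians((self.vision.vertical_fov_down + self.pitch) / 2.0)
        )
        return np.asarray(_EYE_POS) + np.array(
            [z, self.rng.uniform(-0.2, 0.2), -down]
        )

    def invisible_point(self):
        """Behind the near plane: never inside any head-swept view."""

        def sampler():
            return np.array(
                [
                    self.rng.uniform(-0.45, -0.15),
                    self.rng.uniform(-0.4, 0.4),
                    self.rng.uniform(0.2, 0.9),
                ]
            )

        return self.place(
            lambda pos: not self.visible_nominal(pos), sampler, "invisible control"
        )

    def unrecognizable_color_point(self, color: str):
        """In the field of view but outside the colour's central cone."""

        def sampler():
            # far right/left of the panel, still frontal
            side = self.rng.choice([-1.0, 1.0])
            return np.array(
                [
                    self.rng.uniform(0.35, 0.6),
                    side * self.rng.uniform(0.55, 0.85),
                    self.rng.uniform(0.5, 0.9),
                ]
            )

        def predicate(pos):
            return self.visible_nominal(pos) and not self.color_ok(pos, color)

        return self.place(predicate, sampler, f"unrecognizable {color} control")

    def occluder_for(self, cab_pos, other_positions, ident: str) -> Occluder:
        """A small plate halfway along the sight line to one control."""
        eye = np.asarray(_EYE_POS)
        # the intersection point must itself be in the field of view, so the
        # plate sits far enough along the ray to clear the near plane
        for frac_t in (0.6, 0.7, 0.75, 0.8, 0.5, 0.85):
            center = eye + frac_t * (np.asarray(cab_pos) - eye)
            normal = np.asarray(cab_pos) - eye
            normal = normal / np.linalg.norm(normal)
            occ = Occluder(
                id=ident, center=center, normal=normal, half_extents=(0.06, 0.06)
            )
            occ_eye = Occluder(
                id=ident,
                center=self.frames["eye_from_cab"].apply(center),
                normal=self.frames["eye_from_cab"].rotate(normal),
                half_extents=occ.half_extents,
            )
            hits_target = occlusion_test(
                self.eye_frame(cab_pos), occ_eye, self.vision, self.yaw, self.pitch
            )
            hits_other = any(
                occlusion_test(self.eye_frame(p), occ_eye, self.vision, self.yaw, self.pitch)
                for p in other_positions
            )
            if hits_target and not hits_other:
                return occ
        raise GenerationError("could not place an occluder hitting only its target")


def generate_layout(
    spec: LayoutSpec, seed: int = 0
) -> tuple[CockpitLayout, GroundTruth]:
    """Build a cockpit layout matching the requested class counts.

    Deterministic for a given seed.  Every control's intended memberships
    (visible, colour-recognizable, occluded, reachable for its class, at
    the nominal P50 geometry) are returned as ground truth.
    """
    placer = _Placer(spec, seed)
    truth = GroundTruth()
    controls: list[ControlPoint] = []
    occluders: list[Occluder] = []

    def add(ident, pos, limb, ops, color="none", **flags):
        controls.append(
            ControlPoint(
                id=ident,
                position=pos,
                limb=limb,
                ops_per_minute=ops,
                color=color,
                safety_critical=flags.pop("safety_critical", False),
            )
        )
        truth.records[ident] = {
            "limb": limb,
            "intensive": ops >= 4,
            "color": color,
            "visible": flags.pop("visible"),
            "color_ok": flags.pop("color_ok"),
            "occluded": flags.pop("occluded", False),
            "reachable": flags.pop("reachable"),
        }

    n_bad_iu = spec.n_unreachable_intensive_upper
    if n_bad_iu > spec.n_intensive_upper:
        raise GenerationError("more unreachable intensive controls than intensive controls")
    for i in range(spec.n_intensive_upper - n_bad_iu):
        pos = placer.good_upper("upper_comfort")
        add(
            f"iu{i}", pos, "upper", 6.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=True,
        )
    for i in range(n_bad_iu):
        pos = placer.bad_upper("upper_comfort")
        add(
            f"iu_bad{i}", pos, "upper", 6.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=False,
        )

    n_bad_su = spec.n_unreachable_secondary_upper
    n_inv = spec.n_invisible
    n_unrec = spec.n_color_unrecognizable
    n_good_su = spec.n_secondary_upper - n_bad_su - n_inv - n_unrec
    if n_good_su < 0:
        raise GenerationError("secondary-upper defect counts exceed the class size")
    color_cycle = list(spec.colors)

    def next_color():
        return color_cycle.pop(0) if color_cycle else "none"

    for i in range(n_good_su):
        color = next_color()
        pos = placer.good_upper("upper_max", color=color)
        add(
            f"su{i}", pos, "upper", 1.0, color=color,
            visible=placer.visible_nominal(pos),
            color_ok=True,
            reachable=True,
        )
    for i in range(n_unrec):
        color = next_color()
        color = color if color != "none" else "red"
        pos = placer.unrecognizable_color_point(color)
        add(
            f"su_offaxis{i}", pos, "upper", 1.0, color=color,
            visible=True, color_ok=False,
            reachable=placer.upper_reach(pos, "upper_max", [placer.p50]),
        )
    for i in range(n_bad_su):
        color = next_color()
        pos = placer.bad_upper("upper_max")
        add(
            f"su_far{i}", pos, "upper", 1.0, color=color,
            visible=placer.visible_nominal(pos),
            color_ok=placer.color_ok(pos, color) if color != "none" else True,
            reachable=False, safety_critical=(i == 0),
        )
    for i in range(spec.n_marginal_reach_upper):
        pos = placer.marginal_comfort_point()
        add(
            f"mu{i}", pos, "upper", 6.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=True,
        )
    for i in range(spec.n_marginal_visible):
        pos = placer.marginal_visible_point()
        add(
            f"mv{i}", pos, "upper", 1.0,
            visible=placer.visible_nominal(pos), color_ok=True,
            reachable=placer.upper_reach(pos, "upper_max", [placer.p50]),
        )
    for i in range(n_inv):
        pos = placer.invisible_point()
        add(
            f"su_hidden{i}", pos, "upper", 1.0,
            visible=False, color_ok=True,
            reachable=placer.upper_reach(pos, "upper_max", [placer.p50]),
        )

    n_bad_lower = spec.n_lower_off_envelope
    bad_il = min(spec.n_intensive_lower, (n_bad_lower + 1) // 2)
    bad_sl = min(n_bad_lower - bad_il, spec.n_secondary_lower)
    for i in range(spec.n_intensive_lower - bad_il):
        pos = placer.good_lower("lower_knee")
        add(
            f"il{i}", pos, "lower", 8.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=True,
        )
    for i in range(bad_il):
        pos = placer.bad_lower("lower_knee")
        add(
            f"il_off{i}", pos, "lower", 8.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=False,
        )
    for i in range(spec.n_secondary_lower - bad_sl):
        pos = placer.good_lower("lower_knee_hip")
        add(
            f"sl{i}", pos, "lower", 1.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=True,
        )
    for i in range(bad_sl):
        pos = placer.bad_lower("lower_knee_hip")
        add(
            f"sl_off{i}", pos, "lower", 1.0,
            visible=placer.visible_nominal(pos), color_ok=True, reachable=False,
        )

    # occluders cover the first n_occluded good visible upper controls
    if spec.n_occluded:
        candidates = [
            c for c in controls
            if truth.records[c.id]["visible"] and c.limb == "upper"
        ]
        # farther targets leave more room for the plate ahead of the near plane
        candidates.sort(
            key=lambda c: -float(placer.eye_frame(c.position)[2])
        )
        if len(candidates) < spec.n_occluded:
            raise GenerationError("not enough visible controls to occlude")
        others = [c.position for c in controls]
        for i, target in enumerate(candidates[: spec.n_occluded]):
            other_positions = [p for p in others if p is not target.position]
            occ = placer.occluder_for(target.position, other_positions, f"occ{i}")
            occluders.append(occ)
            truth.records[target.id]["occluded"] = True

    layout = CockpitLayout(
        controls=controls, occluders=occluders, **placer.frames
    )
    return layout, truth


# ---------------------------------------------------------------------------
# the qualitative worse/better fixture
# ---------------------------------------------------------------------------

def paperlike_fixture(
    seed: int = 97,
) -> tuple[
    tuple[CockpitLayout, GroundTruth],
    tuple[CockpitLayout, GroundTruth],
    tuple[list[Participant], list[PostureSample]],
]:
    """A defective layout, a cleaned-up layout, and a shared cohort.

    The defective layout plants classic faults: an emergency stop beyond
    everyone's reach, an occluded indicator, a hidden control, an
    off-colour-zone button, and pedals off both lower-limb envelopes.  The
    clean layout keeps all lower-limb controls inside both envelopes for
    every percentile in the mix.  Qualitative by construction: the
    comprehensive score of the defective layout exceeds the clean one's.
    """
    percentiles = ("P5", "P50", "P95")
    clean_spec = LayoutSpec(
        n_intensive_upper=3,
        n_secondary_upper=4,
        n_intensive_lower=2,
        n_secondary_lower=2,
        robust_percentiles=percentiles,
        require_visible=True,
        n_marginal_reach_upper=1,
        n_marginal_visible=1,
    )
    bad_spec = replace(
        clean_spec,
        n_unreachable_intensive_upper=1,
        n_unreachable_secondary_upper=2,
        n_lower_off_envelope=2,
        n_occluded=1,
        n_invisible=1,
        n_color_unrecognizable=1,
        n_secondary_upper=6,
    )
    clean = generate_layout(clean_spec, seed)
    bad = generate_layout(bad_spec, seed + 1)
    cohort = generate_cohort(CohortSpec(seed=seed + 2))
    return bad, clean, cohort
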