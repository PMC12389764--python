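"""Posture-load scorers: additive RULA variant, L5/S1 lower-back forces,
OWAS posture coding, and Krist-style comfort assessment, plus the mapping
of each scorer onto body regions.

These four scorers produce the raw values behind leaf scores P8 (RULA),
P9 (LBA compression), P10 (comfort assessment), and P11 (OWAS level).
The RULA here is the *additive* variant: part scores are summed
(``PT = PA + PB + dw``, ``P_RULA = PT + de``) rather than combined through
the canonical lookup tables, so its attainable range differs from classic
RULA - :func:`rula_range` enumerates it exhaustively for normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from .core import GRAVITY, AnthropometricProfile, PostureSample

__all__ = [
    "RulaParts",
    "RulaScore",
    "OwasCode",
    "LbaResult",
    "CaScore",
    "RegionScores",
    "REGIONS",
    "rula_part_scores",
    "rula_total",
    "rula_range",
    "rula_score_sample",
    "owas_code_from_sample",
    "owas_level",
    "owas_region_level",
    "lba_forces",
    "ca_grade",
    "ca_posture_score",
    "ca_score_sample",
    "ca_weights_for",
    "region_scores",
    "CA_TABLE",
    "OWAS_RISK_TABLE",
]

REGIONS = ("upper", "lower", "trunk", "whole")


# ---------------------------------------------------------------------------
# RULA (additive variant)
# ---------------------------------------------------------------------------

def _upper_arm_points(angle: float) -> int:
    """Upper-arm band points: 1 natural droop, 2 <=20 deg, 3 20-45 deg,
    4 >45 deg or hyperextension (negative angle)."""
    if angle < 0:
        return 4
    if angle == 0:
        return 1
    if angle <= 20:
        return 2
    if angle <= 45:
        return 3
    return 4


def _forearm_points(angle: float) -> int:
    """Forearm band points: 1 for 60-100 deg with the upper arm, else 2."""
    return 1 if 60 <= angle <= 100 else 2


def _wrist_points(flexion: float) -> int:
    return 2 if abs(flexion) >= 15 else 1


def _neck_points(flexion: float, lateral_or_twist: bool = False) -> int:
    return 2 if flexion > 10 or lateral_or_twist else 1


def _trunk_points(flexion: float, lateral_or_twist: bool = False) -> int:
    return 2 if flexion > 10 or lateral_or_twist else 1


_PART_RANGES = {
    "upper_arm": (1, 2, 3, 4),
    "forearm": (1, 2),
    "wrist": (1, 2),
    "neck": (1, 2),
    "trunk": (1, 2),
}

#: body parts entering the posture sum per analysis region
RULA_REGION_PARTS = {
    "upper": ("upper_arm", "forearm", "wrist", "neck"),
    "trunk": ("neck", "trunk"),
    "whole": ("upper_arm", "forearm", "wrist", "neck", "trunk"),
}


@dataclass(frozen=True)
class RulaParts:
    upper_arm: int
    forearm: int
    wrist: int
    neck: int
    trunk: int
    delta_w: int  # wrist-twist addition, 0 or 1

    @property
    def pa(self) -> int:
        """Group A points (arm + wrist base)."""
        return self.upper_arm + self.forearm + self.wrist

    @property
    def pb(self) -> int:
        """Group B points (neck + trunk)."""
        return self.neck + self.trunk


@dataclass(frozen=True)
class RulaScore:
    pa: int
    pb: int
    delta_w: int
    pt: int
    load_score: int
    muscle_score: int
    delta_e: int
    p_rula: int
    risk_level: int


def rula_part_scores(sample: PostureSample) -> RulaParts:
    """Band points for each body part of one posture sample."""
    return RulaParts(
        upper_arm=_upper_arm_points(sample.shoulder_flexion),
        forearm=_forearm_points(sample.elbow_flexion),
        wrist=_wrist_points(sample.wrist_flexion),
        neck=_neck_points(sample.neck_flexion),
        trunk=_trunk_points(sample.trunk_flexion, abs(sample.trunk_lateral) > 10),
        delta_w=1 if sample.wrist_twisted else 0,
    )


def _load_points(load_mass: float) -> int:
    if load_mass <= 0:
        return 0
    if load_mass <= 2:
        return 1
    return 2


def _muscle_points(static_flag: bool, repeat_rate: float) -> int:
    return 1 if static_flag or repeat_rate > 4 else 0


def _delta_e(pt: int, load: int, muscle: int) -> int:
    """Extra points from posture sum, load, and muscle use.

    The printed adjustment rows omit the (low posture sum, no load, muscle
    use) cell; any non-zero load or muscle use takes the adjusted row.
    """
    if pt >= 7:
        return 3
    elevated = load > 0 or muscle > 0
    if pt >= 4:
        return 2 if elevated else 1
    return 1 if elevated else 0


def _risk_level(p_rula: int) -> int:
    if p_rula <= 2:
        return 1
    if p_rula <= 4:
        return 2
    if p_rula <= 6:
        return 3
    return 4


def rula_total(
    parts: RulaParts | tuple[int, int, int],
    load_mass: float = 0.0,
    static_flag: bool = False,
    repeat_rate: float = 0.0,
) -> RulaScore:
    """Total additive RULA score from part scores, load, and muscle use.

    ``parts`` may be a :class:`RulaParts` or a raw ``(PA, PB, dw)`` triple.
    """
    if load_mass < 0:
        raise ValueError("load_mass must be >= 0")
    if isinstance(parts, RulaParts):
        pa, pb, dw = parts.pa, parts.pb, parts.delta_w
    else:
        pa, pb, dw = parts
    pt = pa + pb + dw
    load = _load_points(load_mass)
    muscle = _muscle_points(static_flag, repeat_rate)
    de = _delta_e(pt, load, muscle)
    p_rula = pt + de
    return RulaScore(
        pa=pa,
        pb=pb,
        delta_w=dw,
        pt=pt,
        load_score=load,
        muscle_score=muscle,
        delta_e=de,
        p_rula=p_rula,
        risk_level=_risk_level(p_rula),
    )


@lru_cache(maxsize=None)
def rula_range(region: str = "whole") -> tuple[int, int]:
    """Attainable (min, max) additive RULA total for a region.

    Exhaustively enumerates every band combination (including wrist twist,
    load, and muscle use), which is what the score normalisation needs.
    """
    parts = RULA_REGION_PARTS.get(region)
    if parts is None:
        raise ValueError(f"no RULA variant for region {region!r}")
    include_wrist_twist = "wrist" in parts
    totals = []
    combos = [[]]
    for part in parts:
        combos = [c + [v] for c in combos for v in _PART_RANGES[part]]
    for combo in combos:
        for dw in (0, 1) if include_wrist_twist else (0,):
            pt = sum(combo) + dw
            for load in (0, 1, 2):
                for muscle in (0, 1):
                    totals.append(pt + _delta_e(pt, load, muscle))
    return min(totals), max(totals)


def rula_score_sample(sample: PostureSample, region: str = "whole") -> RulaScore:
    """Additive RULA for a sample restricted to one region's body parts."""
    parts = rula_part_scores(sample)
    included = RULA_REGION_PARTS.get(region)
    if included is None:
        raise ValueError(f"no RULA variant for region {region!r}")
    pa = sum(getattr(parts, p) for p in included if p in ("upper_arm", "forearm", "wrist"))
    pb = sum(getattr(parts, p) for p in included if p in ("neck", "trunk"))
    dw = parts.delta_w if "wrist" in included else 0
    return rula_total(
        (pa, pb, dw),
        load_mass=sample.external_load_mass,
        static_flag=sample.static_or_repetitive,
        repeat_rate=sample.repeat_rate,
    )


# ---------------------------------------------------------------------------
# OWAS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OwasCode:
    back: int  # 1..4
    arms: int  # 1..3
    legs: int  # 1..4
    load: int  # 1..3

    def __post_init__(self) -> None:
        if not (1 <= self.back <= 4 and 1 <= self.arms <= 3 and 1 <= self.legs <= 4 and 1 <= self.load <= 3):
            raise ValueError(f"OWAS code out of range: {self}")


#: printed risk-classification rows; None is an "Any" wildcard, a tuple an
#: alternative set.
OWAS_RISK_TABLE: list[tuple[object, object, object, object, int]] = [
    (1, 1, 1, 1, 1),
    (2, 1, 2, 2, 2),
    (2, 2, 3, 1, 3),
    (3, (2, 3), 4, 3, 4),
    (4, None, None, (2, 3), 4),
]


def _cell_match(cell, value: int) -> bool:
    if cell is None:
        return True
    if isinstance(cell, tuple):
        return value in cell
    return value == cell


def owas_level(code: OwasCode, policy: str = "severity") -> int:
    """Fatigue-risk level (1-4) of a four-digit OWAS code.

    Combinations listed in the classification table return the printed
    level.  The table covers only a handful of the 144 combinations;
    unlisted ones are resolved per ``policy``: ``"severity"`` (default)
    takes the worst single-dimension code, clamped to 4 - which reproduces
    every printed row - while ``"strict"`` raises for unlisted codes.
    """
    for back, arms, legs, load, level in OWAS_RISK_TABLE:
        if (
            _cell_match(back, code.back)
            and _cell_match(arms, code.arms)
            and _cell_match(legs, code.legs)
            and _cell_match(load, code.load)
        ):
            return level
    if policy == "strict":
        raise ValueError(f"unclassified OWAS posture combination {code}")
    if policy != "severity":
        raise ValueError(f"unknown OWAS policy {policy!r}")
    return min(4, max(code.back, code.arms, code.legs, code.load))


def owas_code_from_sample(sample: PostureSample) -> OwasCode:
    """Derive the four OWAS posture codes from sample angles and flags.

    Back: 1 upright or slight flexion (<=10 deg), 2 flexion <=45 deg,
    3 severe flexion >45 deg, 4 twist / lateral bend (>10 deg).
    Arms: 1 hands below shoulder level, 2 above, 3 forward extension.
    Legs: 1 seated, 2 standing with straight legs, 3 leg flexion.
    Load: 1 <=10 kg, 2 10-20 kg, 3 >20 kg.
    """
    if abs(sample.trunk_lateral) > 10:
        back = 4
    elif sample.trunk_flexion > 45:
        back = 3
    elif sample.trunk_flexion > 10:
        back = 2
    else:
        back = 1

    if sample.shoulder_flexion >= 90:
        arms = 2
    elif sample.shoulder_flexion >= 45 and sample.elbow_flexion <= 30:
        arms = 3
    else:
        arms = 1

    if sample.seated:
        legs = 1
    elif sample.knee_angle <= 30:
        legs = 2
    else:
        legs = 3

    m = sample.external_load_mass
    load = 1 if m <= 10 else (2 if m <= 20 else 3)
    return OwasCode(back=back, arms=arms, legs=legs, load=load)


def owas_region_level(sample: PostureSample, region: str, policy: str = "severity") -> int:
    """Region-restricted OWAS level.

    ``whole`` classifies the full four-digit code; the local regions use the
    single matching dimension's code as the level (arms for upper, legs for
    lower, back for trunk), keeping every value on the shared 1-4 scale.
    """
    code = owas_code_from_sample(sample)
    if region == "whole":
        return owas_level(code, policy=policy)
    if region == "upper":
        return min(4, code.arms)
    if region == "lower":
        return min(4, code.legs)
    if region == "trunk":
        return min(4, code.back)
    raise ValueError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# LBA (L5/S1 forces)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LbaResult:
    moment: float  # N*m about L5/S1
    f_vertical: float  # N
    f_comp: float  # N, disc compression
    f_shear: float  # N, disc shear
    f_load: float
    d_load: float
    d_body: float


def lba_forces(
    sample: PostureSample,
    profile: AnthropometricProfile,
    f_load: float | None = None,
    d_load: float | None = None,
    d_body: float | None = None,
) -> LbaResult:
    """L5/S1 moment, compression, and shear for one posture.

    The moment sums the external-load and upper-body-weight contributions
    (``M = F_load d_load + a F_body d_body``); compression adds the extensor
    muscle force ``M / d_muscle`` to the vertical force
    ``F_load + a F_body``; shear is ``(F_load + F_body) sin(theta3)``.

    Defaults derived from the sample: ``f_load`` from the carried mass,
    ``d_load`` 0.4 m when a load is held, ``d_body`` from the trunk-flexion
    lever of a mid-trunk centre of mass (0.5 Lt sin theta3).
    """
    if profile.extensor_lever <= 0:
        raise ValueError("extensor_lever must be positive")
    theta3 = math.radians(sample.trunk_flexion)
    if f_load is None:
        f_load = sample.external_load_mass * GRAVITY
    if d_load is None:
        d_load = 0.4 if f_load > 0 else 0.0
    if d_body is None:
        d_body = 0.5 * profile.trunk_len * math.sin(theta3)
    if f_load < 0 or d_load < 0 or d_body < 0:
        raise ValueError("forces and lever arms must be >= 0")

    a = profile.upper_body_fraction
    f_body = profile.body_weight_force
    moment = f_load * d_load + a * f_body * d_body
    f_vertical = f_load + a * f_body
    f_comp = moment / profile.extensor_lever + f_vertical
    f_shear = (f_load + f_body) * math.sin(theta3)
    return LbaResult(
        moment=moment,
        f_vertical=f_vertical,
        f_comp=f_comp,
        f_shear=f_shear,
        f_load=f_load,
        d_load=d_load,
        d_body=d_body,
    )


# ---------------------------------------------------------------------------
# Comfort assessment (Krist-style deviation grading)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaBands:
    neutral: float
    comfort: tuple[float, float]  # grade 0 inside
    risk_low: float | None  # grade 2 below (None: no lower threshold)
    risk_high: float | None  # grade 2 above


#: per-joint neutral angle, comfort range, and high-risk thresholds (deg)
CA_TABLE: dict[str, CaBands] = {
    "shoulder_abduction": CaBands(0.0, (0.0, 20.0), None, 30.0),
    "elbow_flexion": CaBands(0.0, (80.0, 120.0), 60.0, 140.0),
    "lumbar_flexion": CaBands(0.0, (0.0, 20.0), None, 30.0),
    "knee_flexion": CaBands(0.0, (90.0, 110.0), 70.0, 130.0),
}

#: joints graded per analysis region
CA_REGION_JOINTS = {
    "upper": ("shoulder_abduction", "elbow_flexion"),
    "lower": ("knee_flexion",),
    "trunk": ("lumbar_flexion",),
    "whole": tuple(CA_TABLE),
}

CA_MAX_SCORE = 80.0
_CA_MAX_GRADE = 2


def ca_grade(joint: str, angle: float) -> tuple[float, int]:
    """Deviation ``D = |angle - neutral|`` and grade ``Di`` in {0, 1, 2}.

    Grade 0 inside the comfort range, 2 beyond a high-risk threshold,
    1 in between.  Deviation is two-sided: bending past neutral in either
    direction counts.
    """
    bands = CA_TABLE.get(joint)
    if bands is None:
        raise ValueError(f"unknown comfort-assessment joint {joint!r}")
    a = abs(angle) if bands.comfort[0] <= 0 <= bands.comfort[1] else angle
    deviation = abs(angle - bands.neutral)
    if bands.comfort[0] <= a <= bands.comfort[1]:
        return deviation, 0
    if (bands.risk_low is not None and a < bands.risk_low) or (
        bands.risk_high is not None and a > bands.risk_high
    ):
        return deviation, 2
    return deviation, 1


@dataclass(frozen=True)
class CaScore:
    deviations: dict[str, float]
    grades: dict[str, int]
    weights: dict[str, float]
    score: float  # sum w_i * D_i, in [0, CA_MAX_SCORE] under default weights


def ca_weights_for(joints: tuple[str, ...] | list[str]) -> dict[str, float]:
    """Equal weights scaled so the worst posture scores ``CA_MAX_SCORE``."""
    if not joints:
        raise ValueError("need at least one joint")
    w = CA_MAX_SCORE / (_CA_MAX_GRADE * len(joints))
    return {j: w for j in joints}


def ca_posture_score(
    grades: dict[str, int], weights: dict[str, float] | None = None
) -> CaScore:
    """Weighted sum of deviation grades (``P = sum w_i D_i``)."""
    if weights is None:
        weights = ca_weights_for(tuple(grades))
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    if sum(weights.values()) == 0:
        raise ValueError("weights must not all be zero")
    score = sum(weights[j] * grades[j] for j in grades)
    return CaScore(deviations={}, grades=dict(grades), weights=dict(weights), score=score)


def ca_score_sample(sample: PostureSample, region: str = "whole") -> CaScore:
    joints = CA_REGION_JOINTS.get(region)
    if joints is None:
        raise ValueError(f"unknown region {region!r}")
    angles = sample.ca_joint_angles()
    deviations: dict[str, float] = {}
    grades: dict[str, int] = {}
    for j in joints:
        d, g = ca_grade(j, angles[j])
        deviations[j] = d
        grades[j] = g
    weights = ca_weights_for(joints)
    score = ca_posture_score(grades, weights)
    return CaScore(
        deviations=deviations, grades=grades, weights=weights, score=score.score
    )


# ---------------------------------------------------------------------------
# region mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionScores:
    """Raw (un-normalised) P8-P11 for one region; ``None`` = not applicable."""

    region: str
    p8_rula: float | None
    p9_lba: float | None
    p10_ca: float | None
    p11_owas: float | None
    rula_range: tuple[int, int] | None = None
    details: dict = field(default_factory=dict)


def region_scores(
    sample: PostureSample,
    profile: AnthropometricProfile,
    region: str,
    owas_policy: str = "severity",
) -> RegionScores:
    """Evaluate the applicable posture scorers on one region's joint subset.

    Upper: additive RULA (arm + wrist + neck), comfort assessment
    (shoulder/elbow), OWAS arms.  Trunk: RULA (neck + trunk), comfort
    (lumbar), OWAS back.  Lower: LBA (whole-body by definition - lumbar
    loading has no regional variant) and OWAS legs.  Whole: all scorers on
    the full body.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    details: dict = {}

    if region in RULA_REGION_PARTS:
        rula = rula_score_sample(sample, region)
        details["rula"] = rula
        p8 = float(rula.p_rula)
        rr = rula_range(region)
    else:
        p8, rr = None, None

    if region == "lower":
        lba = lba_forces(sample, profile)
        details["lba"] = lba
        p9 = lba.f_comp
    else:
        p9 = None

    if region in CA_REGION_JOINTS and region != "lower":
        ca = ca_score_sample(sample, region)
        details["ca"] = ca
        p10 = ca.score
    else:
        p10 = None

    p11 = float(owas_region_level(sample, region, policy=owas_policy))

    return RegionScores(
        region=region,
        p8_rula=p8,
        p9_lba=p9,
        p10_ca=p10,
        p11_owas=p11,
        rula_range=rr,
        details=details,
    )
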