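"""Posture-load scorers: additive RULA bands, OWAS coding, L5/S1 forces,
comfort-assessment grading, and the region mapping."""

import itertools

import pytest

from ergocab.core import AnthropometricProfile, PostureSample, default_profile
from ergocab.posture_scores import (
    CA_TABLE,
    OWAS_RISK_TABLE,
    OwasCode,
    RulaParts,
    ca_grade,
    ca_posture_score,
    ca_score_sample,
    ca_weights_for,
    lba_forces,
    owas_code_from_sample,
    owas_level,
    region_scores,
    rula_part_scores,
    rula_range,
    rula_score_sample,
    rula_total,
)
from ergocab.posture_scores import _delta_e  # enumeration oracle needs the rule

NEUTRAL = PostureSample("S01")  # elbow 90, knee 100, everything else relaxed


class TestRulaBands:
    @pytest.mark.parametrize(
        "angle, points",
        [(0, 1), (10, 2), (20, 2), (30, 3), (45, 3), (50, 4), (-5, 4)],
    )
    def test_upper_arm_bands(self, angle, points):
        parts = rula_part_scores(PostureSample("x", shoulder_flexion=angle))
        assert parts.upper_arm == points

    @pytest.mark.parametrize(
        "angle, points", [(60, 1), (90, 1), (100, 1), (59, 2), (101, 2), (110, 2)]
    )
    def test_forearm_bands(self, angle, points):
        parts = rula_part_scores(PostureSample("x", elbow_flexion=angle))
        assert parts.forearm == points

    @pytest.mark.parametrize("angle, points", [(0, 1), (10, 1), (15, 2), (-20, 2)])
    def test_wrist_bands(self, angle, points):
        parts = rula_part_scores(PostureSample("x", wrist_flexion=angle))
        assert parts.wrist == points

    @pytest.mark.parametrize("angle, points", [(0, 1), (10, 1), (11, 2)])
    def test_neck_and_trunk_bands(self, angle, points):
        parts = rula_part_scores(
            PostureSample("x", neck_flexion=angle, trunk_flexion=angle)
        )
        assert parts.neck == points and parts.trunk == points

    def test_neutral_posture_part_sums(self):
        parts = rula_part_scores(NEUTRAL)
        assert (parts.pa, parts.pb, parts.delta_w) == (3, 2, 0)

    def test_wrist_twist_adds_one(self):
        twisted = rula_part_scores(PostureSample("x", wrist_twisted=True))
        assert twisted.delta_w == 1


class TestRulaTotal:
    @pytest.mark.parametrize(
        "pt, load, static, expected_de, expected_total, expected_level",
        [
            (2, 0.0, False, 0, 2, 1),
            (5, 0.0, False, 1, 6, 3),
            (8, 5.0, True, 3, 11, 4),
            (3, 1.5, False, 1, 4, 2),
        ],
    )
    def test_adjustment_rows(self, pt, load, static, expected_de, expected_total, expected_level):
        score = rula_total((pt - 2, 2, 0), load_mass=load, static_flag=static)
        assert score.pt == pt
        assert score.delta_e == expected_de
        assert score.p_rula == expected_total
        assert score.risk_level == expected_level

    @pytest.mark.parametrize("mass, points", [(0, 0), (1.5, 1), (2.0, 1), (2.1, 2)])
    def test_load_bands(self, mass, points):
        assert rula_total((1, 2, 0), load_mass=mass).load_score == points

    def test_muscle_use_flags(self):
        assert rula_total((1, 2, 0), static_flag=True).muscle_score == 1
        assert rula_total((1, 2, 0), repeat_rate=5.0).muscle_score == 1
        assert rula_total((1, 2, 0), repeat_rate=4.0).muscle_score == 0

    def test_risk_level_monotone_in_total(self):
        levels = [rula_total((p, 0, 0)).risk_level for p in range(1, 15)]
        assert levels == sorted(levels)

    def test_range_matches_brute_enumeration(self):
        """Independent oracle: enumerate every band/score combination."""
        totals = []
        for ua, fa, wr, nk, tr, dw in itertools.product(
            (1, 2, 3, 4), (1, 2), (1, 2), (1, 2), (1, 2), (0, 1)
        ):
            pt = ua + fa + wr + nk + tr + dw
            for load, muscle in itertools.product((0, 1, 2), (0, 1)):
                totals.append(pt + _delta_e(pt, load, muscle))
        assert rula_range("whole") == (min(totals), max(totals))
        lo, hi = rula_range("whole")
        assert lo < hi

    def test_neutral_posture_attains_the_minimum(self):
        score = rula_score_sample(NEUTRAL, "whole")
        assert score.p_rula == rula_range("whole")[0]


class TestOwas:
    @pytest.mark.parametrize("row", OWAS_RISK_TABLE)
    def test_printed_rows_round_trip(self, row):
        back, arms, legs, load, level = row
        pick = lambda cell, default: (
            default if cell is None else (cell[0] if isinstance(cell, tuple) else cell)
        )
        code = OwasCode(pick(back, 1), pick(arms, 1), pick(legs, 1), pick(load, 1))
        assert owas_level(code, policy="strict") == level

    def test_wildcard_row_matches_any_arm_leg(self):
        assert owas_level(OwasCode(4, 3, 2, 2), policy="strict") == 4

    def test_strict_policy_rejects_unlisted(self):
        with pytest.raises(ValueError, match="unclassified"):
            owas_level(OwasCode(1, 3, 1, 1), policy="strict")

    def test_severity_policy_takes_worst_dimension(self):
        assert owas_level(OwasCode(1, 3, 1, 1)) == 3
        assert owas_level(OwasCode(1, 1, 4, 1)) == 4

    def test_code_from_seated_light_posture(self):
        s = PostureSample("x", trunk_flexion=5, external_load_mass=2.0)
        assert owas_code_from_sample(s) == OwasCode(1, 1, 1, 1)

    @pytest.mark.parametrize(
        "kwargs, field, value",
        [
            ({"trunk_flexion": 50}, "back", 3),
            ({"trunk_flexion": 30}, "back", 2),
            ({"trunk_lateral": 20}, "back", 4),
            ({"shoulder_flexion": 95}, "arms", 2),
            ({"external_load_mass": 15}, "load", 2),
            ({"external_load_mass": 25}, "load", 3),
        ],
    )
    def test_coding_rules(self, kwargs, field, value):
        code = owas_code_from_sample(PostureSample("x", **kwargs))
        assert getattr(code, field) == value


class TestLba:
    def test_moment_from_load_and_body(self, p50):
        # 100 N at 0.4 m plus a 400 N upper body at 0.2 m -> 120 N*m
        profile = AnthropometricProfile(0.3, 0.25, 0.5, 0.4, 0.38, 800.0)
        res = lba_forces(NEUTRAL, profile, f_load=100.0, d_load=0.4, d_body=0.2)
        assert res.moment == pytest.approx(120.0)

    def test_compression_sums_muscle_and_vertical_forces(self):
        # moment 120 N*m over a 0.06 m lever + 100 N load + 200 N upper body
        profile = AnthropometricProfile(0.3, 0.25, 0.5, 0.4, 0.38, 400.0)
        res = lba_forces(NEUTRAL, profile, f_load=100.0, d_load=0.4, d_body=0.4)
        assert res.moment == pytest.approx(40 + 200 * 0.4)
        assert res.f_comp == pytest.approx(res.moment / 0.06 + 100 + 200)

    def test_upright_unloaded_shear_is_zero(self, p50):
        res = lba_forces(NEUTRAL, p50)
        assert res.f_shear == 0.0
        assert res.f_load == 0.0

    def test_compression_monotone_in_each_input(self, p50):
        base = lba_forces(NEUTRAL, p50, f_load=100, d_load=0.4, d_body=0.2).f_comp
        assert lba_forces(NEUTRAL, p50, f_load=150, d_load=0.4, d_body=0.2).f_comp > base
        assert lba_forces(NEUTRAL, p50, f_load=100, d_load=0.5, d_body=0.2).f_comp > base
        assert lba_forces(NEUTRAL, p50, f_load=100, d_load=0.4, d_body=0.3).f_comp > base

    def test_shear_tracks_trunk_flexion(self, p50):
        bent = PostureSample("x", trunk_flexion=30)
        res = lba_forces(bent, p50, f_load=100, d_load=0.4)
        assert res.f_shear == pytest.approx((100 + p50.body_weight_force) * 0.5)

    def test_degenerate_extensor_lever_rejected(self, p50):
        import dataclasses, warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            broken = dataclasses.replace(p50, extensor_lever=0.0)
        with pytest.raises(ValueError, match="extensor_lever"):
            lba_forces(NEUTRAL, broken)


class TestComfortAssessment:
    @pytest.mark.parametrize(
        "joint, angle, grade",
        [
            ("elbow_flexion", 100, 0),
            ("elbow_flexion", 70, 1),
            ("elbow_flexion", 50, 2),
            ("elbow_flexion", 145, 2),
            ("lumbar_flexion", 10, 0),
            ("lumbar_flexion", 25, 1),
            ("lumbar_flexion", 35, 2),
            ("shoulder_abduction", 0, 0),
            ("shoulder_abduction", 25, 1),
            ("shoulder_abduction", 40, 2),
            ("knee_flexion", 100, 0),
            ("knee_flexion", 120, 1),
            ("knee_flexion", 135, 2),
        ],
    )
    def test_printed_bands(self, joint, angle, grade):
        d, di = ca_grade(joint, angle)
        assert di == grade
        assert d == abs(angle - CA_TABLE[joint].neutral)

    def test_neutral_shoulder_has_zero_deviation(self):
        assert ca_grade("shoulder_abduction", 0.0) == (0.0, 0)

    def test_unknown_joint_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ca_grade("tail", 10.0)

    def test_score_is_zero_at_neutral_and_eighty_at_worst(self):
        joints = tuple(CA_TABLE)
        weights = ca_weights_for(joints)
        assert ca_posture_score({j: 0 for j in joints}, weights).score == 0.0
        assert ca_posture_score({j: 2 for j in joints}, weights).score == pytest.approx(80.0)

    def test_linearity_in_weights(self):
        grades = {"elbow_flexion": 1, "knee_flexion": 2}
        w = {"elbow_flexion": 1.0, "knee_flexion": 1.0}
        base = ca_posture_score(grades, w).score
        w2 = {"elbow_flexion": 2.0, "knee_flexion": 1.0}
        assert ca_posture_score(grades, w2).score == base + 1.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ca_posture_score({"elbow_flexion": 1}, {"elbow_flexion": 0.0})

    def test_score_monotone_in_any_grade(self):
        joints = tuple(CA_TABLE)
        weights = ca_weights_for(joints)
        base = {j: 1 for j in joints}
        for j in joints:
            worse = dict(base) | {j: 2}
            assert (
                ca_posture_score(worse, weights).score
                > ca_posture_score(base, weights).score
            )


class TestRegionMapping:
    def test_neutral_whole_region_composes_scorer_neutrals(self, p50):
        rs = region_scores(NEUTRAL, p50, "whole")
        assert rs.p8_rula == rula_score_sample(NEUTRAL, "whole").p_rula
        assert rs.p10_ca == 0.0
        assert rs.p11_owas == 1.0
        assert rs.p9_lba is None  # lumbar loading reported in the lower region

    def test_upper_region_ignores_trunk(self, p50):
        bent = PostureSample("S01", trunk_flexion=40)
        up_neutral = region_scores(NEUTRAL, p50, "upper")
        up_bent = region_scores(bent, p50, "upper")
        assert up_neutral.p8_rula == up_bent.p8_rula

    def test_lower_region_reports_whole_body_lumbar_load(self, p50):
        rs = region_scores(NEUTRAL, p50, "lower")
        assert rs.p9_lba == pytest.approx(lba_forces(NEUTRAL, p50).f_comp)
        assert rs.p8_rula is None  # no leg variant of the upper-limb scorer

    def test_regional_rula_ranges_are_narrower(self):
        assert rula_range("trunk") == (2, 6)
        assert rula_range("upper")[1] < rula_range("whole")[1]

    def test_trunk_region_ca_uses_lumbar_only(self, p50):
        bent = PostureSample("S01", trunk_flexion=35)
        rs = region_scores(bent, p50, "trunk")
        # one joint at grade 2 with weights scaled to a 0-80 ceiling
        assert rs.p10_ca == pytest.approx(80.0)

    def test_parts_container_sums(self):
        parts = RulaParts(2, 1, 1, 1, 2, 1)
        assert parts.pa == 4 and parts.pb == 3
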