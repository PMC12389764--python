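"""Reach envelopes: forward kinematics, membership queries, P4-P7 scores."""

import numpy as np
import pytest

from ergocab.core import (
    AnthropometricProfile,
    CockpitLayout,
    ControlPoint,
    standard_frames,
)
from ergocab.reach import (
    COMFORT_ARM_RANGES,
    PHYSIO_ARM_RANGES,
    ArmAngles,
    LegAngles,
    ReachOptions,
    TrunkAngles,
    arm_endpoint,
    arm_max_endpoint,
    foot_endpoint,
    knee_arc_contains,
    leg_region_boundary,
    reachable,
    score_reach,
    trunk_offset,
)

PROFILE = AnthropometricProfile(
    upper_arm_len=0.30,
    forearm_len=0.25,
    trunk_len=0.50,
    thigh_len=0.40,
    shank_len=0.38,
    body_weight_force=700.0,
)


class TestArmChain:
    def test_straight_arm_along_x(self):
        assert np.allclose(arm_endpoint(ArmAngles(0, 0, 0, 0), PROFILE), (0.55, 0, 0))

    def test_flexed_arm_hand_position(self):
        p = arm_endpoint(ArmAngles(30, 0, 60, 0), PROFILE)
        assert np.allclose(p, (0.2598, 0.40, 0), atol=1e-4)

    def test_full_abduction_moves_laterally(self):
        p = arm_endpoint(ArmAngles(0, 90, 0, 0), PROFILE)
        assert np.allclose(p, (0, 0, 0.55), atol=1e-12)

    def test_trunk_offset(self):
        assert trunk_offset(TrunkAngles(0, 0), PROFILE) == (0, 0)
        assert trunk_offset(TrunkAngles(30, 0), PROFILE)[0] == pytest.approx(0.25)
        assert trunk_offset(TrunkAngles(0, 15), PROFILE)[1] == pytest.approx(0.1294, abs=1e-4)

    def test_neutral_trunk_adds_trunk_length_in_z(self):
        arm = arm_endpoint(ArmAngles(30, 0, 60, 0), PROFILE)
        full = arm_max_endpoint(ArmAngles(30, 0, 60, 0), TrunkAngles(0, 0), PROFILE)
        assert np.allclose(full, arm + np.array([0, 0, 0.5]))

    def test_flexed_trunk_chain(self):
        full = arm_max_endpoint(ArmAngles(30, 0, 60, 0), TrunkAngles(30, 0), PROFILE)
        assert np.allclose(full, (0.5098, 0.40, 0.4330), atol=1e-4)

    def test_endpoint_never_exceeds_total_chain_length(self):
        rng = np.random.default_rng(7)
        total = PROFILE.trunk_len + PROFILE.upper_arm_len + PROFILE.forearm_len
        for _ in range(200):
            arm = ArmAngles(
                *(rng.uniform(lo, hi) for lo, hi in PHYSIO_ARM_RANGES.values())
            )
            trunk = TrunkAngles(rng.uniform(0, 30), rng.uniform(0, 15))
            assert np.linalg.norm(arm_max_endpoint(arm, trunk, PROFILE)) <= total + 1e-9


class TestLegChain:
    def test_folded_zero_angles(self):
        assert np.allclose(foot_endpoint(LegAngles(0, 0), PROFILE), (0, 0.02))

    def test_right_angle_pose(self):
        assert np.allclose(
            foot_endpoint(LegAngles(90, 90), PROFILE), (0.40, 0.38), atol=1e-12
        )

    def test_collinear_segments_at_zero_knee_parameter(self):
        for th in (0.0, 30.0, 75.0):
            p = foot_endpoint(LegAngles(th, 0), PROFILE)
            assert np.linalg.norm(p) == pytest.approx(
                abs(PROFILE.thigh_len - PROFILE.shank_len)
            )

    def test_point_on_knee_circle(self):
        # centre (0, 0.40), radius 0.38: (0.38, 0.40) lies exactly on it
        assert knee_arc_contains((0.38, 0.40), 0.0, PROFILE, tol=0.001)

    def test_circle_centre_is_not_on_the_arc(self):
        assert not knee_arc_contains((0.0, 0.40), 0.0, PROFILE, tol=0.01)

    def test_tolerance_contract(self):
        tol = 0.02
        p = (0.0, 0.40 + PROFILE.shank_len + 2 * tol)
        assert not knee_arc_contains(p, 0.0, PROFILE, tol=tol)

    def test_arc_restriction_by_knee_range(self):
        # straight-leg point (chain parameter 180 deg) from a seated hip
        straight = foot_endpoint(LegAngles(90, 180), PROFILE)
        assert knee_arc_contains(straight, 90.0, PROFILE, tol=1e-6, knee_range=(45, 180))
        assert not knee_arc_contains(straight, 90.0, PROFILE, tol=1e-6, knee_range=(45, 90))


class TestLegRegionBoundary:
    def test_vertices_are_forward_kinematic_images(self):
        verts, params = leg_region_boundary(PROFILE, step=5.0)
        for v, (th, tk) in zip(verts, params):
            assert np.allclose(v, foot_endpoint(LegAngles(th, tk), PROFILE), atol=1e-12)

    def test_boundary_closes_and_corners_coincide(self):
        verts, _ = leg_region_boundary(PROFILE, step=2.0)
        assert np.linalg.norm(verts[0] - verts[-1]) < 1e-9

    def test_enclosed_area_positive(self):
        verts, _ = leg_region_boundary(PROFILE, step=2.0)
        x, y = verts[:, 0], verts[:, 1]
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert shoelace > 0.1

    def test_degenerate_hip_limits_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            leg_region_boundary(PROFILE, hip_limits=(30.0, 30.0))


class TestMembership:
    def test_beyond_total_length_is_unreachable(self):
        total = PROFILE.trunk_len + PROFILE.upper_arm_len + PROFILE.forearm_len
        assert not reachable((total + 0.05, 0, 0), PROFILE, "upper_max")
        assert not reachable((1.2, 0, 0), PROFILE, "upper_comfort")

    def test_forward_images_are_members(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            angles = ArmAngles(
                *(rng.uniform(lo, hi) for lo, hi in COMFORT_ARM_RANGES.values())
            )
            p = arm_endpoint(angles, PROFILE)
            assert reachable(p, PROFILE, "upper_comfort")
            assert reachable(p, PROFILE, "upper_max")  # comfort subset of max

    def test_comfort_subset_of_max_on_probes(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            p = rng.uniform([-0.6, -0.6, -0.6], [0.8, 0.8, 0.8])
            if reachable(p, PROFILE, "upper_comfort"):
                assert reachable(p, PROFILE, "upper_max")

    def test_agrees_with_dense_grid_oracle(self):
        """Exhaustive forward-kinematics sweep as the membership oracle.

        The oracle grid quantises the envelope surface more coarsely than
        the 5 mm membership tolerance, so probes whose oracle distance is
        within the quantisation band of the tolerance may legitimately
        disagree; every decisive probe must match.
        """
        step = 3.0
        axes = [
            np.arange(lo, hi + step, step) for lo, hi in COMFORT_ARM_RANGES.values()
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        t1, p1, t2, p2 = [np.radians(m.ravel()) for m in mesh]
        L1, L2 = PROFILE.upper_arm_len, PROFILE.forearm_len
        pts = np.stack(
            [
                L1 * np.cos(t1) * np.cos(p1) + L2 * np.cos(t1 + t2) * np.cos(p1 + p2),
                L1 * np.sin(t1) + L2 * np.sin(t1 + t2),
                L1 * np.cos(t1) * np.sin(p1) + L2 * np.cos(t1 + t2) * np.sin(p1 + p2),
            ],
            axis=1,
        )
        opts = ReachOptions()
        guard = 0.03  # grid quantisation allowance (m)
        rng = np.random.default_rng(17)
        n_decisive = 0
        for _ in range(150):
            probe = rng.uniform([-0.3, -0.4, -0.3], [0.6, 0.6, 0.6])
            oracle_dist = float(np.min(np.linalg.norm(pts - probe, axis=1)))
            ours = reachable(probe, PROFILE, "upper_comfort", opts)
            oracle = oracle_dist <= opts.eps
            if abs(oracle_dist - opts.eps) > guard:
                n_decisive += 1
                assert ours == oracle, (probe, oracle_dist)
        assert n_decisive > 100  # the probe cloud is mostly decisive


class TestReachScores:
    def _layout(self, controls):
        return CockpitLayout(controls=controls, **standard_frames())

    def test_one_of_four_intensive_unreachable(self):
        frames = standard_frames()
        inv = frames["shoulder_from_cab"].inverse()
        good = [
            inv.apply(arm_endpoint(ArmAngles(20, 20, 70, 0), PROFILE)),
            inv.apply(arm_endpoint(ArmAngles(40, 30, 90, 10), PROFILE)),
            inv.apply(arm_endpoint(ArmAngles(10, 45, 60, -10), PROFILE)),
        ]
        controls = [
            ControlPoint(f"c{i}", p, ops_per_minute=6.0) for i, p in enumerate(good)
        ] + [ControlPoint("far", (2.0, 0, 1.0), ops_per_minute=6.0)]
        scores = score_reach(self._layout(controls), PROFILE)
        assert scores.p4 == pytest.approx(0.25)
        assert scores.p5 is None  # no secondary upper controls
        assert scores.p6 is None and scores.p7 is None

    def test_double_arm_length_fails_both_upper_modes(self):
        far = (2 * (PROFILE.upper_arm_len + PROFILE.forearm_len) + PROFILE.trunk_len, 0, 0)
        assert not reachable(far, PROFILE, "upper_comfort")
        assert not reachable(far, PROFILE, "upper_max")

    def test_all_reachable_layout_scores_zero(self, allgood, p50):
        layout, truth = allgood
        scores = score_reach(layout, p50)
        expected = truth.expected_leaf_scores()
        assert (scores.p4, scores.p5, scores.p6, scores.p7) == (
            expected["P4"],
            expected["P5"],
            expected["P6"],
            expected["P7"],
        ) == (0.0, 0.0, 0.0, 0.0)
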