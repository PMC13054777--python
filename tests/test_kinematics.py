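"""Unit and property tests for the angular data model and metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stancekin.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    MissingLandmarkError,
    UndefinedIndexError,
)
from stancekin.kinematics import (
    FORELIMB_JOINTS,
    JointPose,
    LimbRecord,
    SpeciesRecord,
    aui,
    extract_poses_from_landmarks,
    jae,
    joint_angle,
    mass_class_for,
    relative_jae,
    segment_angle,
    summarize_limb,
    tae,
)


def fore_limb(angles, seg_td=25.0, seg_to=-25.0):
    """Helper: forelimb record from {joint: (td, ms, to)}."""
    poses = [JointPose(j, *angles[j]) for j in FORELIMB_JOINTS]
    return LimbRecord("forelimb", poses, seg_angle_td=seg_td, seg_angle_to=seg_to)


class TestJointAngle:
    def test_collinear_points_give_straight_angle(self):
        assert joint_angle((0, 2), (0, 0), (0, -2)) == pytest.approx(180.0)

    def test_perpendicular_rays(self):
        assert joint_angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90.0)

    def test_matches_dot_product_oracle(self):
        a, j, d = np.array([2.0, 1.0]), np.array([0.0, 0.0]), np.array([3.0, -1.0])
        u, v = a - j, d - j
        expected = math.degrees(
            math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        )
        assert joint_angle(a, j, d) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle((0, 0), (0, 0), (1, 1))

    @given(
        st.floats(1.0, 179.0),
        st.floats(0.0, 360.0),
        st.floats(0.1, 10.0),
        st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_recovers_constructed_angle(self, phi, heading, r1, r2):
        """Placing rays phi degrees apart recovers phi, whatever the frame."""
        t0 = math.radians(heading)
        t1 = t0 + math.radians(phi)
        p = (r1 * math.cos(t0), r1 * math.sin(t0))
        d = (r2 * math.cos(t1), r2 * math.sin(t1))
        assert joint_angle(p, (0, 0), d) == pytest.approx(phi, abs=1e-7)


class TestSegmentAngle:
    @pytest.mark.parametrize(
        "pivot,expected",
        [((0, 1), 0.0), ((1, 1), 45.0), ((-1, 1), -45.0)],
    )
    def test_sign_convention_from_vertical(self, pivot, expected):
        assert segment_angle((0, 0), pivot, travel_sign=1.0) == pytest.approx(expected)

    def test_travel_direction_flips_sign(self):
        assert segment_angle((0, 0), (1, 1), travel_sign=-1.0) == pytest.approx(-45.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            segment_angle((1, 1), (1, 1))


class TestJae:
    @pytest.mark.parametrize(
        "angles,expected",
        [((96, 72, 63), 33.0), ((100, 100, 100), 0.0), ((100, 80, 120), 40.0)],
    )
    def test_max_minus_min(self, angles, expected):
        assert jae(JointPose("shoulder", *angles)) == pytest.approx(expected)

    def test_two_events_suffice(self):
        assert jae(JointPose("hip", angle_td=60, angle_to=100)) == pytest.approx(40.0)

    def test_single_event_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            jae(JointPose("hip", angle_td=60))

    @given(
        st.permutations([0, 1, 2]),
        st.tuples(st.floats(0, 300), st.floats(0, 300), st.floats(0, 300)),
        st.floats(0, 50),
    )
    @settings(deadline=None, max_examples=100)
    def test_invariant_to_event_relabeling_and_offset(self, perm, angles, shift):
        """JAE ignores which event is which and any common angular offset."""
        base = jae(JointPose("knee", *angles))
        permuted = [angles[i] for i in perm]
        assert jae(JointPose("knee", *permuted)) == pytest.approx(base)
        shifted = [min(a + shift, 359.999) for a in angles]
        if max(shifted) - min(shifted) == pytest.approx(max(angles) - min(angles)):
            assert jae(JointPose("knee", *shifted)) == pytest.approx(base, abs=1e-9)


class TestTaeAui:
    @pytest.mark.parametrize(
        "seg_td,seg_to,expected", [(25, -25, 50.0), (10, 10, 0.0), (30, -34, 64.0)]
    )
    def test_tae_absolute_sweep(self, seg_td, seg_to, expected):
        limb = fore_limb(
            {j: (90, 90, 90) for j in FORELIMB_JOINTS}, seg_td=seg_td, seg_to=seg_to
        )
        assert tae(limb) == pytest.approx(expected)

    def test_tae_requires_both_segment_angles(self):
        limb = fore_limb({j: (90, 90, 90) for j in FORELIMB_JOINTS}, seg_to=None)
        with pytest.raises(InsufficientDataError):
            tae(limb)

    def test_midstance_variant_captures_extremum(self):
        limb = fore_limb({j: (90, 90, 90) for j in FORELIMB_JOINTS}, 10.0, -10.0)
        limb.seg_angle_ms = 30.0
        assert tae(limb) == pytest.approx(20.0)
        assert tae(limb, use_midstance=True) == pytest.approx(40.0)

    @pytest.mark.parametrize(
        "t,s,expected", [(50, 100, 50.0), (63, 63, 100.0), (45, 63, 71.43)]
    )
    def test_aui_ratio(self, t, s, expected):
        assert aui(t, s) == pytest.approx(expected, abs=0.005)

    def test_aui_undefined_for_zero_denominator(self):
        with pytest.raises(UndefinedIndexError):
            aui(50, 0)


class TestRelativeJae:
    @pytest.mark.parametrize(
        "jaes,expected",
        [
            ((30, 30, 30), (33.333, 33.333, 33.333)),
            ((60, 0, 0), (100.0, 0.0, 0.0)),
            ((36, 24, 35), (37.895, 25.263, 36.842)),
        ],
    )
    def test_shares(self, jaes, expected):
        out = relative_jae(dict(zip(FORELIMB_JOINTS, jaes)))
        for j, e in zip(FORELIMB_JOINTS, expected):
            assert out[j] == pytest.approx(e, abs=0.005)

    @given(st.lists(st.floats(0.1, 200.0), min_size=3, max_size=3))
    @settings(deadline=None)
    def test_complete_limb_shares_sum_to_100(self, jaes):
        out = relative_jae(dict(zip(FORELIMB_JOINTS, jaes)))
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)


class TestSummarizeLimb:
    def test_composes_elementary_metrics(self):
        limb = fore_limb(
            {"shoulder": (100, 95, 90), "elbow": (100, 110, 120), "wrist": (140, 150, 170)},
            seg_td=15.0,
            seg_to=-15.0,
        )
        s = summarize_limb(limb)
        assert s.sum_jae == pytest.approx(10 + 20 + 30)
        assert s.tae == pytest.approx(30.0)
        assert s.aui_pct == pytest.approx(50.0)

    def test_missing_joint_excluded_and_flagged(self):
        limb = fore_limb(
            {"shoulder": (100, 95, 90), "elbow": (None, None, None), "wrist": (140, 150, 170)}
        )
        s = summarize_limb(limb)
        assert s.missing_joints == ("elbow",)
        assert s.sum_jae == pytest.approx(10 + 30)
        assert s.jae_per_joint["elbow"] is None
        assert s.relative_jae_pct["elbow"] is None

    def test_recomposition_on_random_limbs(self):
        """summarize_limb equals recomputation from the raw fields."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            angles = {j: tuple(rng.uniform(10, 340, 3)) for j in FORELIMB_JOINTS}
            seg_td, seg_to = rng.uniform(-60, 60, 2)
            limb = fore_limb(angles, seg_td=seg_td, seg_to=seg_to)
            s = summarize_limb(limb)
            jaes = {j: max(a) - min(a) for j, a in angles.items()}
            assert s.sum_jae == pytest.approx(sum(jaes.values()))
            assert s.tae == pytest.approx(abs(seg_to - seg_td))
            if s.sum_jae > 0:
                assert s.aui_pct == pytest.approx(100 * s.tae / s.sum_jae)
                for j in FORELIMB_JOINTS:
                    assert s.relative_jae_pct[j] == pytest.approx(
                        100 * jaes[j] / s.sum_jae
                    )

    def test_scaling_angles_preserves_aui(self):
        angles = {"shoulder": (100, 95, 90), "elbow": (100, 110, 120), "wrist": (140, 150, 170)}
        limb = fore_limb(angles, seg_td=15.0, seg_to=-15.0)
        c = 1.7
        scaled = fore_limb(
            {j: tuple(c * a for a in v) for j, v in angles.items()},
            seg_td=c * 15.0,
            seg_to=c * -15.0,
        )
        s0, s1 = summarize_limb(limb), summarize_limb(scaled)
        assert s1.sum_jae == pytest.approx(c * s0.sum_jae)
        assert s1.tae == pytest.approx(c * s0.tae)
        assert s1.aui_pct == pytest.approx(s0.aui_pct)


class TestSpeciesRecord:
    def test_mass_class_thresholds(self):
        assert mass_class_for(0.5) == "small"
        assert mass_class_for(1.0) == "medium"
        assert mass_class_for(29.9) == "medium"
        assert mass_class_for(30.0) == "large"
        assert mass_class_for(100.0) == "large"
        assert mass_class_for(100.5) == "very_large"

    def test_inconsistent_mass_class_rejected(self):
        limb = fore_limb({j: (90, 90, 90) for j in FORELIMB_JOINTS})
        with pytest.raises(ValueError, match="mass_class"):
            SpeciesRecord(
                species_id="Genus_species",
                order_name="Carnivora",
                body_mass_kg=250.0,
                posture="digitigrade",
                habit="cursorial",
                mass_class="small",
                forelimb=limb,
            )

    def test_at_least_one_limb_required(self):
        with pytest.raises(ValueError, match="limb"):
            SpeciesRecord(
                species_id="Genus_species",
                order_name="Rodentia",
                body_mass_kg=0.2,
                posture="plantigrade",
                habit="scansorial",
            )


# ---------------------------------------------------------------------------
# landmark extraction
# ---------------------------------------------------------------------------

MARKER_MAP = {
    "m_trunk": "trunk",
    "m_shoulder": "shoulder",
    "m_elbow": "elbow",
    "m_wrist": "wrist",
    "m_toe": "contact",
}


def chain_track(angle_sets, seg_length=1.0):
    """Forward geometry: landmark frames from interior joint angles.

    Each frame is built by turning the chain so the interior angle at each
    joint equals the requested value; recovery via arccos is an independent
    path through the geometry.
    """
    rows = []
    markers = list(MARKER_MAP)
    for frame, (phis, heading) in enumerate(angle_sets):
        pts = [np.array([0.0, 10.0])]
        direction = math.radians(heading)
        pts.append(pts[0] + seg_length * np.array([math.cos(direction), math.sin(direction)]))
        for phi in phis:
            # interior angle phi at the last joint: rotate the back-pointing
            # ray by phi to get the outgoing direction
            back = direction + math.pi
            direction = back - math.radians(phi)
            pts.append(pts[-1] + seg_length * np.array([math.cos(direction), math.sin(direction)]))
        for name, p in zip(markers, pts):
            rows.append({"frame": frame, "marker": name, "x": p[0], "y": p[1]})
    return pd.DataFrame(rows)


class TestExtractPoses:
    def test_straight_leg_gives_180_everywhere(self):
        track = chain_track([((180, 180, 180), -90.0)] * 3)
        limb = extract_poses_from_landmarks(
            track, {"td": 0, "ms": 1, "to": 2}, MARKER_MAP, "forelimb"
        )
        for pose in limb.poses:
            for angle in pose.angles.values():
                assert angle == pytest.approx(180.0, abs=1e-6)

    def test_forward_geometry_round_trip(self):
        rng = np.random.default_rng(7)
        sets = [(tuple(rng.uniform(30, 170, 3)), rng.uniform(-120, -60)) for _ in range(3)]
        track = chain_track(sets)
        limb = extract_poses_from_landmarks(
            track, {"td": 0, "ms": 1, "to": 2}, MARKER_MAP, "forelimb"
        )
        for ev_idx, ev in enumerate(("td", "ms", "to")):
            expected = sets[ev_idx][0]
            for pose, phi in zip(limb.poses, expected):
                assert pose.angles[ev] == pytest.approx(phi, abs=1e-6)

    def test_segment_angles_computed_at_td_and_to(self):
        track = chain_track([((170, 170, 170), -80.0), ((160, 160, 160), -85.0)])
        limb = extract_poses_from_landmarks(
            track, {"td": 0, "to": 1}, MARKER_MAP, "forelimb"
        )
        assert limb.seg_angle_td is not None and limb.seg_angle_to is not None
        # near-straight, near-vertical leg: segment angle close to 0
        assert abs(limb.seg_angle_td) < 45

    def test_missing_marker_names_frame_and_marker(self):
        track = chain_track([((150, 150, 150), -90.0)] * 3)
        track = track[~((track["frame"] == 1) & (track["marker"] == "m_elbow"))]
        with pytest.raises(MissingLandmarkError, match="m_elbow.*frame 1"):
            extract_poses_from_landmarks(
                track, {"td": 0, "ms": 1, "to": 2}, MARKER_MAP, "forelimb"
            )

    def test_y_down_flag_flips_image_coordinates(self):
        track = chain_track([((120, 140, 160), -90.0)] * 3)
        flipped = track.assign(y=-track["y"])
        a = extract_poses_from_landmarks(
            track, {"td": 0, "ms": 1, "to": 2}, MARKER_MAP, "forelimb"
        )
        b = extract_poses_from_landmarks(
            flipped, {"td": 0, "ms": 1, "to": 2}, MARKER_MAP, "forelimb", y_down=True
        )
        for pa, pb in zip(a.poses, b.poses):
            for ev in ("td", "ms", "to"):
                assert pa.angles[ev] == pytest.approx(pb.angles[ev], abs=1e-9)
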