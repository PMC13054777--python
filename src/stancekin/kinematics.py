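"""Angular data model and stance-phase kinematic metrics.

Joint angles are measured at three discrete stance events — touchdown (TD),
midstance (MS) and toe-off (TO) — for the shoulder/elbow/wrist (forelimb) and
hip/knee/ankle (hindlimb). From those poses this module derives:

* JAE, the joint angular excursion: max - min angle across the events;
* TAE, the total angular excursion of the functional limb segment (the line
  from the ground-contact point to the shoulder or hip) between TD and TO;
* AUI%, the angular utilization index: 100 * TAE / sum(JAE), the fraction of
  summed joint excursion realized as net limb excursion;
* relative JAE, each joint's percentage share of its limb's summed excursion.

All angles are stored in degrees. Missing events or joints are explicit
(``None``) and propagate as missing — never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    MissingLandmarkError,
    UndefinedIndexError,
)

FORELIMB_JOINTS = ("shoulder", "elbow", "wrist")
HINDLIMB_JOINTS = ("hip", "knee", "ankle")
JOINTS = FORELIMB_JOINTS + HINDLIMB_JOINTS
EVENTS = ("td", "ms", "to")

POSTURES = ("plantigrade", "digitigrade", "subunguligrade", "unguligrade", "mixed")
MASS_CLASSES = ("small", "medium", "large", "very_large")
SPEED_CLASSES = ("slow", "medium", "fast")
HABITS = ("cursorial", "scansorial", "arboreal", "terrestrial")


def mass_class_for(body_mass_kg: float) -> str:
    """Categorize body mass: small < 1 kg, medium 1-29, large 30-100, very large > 100."""
    if body_mass_kg <= 0 or not math.isfinite(body_mass_kg):
        raise ValueError(f"body mass must be positive and finite, got {body_mass_kg}")
    if body_mass_kg < 1:
        return "small"
    if body_mass_kg < 30:
        return "medium"
    if body_mass_kg <= 100:
        return "large"
    return "very_large"


def speed_class_for(top_speed_kmh: float) -> str:
    """Categorize top speed: slow < 35 km/h, medium 35-50, fast > 50."""
    if top_speed_kmh < 35:
        return "slow"
    if top_speed_kmh <= 50:
        return "medium"
    return "fast"


def _check_angle(value: Optional[float], what: str) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    if not math.isfinite(value) or not (0.0 <= value < 360.0):
        raise ValueError(f"{what} must be finite and in [0, 360), got {value}")
    return value


@dataclass
class JointPose:
    """Angles of one joint at the three stance events, in degrees.

    Missing events are ``None`` and are excluded from excursion computation.
    """

    joint_name: str
    angle_td: Optional[float] = None
    angle_ms: Optional[float] = None
    angle_to: Optional[float] = None

    def __post_init__(self):
        if self.joint_name not in JOINTS:
            raise ValueError(f"unknown joint {self.joint_name!r}")
        self.angle_td = _check_angle(self.angle_td, f"{self.joint_name} TD angle")
        self.angle_ms = _check_angle(self.angle_ms, f"{self.joint_name} MS angle")
        self.angle_to = _check_angle(self.angle_to, f"{self.joint_name} TO angle")

    @property
    def angles(self) -> dict[str, Optional[float]]:
        return {"td": self.angle_td, "ms": self.angle_ms, "to": self.angle_to}

    @property
    def present_angles(self) -> list[float]:
        return [a for a in (self.angle_td, self.angle_ms, self.angle_to) if a is not None]


@dataclass
class LimbRecord:
    """One limb's joint poses plus the functional-segment angles at TD and TO.

    Segment angles are signed, measured from the vertical through the contact
    point, positive toward the direction of travel.
    """

    limb: str
    poses: Sequence[JointPose]
    seg_angle_td: Optional[float] = None
    seg_angle_to: Optional[float] = None
    seg_angle_ms: Optional[float] = None

    def __post_init__(self):
        if self.limb not in ("forelimb", "hindlimb"):
            raise ValueError(f"limb must be forelimb or hindlimb, got {self.limb!r}")
        expected = FORELIMB_JOINTS if self.limb == "forelimb" else HINDLIMB_JOINTS
        names = tuple(p.joint_name for p in self.poses)
        if sorted(names) != sorted(expected):
            raise ValueError(f"{self.limb} poses must cover {expected}, got {names}")
        self.poses = tuple(sorted(self.poses, key=lambda p: expected.index(p.joint_name)))
        for a in (self.seg_angle_td, self.seg_angle_to, self.seg_angle_ms):
            if a is not None and not math.isfinite(float(a)):
                raise ValueError("segment angles must be finite")

    @property
    def joint_names(self) -> tuple[str, ...]:
        return tuple(p.joint_name for p in self.poses)

    def pose(self, joint_name: str) -> JointPose:
        for p in self.poses:
            if p.joint_name == joint_name:
                return p
        raise KeyError(joint_name)


@dataclass
class SpeciesRecord:
    """One species' mass, factor categories and per-limb angular data."""

    species_id: str
    order_name: str
    body_mass_kg: float
    posture: str
    habit: str
    mass_class: Optional[str] = None
    speed_class: Optional[str] = None
    forelimb: Optional[LimbRecord] = None
    hindlimb: Optional[LimbRecord] = None
    stride_length: Optional[float] = None

    def __post_init__(self):
        if self.body_mass_kg <= 0 or not math.isfinite(self.body_mass_kg):
            raise ValueError("body mass must be positive and finite")
        expected_class = mass_class_for(self.body_mass_kg)
        if self.mass_class is None:
            self.mass_class = expected_class
        elif self.mass_class != expected_class:
            raise ValueError(
                f"{self.species_id}: mass_class {self.mass_class!r} inconsistent with "
                f"{self.body_mass_kg} kg (expected {expected_class!r})"
            )
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        if self.habit not in HABITS:
            raise ValueError(f"unknown habit {self.habit!r}")
        if self.speed_class is not None and self.speed_class not in SPEED_CLASSES:
            raise ValueError(f"unknown speed class {self.speed_class!r}")
        if self.forelimb is None and self.hindlimb is None:
            raise ValueError(f"{self.species_id}: at least one limb must be present")

    def limb(self, which: str) -> Optional[LimbRecord]:
        return self.forelimb if which == "forelimb" else self.hindlimb


@dataclass
class AngularSummary:
    """Derived per-limb metrics: JAE per joint, their sum, TAE, AUI%, relative JAE."""

    limb: str
    jae_per_joint: Mapping[str, Optional[float]]
    sum_jae: Optional[float]
    tae: Optional[float]
    aui_pct: Optional[float]
    relative_jae_pct: Mapping[str, Optional[float]]
    missing_joints: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def joint_angle(p_proximal, p_joint, p_distal) -> float:
    """Interior angle at ``p_joint`` (degrees, in [0, 180]).

    The angle between the joint->proximal and joint->distal rays, via the
    arccosine of the normalized dot product.
    """
    a = np.asarray(p_proximal, dtype=float) - np.asarray(p_joint, dtype=float)
    b = np.asarray(p_distal, dtype=float) - np.asarray(p_joint, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("coincident points: joint angle undefined")
    cosang = float(np.dot(a, b) / (na * nb))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def segment_angle(contact_point, pivot_point, travel_sign: float = 1.0) -> float:
    """Signed angle (degrees) of the contact->pivot vector from the vertical.

    Measured from the vertical axis through the contact point, positive toward
    the direction of travel. ``travel_sign`` is +1 when the animal travels
    toward +x, -1 toward -x. Coordinates are mathematical y-up.
    """
    c = np.asarray(contact_point, dtype=float)
    p = np.asarray(pivot_point, dtype=float)
    d = p - c
    if np.linalg.norm(d) == 0.0:
        raise DegenerateGeometryError("coincident points: segment angle undefined")
    return math.degrees(math.atan2(travel_sign * d[0], d[1]))


# ---------------------------------------------------------------------------
# excursion metrics
# ---------------------------------------------------------------------------

def jae(pose: JointPose) -> float:
    """Joint angular excursion: max - min angle over the present stance events."""
    angles = pose.present_angles
    if len(angles) < 2:
        raise InsufficientDataError(
            f"{pose.joint_name}: JAE needs at least two of TD/MS/TO, "
            f"got {len(angles)}"
        )
    return max(angles) - min(angles)


def tae(limb: LimbRecord, use_midstance: bool = False) -> float:
    """Total angular excursion of the functional limb segment, degrees.

    By default the absolute TD-to-TO sweep, |seg_to - seg_td| (net limb sweep
    during stance is monotonic). With ``use_midstance`` the max - min of all
    available segment angles, should MS ever be an extremum.
    """
    if limb.seg_angle_td is None or limb.seg_angle_to is None:
        raise InsufficientDataError(f"{limb.limb}: TAE needs segment angles at TD and TO")
    if use_midstance and limb.seg_angle_ms is not None:
        angles = [limb.seg_angle_td, limb.seg_angle_ms, limb.seg_angle_to]
        return max(angles) - min(angles)
    return abs(limb.seg_angle_to - limb.seg_angle_td)


def aui(tae_val: float, sum_jae: float) -> float:
    """Angular utilization index, percent: 100 * TAE / sum(JAE)."""
    if sum_jae <= 0:
        raise UndefinedIndexError(f"AUI undefined for sum_jae = {sum_jae}")
    if tae_val < 0:
        raise ValueError("TAE must be non-negative")
    return 100.0 * tae_val / sum_jae


def relative_jae(jae_per_joint: Mapping[str, Optional[float]]) -> dict[str, Optional[float]]:
    """Each joint's JAE as a percentage of the limb's summed JAE.

    Joints with missing JAE get a missing share; present shares sum to 100.
    """
    present = {j: v for j, v in jae_per_joint.items() if v is not None}
    total = sum(present.values())
    if total <= 0:
        raise UndefinedIndexError(f"relative JAE undefined for sum_jae = {total}")
    return {
        j: (100.0 * v / total if v is not None else None)
        for j, v in jae_per_joint.items()
    }


def summarize_limb(limb: LimbRecord, use_midstance: bool = False) -> AngularSummary:
    """Compose JAE, sum(JAE), TAE, AUI% and relative JAE for one limb.

    Joints whose JAE cannot be computed (fewer than two events) are excluded
    from the sum and flagged in ``missing_joints``. TAE and AUI% are missing
    when their inputs are.
    """
    jae_per_joint: dict[str, Optional[float]] = {}
    missing = []
    for p in limb.poses:
        try:
            jae_per_joint[p.joint_name] = jae(p)
        except InsufficientDataError:
            jae_per_joint[p.joint_name] = None
            missing.append(p.joint_name)

    present = [v for v in jae_per_joint.values() if v is not None]
    sum_jae = sum(present) if present else None

    try:
        tae_val: Optional[float] = tae(limb, use_midstance=use_midstance)
    except InsufficientDataError:
        tae_val = None

    aui_pct: Optional[float] = None
    if tae_val is not None and sum_jae is not None and sum_jae > 0:
        aui_pct = aui(tae_val, sum_jae)

    rel: dict[str, Optional[float]]
    if sum_jae is not None and sum_jae > 0:
        rel = relative_jae(jae_per_joint)
    else:
        rel = {j: None for j in jae_per_joint}

    return AngularSummary(
        limb=limb.limb,
        jae_per_joint=jae_per_joint,
        sum_jae=sum_jae,
        tae=tae_val,
        aui_pct=aui_pct,
        relative_jae_pct=rel,
        missing_joints=tuple(missing),
    )


# ---------------------------------------------------------------------------
# landmark extraction
# ---------------------------------------------------------------------------

#: marker roles required per limb, proximal to distal; the first is the
#: trunk reference used only to define the angle at the most proximal joint.
LIMB_ROLES = {
    "forelimb": ("trunk", "shoulder", "elbow", "wrist", "contact"),
    "hindlimb": ("trunk", "hip", "knee", "ankle", "contact"),
}


def extract_poses_from_landmarks(
    track: pd.DataFrame,
    events: Mapping[str, int],
    marker_map: Mapping[str, str],
    limb: str,
    travel_sign: float = 1.0,
    y_down: bool = False,
) -> LimbRecord:
    """Build a :class:`LimbRecord` from digitized landmark coordinates.

    Parameters
    ----------
    track
        Long-format table with columns ``frame, marker, x, y``.
    events
        Mapping of stance-event name (``td``/``ms``/``to``, case-insensitive)
        to frame index.
    marker_map
        Mapping from marker names in ``track`` to the limb roles in
        :data:`LIMB_ROLES` (trunk, shoulder/hip, elbow/knee, wrist/ankle,
        contact).
    limb
        ``"forelimb"`` or ``"hindlimb"``.
    travel_sign
        +1 if the animal moves toward +x, -1 toward -x.
    y_down
        Set for image-style coordinates (y increasing downward); the y axis
        is flipped so geometry is computed in mathematical y-up.
    """
    roles = LIMB_ROLES[limb]
    role_to_marker = {role: m for m, role in marker_map.items()}
    missing_roles = [r for r in roles if r not in role_to_marker]
    if missing_roles:
        raise ValueError(f"marker_map lacks roles: {missing_roles}")

    ev = {str(k).lower(): int(v) for k, v in events.items()}
    unknown = set(ev) - set(EVENTS)
    if unknown:
        raise ValueError(f"unknown events: {sorted(unknown)}")

    def point(role: str, frame: int) -> np.ndarray:
        marker = role_to_marker[role]
        rows = track[(track["frame"] == frame) & (track["marker"] == marker)]
        if rows.empty:
            raise MissingLandmarkError(marker, frame)
        x = float(rows.iloc[0]["x"])
        y = float(rows.iloc[0]["y"])
        return np.array([x, -y if y_down else y])

    joint_names = roles[1:4]
    angles: dict[str, dict[str, Optional[float]]] = {j: {} for j in joint_names}
    for event in EVENTS:
        if event not in ev:
            for j in joint_names:
                angles[j][event] = None
            continue
        frame = ev[event]
        pts = {role: point(role, frame) for role in roles}
        chain = [pts[r] for r in roles]
        for i, j in enumerate(joint_names, start=1):
            angles[j][event] = joint_angle(chain[i - 1], chain[i], chain[i + 1])

    poses = [
        JointPose(j, angle_td=angles[j]["td"], angle_ms=angles[j]["ms"], angle_to=angles[j]["to"])
        for j in joint_names
    ]

    seg: dict[str, Optional[float]] = {}
    pivot_role = roles[1]  # shoulder or hip
    for event in ("td", "to", "ms"):
        if event in ev:
            frame = ev[event]
            seg[event] = segment_angle(
                point("contact", frame), point(pivot_role, frame), travel_sign=travel_sign
            )
        else:
            seg[event] = None

    return LimbRecord(
        limb=limb,
        poses=poses,
        seg_angle_td=seg["td"],
        seg_angle_to=seg["to"],
        seg_angle_ms=seg["ms"],
    )
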