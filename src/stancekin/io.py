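"""Reading and writing the species angle table and landmark files.

The species table is a UTF-8 CSV, one row per species, with columns
``species, order, body_mass_kg, posture, mass_class, speed_class, habit``,
then per-limb event angles ``{fore|hind}_{joint}_{td|ms|to}`` (degrees),
segment angles ``{fore|hind}_seg_{td|to}`` and optional ``stride_length``.
Empty cells are missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import StanceKinError
from .kinematics import (
    FORELIMB_JOINTS,
    HINDLIMB_JOINTS,
    JointPose,
    LimbRecord,
    SpeciesRecord,
)

log = logging.getLogger(__name__)

FACTOR_COLUMNS = ("posture", "mass_class", "speed_class", "habit")
REQUIRED_COLUMNS = ("species", "order", "body_mass_kg", "posture", "habit")

LIMB_PREFIX = {"forelimb": "fore", "hindlimb": "hind"}


def angle_columns() -> list[str]:
    cols = []
    for limb, joints in (("fore", FORELIMB_JOINTS), ("hind", HINDLIMB_JOINTS)):
        for joint in joints:
            for ev in ("td", "ms", "to"):
                cols.append(f"{limb}_{joint}_{ev}")
        cols += [f"{limb}_seg_td", f"{limb}_seg_to"]
    return cols


def _opt(row, col) -> Optional[float]:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _limb_from_row(row: pd.Series, limb: str) -> Optional[LimbRecord]:
    prefix = LIMB_PREFIX[limb]
    joints = FORELIMB_JOINTS if limb == "forelimb" else HINDLIMB_JOINTS
    cols = [f"{prefix}_{j}_{ev}" for j in joints for ev in ("td", "ms", "to")]
    cols += [f"{prefix}_seg_td", f"{prefix}_seg_to"]
    if all(_opt(row, c) is None for c in cols):
        return None
    poses = [
        JointPose(
            j,
            angle_td=_opt(row, f"{prefix}_{j}_td"),
            angle_ms=_opt(row, f"{prefix}_{j}_ms"),
            angle_to=_opt(row, f"{prefix}_{j}_to"),
        )
        for j in joints
    ]
    return LimbRecord(
        limb=limb,
        poses=poses,
        seg_angle_td=_opt(row, f"{prefix}_seg_td"),
        seg_angle_to=_opt(row, f"{prefix}_seg_to"),
    )


def records_from_dataframe(
    df: pd.DataFrame,
) -> tuple[list[SpeciesRecord], list[dict]]:
    """Build species records from a schema-valid table.

    Returns the records plus an exclusion list of ``{species, stage, reason}``
    dicts for rows that could not be parsed.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise StanceKinError(f"species table missing columns: {missing_cols}")
    records, exclusions = [], []
    for _, row in df.iterrows():
        sp = str(row["species"])
        try:
            rec = SpeciesRecord(
                species_id=sp,
                order_name=str(row["order"]),
                body_mass_kg=float(row["body_mass_kg"]),
                posture=str(row["posture"]),
                habit=str(row["habit"]),
                mass_class=(
                    str(row["mass_class"])
                    if "mass_class" in row and pd.notna(row["mass_class"])
                    else None
                ),
                speed_class=(
                    str(row["speed_class"])
                    if "speed_class" in row and pd.notna(row["speed_class"])
                    else None
                ),
                forelimb=_limb_from_row(row, "forelimb"),
                hindlimb=_limb_from_row(row, "hindlimb"),
                stride_length=_opt(row, "stride_length"),
            )
            records.append(rec)
        except (ValueError, StanceKinError) as exc:
            exclusions.append({"species": sp, "stage": "input", "reason": str(exc)})
            log.warning("excluding %s: %s", sp, exc)
    return records, exclusions


def read_species_table(path: str | Path) -> tuple[list[SpeciesRecord], list[dict]]:
    df = pd.read_csv(path)
    return records_from_dataframe(df)


def read_landmarks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"frame", "marker", "x", "y"}
    if not expected.issubset(df.columns):
        raise StanceKinError(f"landmark file must have columns {sorted(expected)}")
    return df


def read_events(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    if not {"event", "frame"}.issubset(df.columns):
        raise StanceKinError("event file must have columns event,frame")
    return {str(r["event"]).lower(): int(r["frame"]) for _, r in df.iterrows()}


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV deterministically (fixed float formatting, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
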