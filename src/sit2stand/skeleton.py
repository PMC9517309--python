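"""Skeletal frame data model and delimited-text I/O.

A depth sensor tracks 25 named body landmarks per frame in a camera-fixed
right-handed coordinate system: origin at the sensor, ``x`` lateral (to the
subject's left as seen by the camera), ``y`` vertical up, ``z`` along the view
direction.  Coordinates are stored in meters; anthropometric body measures are
stored in millimeters (the unit furniture dimensions are quoted in), and the
two unit conventions meet only at explicit type boundaries.

Frames with missing joints are rejected rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The 25 tracked skeletal key points, in canonical (file-schema) order.
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "spine_shoulder",
    "shoulder_left",
    "shoulder_right",
    "spine_mid",
    "elbow_left",
    "elbow_right",
    "spine_base",
    "hip_left",
    "hip_right",
    "wrist_left",
    "wrist_right",
    "hand_left",
    "hand_right",
    "thumb_left",
    "thumb_right",
    "hand_tip_left",
    "hand_tip_right",
    "knee_left",
    "knee_right",
    "ankle_left",
    "ankle_right",
    "foot_left",
    "foot_right",
)

N_JOINTS = len(JOINT_NAMES)

COHORTS = ("elderly", "control")

#: Standing (L1..L14) and sitting (Z1..Z14) anthropometric measure codes.
STANDING_MEASURES: tuple[str, ...] = tuple(f"L{i}" for i in range(1, 15))
SITTING_MEASURES: tuple[str, ...] = tuple(f"Z{i}" for i in range(1, 15))


class SkeletonFormatError(ValueError):
    """A motion file does not conform to the published column schema."""


class SkeletonParseError(ValueError):
    """A motion file contains a cell that cannot be parsed as a number."""


def _as_point(value) -> np.ndarray:
    p = np.asarray(value, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"a 3D coordinate is required, got shape {p.shape}")
    return p


@dataclass
class SkeletonFrame:
    """Positions of all 25 joints at one timestamp.

    Parameters
    ----------
    timestamp : float
        Seconds since the start of the recording (non-negative, finite).
    positions : mapping
        Joint name -> length-3 coordinate in meters (camera frame).
    """

    timestamp: float
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = {k: _as_point(v) for k, v in self.positions.items()}

    def violations(self) -> list[str]:
        """Invariant violations of this frame (empty list iff valid)."""
        report: list[str] = []
        if not math.isfinite(self.timestamp):
            report.append("timestamp is not finite")
        elif self.timestamp < 0:
            report.append("timestamp is negative")
        for joint in JOINT_NAMES:
            if joint not in self.positions:
                report.append(f"missing joint: {joint}")
            elif not np.all(np.isfinite(self.positions[joint])):
                report.append(f"non-finite coordinate for joint: {joint}")
        for joint in self.positions:
            if joint not in JOINT_NAMES:
                report.append(f"unknown joint: {joint}")
        return report

    def __getitem__(self, joint: str) -> np.ndarray:
        return self.positions[joint]


def validate_frame(frame: SkeletonFrame) -> list[str]:
    """Report invariant violations of ``frame``; an empty report means valid."""
    return frame.violations()


@dataclass
class MotionSequence:
    """An ordered recording of skeletal frames for one subject."""

    subject_id: str
    cohort: str
    frames: list[SkeletonFrame]

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if len(self.frames) < 1:
            raise ValueError("a motion sequence requires at least one frame")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def motion_columns() -> list[str]:
    """The fixed published motion-file schema: timestamp then 25 x/y/z triples."""
    cols = ["timestamp"]
    for joint in JOINT_NAMES:
        cols += [f"{joint}_x", f"{joint}_y", f"{joint}_z"]
    return cols


def write_motion(seq: MotionSequence, path) -> Path:
    """Write a sequence as CSV (UTF-8, 6-decimal fixed point, fixed column order).

    Two writes of the same sequence are byte-identical.
    """
    path = Path(path)
    bad = [v for f in seq.frames for v in f.violations()]
    if bad:
        raise ValueError(f"sequence fails validation: {bad[:5]}")
    rows = []
    for frame in seq.frames:
        row = [frame.timestamp]
        for joint in JOINT_NAMES:
            row.extend(frame.positions[joint])
        rows.append(row)
    df = pd.DataFrame(rows, columns=motion_columns())
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_motion(path, subject_id: str | None = None, cohort: str = "elderly") -> MotionSequence:
    """Read a motion CSV written to the published schema.

    The file does not carry subject metadata; ``subject_id`` defaults to the
    file stem and ``cohort`` must be supplied by the caller (defaults to
    ``elderly``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    expected = motion_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SkeletonFormatError(f"missing column(s): {', '.join(missing)}")
    values = np.empty((len(df), len(expected)))
    for j, col in enumerate(expected):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(df[col].index[df[col].isna()])
        if len(bad):
            raise SkeletonParseError(
                f"non-numeric value in column {col!r} at data row {int(bad[0])}"
            )
        values[:, j] = parsed.to_numpy()
    frames = []
    for row in values:
        positions = {
            joint: row[1 + 3 * i: 4 + 3 * i] for i, joint in enumerate(JOINT_NAMES)
        }
        frames.append(SkeletonFrame(timestamp=float(row[0]), positions=positions))
    return MotionSequence(
        subject_id=subject_id or path.stem, cohort=cohort, frames=frames
    )


@dataclass
class Anthropometry:
    """Standing (L1–L14) and sitting (Z1–Z14) body measures in millimeters.

    Catalogue (standing): L1 height, L2 upper-arm length, L3 forearm length,
    L4 greater trochanteric height, L5 lower-leg length, L6 eye height,
    L7 shoulder height, L8 elbow height, L9 hand functional height,
    L10 bilateral arm functional supination height, L11 tibial point height,
    L12 bilateral arm functional spread width, L13 bilateral elbow spread
    width, L14 maximum body width.

    Catalogue (sitting): Z1 sitting height, Z2 sitting shoulder height,
    Z3 sitting depth, Z4 sitting thigh thickness, Z5 sitting knee height,
    Z6 sitting eye height, Z7 calf-plus-foot height, Z8 forearm-plus-hand
    functional forward reach, Z9 sitting lower-limb length, Z10 sitting
    external occipital ridge height, Z11 sitting elbow height, Z12 sitting
    upper-limb functional forward reach, Z13 bilateral inter-elbow width,
    Z14 sitting hip width.
    """

    standing: dict[str, float]
    sitting: dict[str, float]

    def __post_init__(self) -> None:
        missing = [m for m in STANDING_MEASURES if m not in self.standing]
        missing += [m for m in SITTING_MEASURES if m not in self.sitting]
        if missing:
            raise ValueError(f"missing anthropometric measure(s): {missing}")
        for name, table in (("standing", self.standing), ("sitting", self.sitting)):
            for k, v in table.items():
                if not (math.isfinite(v) and v > 0):
                    raise ValueError(f"{name} measure {k} must be positive, got {v}")
        if not self.standing["L4"] < self.standing["L1"]:
            raise ValueError("L4 (trochanteric height) must be below L1 (stature)")
        if not self.sitting["Z5"] < self.sitting["Z1"] + self.sitting["Z9"]:
            raise ValueError("Z5 (sitting knee height) inconsistent with Z1 + Z9")

    def __getitem__(self, code: str) -> float:
        if code.startswith("L"):
            return self.standing[code]
        return self.sitting[code]

    def thigh_length(self) -> float:
        """Thigh length (mm) used by the seat geometry: Z9 − Z7.

        Sitting lower-limb length minus calf-plus-foot height; configurable
        at call sites that accept an explicit thigh length.
        """
        return self.sitting["Z9"] - self.sitting["Z7"]


def anthropometry_columns() -> list[str]:
    return ["subject_id", "cohort", *STANDING_MEASURES, *SITTING_MEASURES]


def write_anthropometry(
    records: Iterable[tuple[str, str, Anthropometry]], path
) -> Path:
    """Write ``(subject_id, cohort, Anthropometry)`` records as CSV in mm."""
    path = Path(path)
    rows = []
    for subject_id, cohort, anthro in records:
        row = {"subject_id": subject_id, "cohort": cohort}
        row.update(anthro.standing)
        row.update(anthro.sitting)
        rows.append(row)
    pd.DataFrame(rows, columns=anthropometry_columns()).to_csv(
        path, index=False, float_format="%.1f"
    )
    return path


def read_anthropometry(path) -> list[tuple[str, str, Anthropometry]]:
    """Read the anthropometry CSV schema back into typed records."""
    df = pd.read_csv(path)
    missing = [c for c in anthropometry_columns() if c not in df.columns]
    if missing:
        raise SkeletonFormatError(f"missing column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        anthro = Anthropometry(
            standing={m: float(row[m]) for m in STANDING_MEASURES},
            sitting={m: float(row[m]) for m in SITTING_MEASURES},
        )
        out.append((str(row["subject_id"]), str(row["cohort"]), anthro))
    return out
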