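"""Joint-angle extraction from skeletal key points, and seat-surface geometry.

The 25 tracked landmarks are reduced to 12 named joint angles, each either

* a *three-point* angle at a vertex joint between two bone vectors
  (``theta = arccos(AB.AO / |AB||AO|)``, vertex ``A``), or
* a *segment-vs-reference* angle between one bone vector (optionally
  projected onto the sagittal plane) and a fixed reference direction.

Reference directions in the camera frame: gravity ``(0, -1, 0)``,
anti-gravity ``(0, 1, 0)``, forward-horizontal ``(0, 0, 1)``.  The sagittal
plane is taken as the camera's y–z plane (the lateral ``x`` component is
dropped), which assumes the subject faces the sensor.

All angles are unsigned and lie in [0°, 180°].  The seat-surface relation
``theta5 = 90° − arctan(y/x)`` links seat height ``y`` to thigh length ``x``
with the knee as the pivot of the sit-to-stand arc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .skeleton import JOINT_NAMES, SkeletonFrame, MotionSequence

#: The 12 angle identifiers, in presentation order.  The ``_1`` / ``_2``
#: suffixes denote the left and right limb respectively.
ANGLE_IDS: tuple[str, ...] = (
    "theta1",
    "theta2_1",
    "theta2_2",
    "theta3_1",
    "theta3_2",
    "theta4",
    "theta5_1",
    "theta5_2",
    "theta6_1",
    "theta6_2",
    "theta7_1",
    "theta7_2",
)

#: Human-readable names matching the threshold-table presentation.
ANGLE_LABELS: dict[str, str] = {
    "theta1": "neck bending angle θ1",
    "theta2_1": "torso arm angle θ2-1",
    "theta2_2": "torso arm angle θ2-2",
    "theta3_1": "elbow bending angle θ3-1",
    "theta3_2": "elbow bending angle θ3-2",
    "theta4": "torso bending angle θ4",
    "theta5_1": "torso thigh angle θ5-1",
    "theta5_2": "torso thigh angle θ5-2",
    "theta6_1": "thigh calf angle θ6-1",
    "theta6_2": "thigh calf angle θ6-2",
    "theta7_1": "calf ground angle θ7-1",
    "theta7_2": "calf ground angle θ7-2",
}

REFERENCES: dict[str, np.ndarray] = {
    "gravity": np.array([0.0, -1.0, 0.0]),
    "anti_gravity": np.array([0.0, 1.0, 0.0]),
    "forward_horizontal": np.array([0.0, 0.0, 1.0]),
}

_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """A bone vector (or its sagittal projection) has zero length."""


@dataclass(frozen=True)
class AngleDefinition:
    """How one named angle is computed from joint positions.

    ``mode`` is ``"three_point"`` (joints = vertex, end1, end2) or
    ``"segment_reference"`` (joints = from, to; ``reference`` names the fixed
    direction; ``sagittal`` projects the segment onto the y–z plane first).
    """

    angle_id: str
    mode: str
    joints: tuple[str, ...]
    reference: str | None = None
    sagittal: bool = False

    def __post_init__(self) -> None:
        if self.mode == "three_point":
            if len(self.joints) != 3:
                raise ValueError(f"{self.angle_id}: three-point mode needs 3 joints")
        elif self.mode == "segment_reference":
            if len(self.joints) != 2:
                raise ValueError(f"{self.angle_id}: segment mode needs 2 joints")
            if self.reference not in REFERENCES:
                raise ValueError(
                    f"{self.angle_id}: unknown reference {self.reference!r}"
                )
        else:
            raise ValueError(f"{self.angle_id}: unknown mode {self.mode!r}")
        unknown = [j for j in self.joints if j not in JOINT_NAMES]
        if unknown:
            raise ValueError(f"{self.angle_id}: unknown joint(s) {unknown}")


@dataclass
class AngleVector:
    """The 12 joint angles (degrees) for one frame."""

    timestamp: float
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in ANGLE_IDS if a not in self.values]
        if missing:
            raise ValueError(f"missing angle value(s): {missing}")
        for k, v in self.values.items():
            if not (-1e-9 <= v <= 180 + 1e-9):
                raise ValueError(f"{k} = {v} outside [0, 180] degrees")

    def __getitem__(self, angle_id: str) -> float:
        return self.values[angle_id]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in ANGLE_IDS])


def default_definitions() -> dict[str, AngleDefinition]:
    """The shipped definition set for the 12 angles.

    Conventions (each overridable via :func:`definitions_from_config`):

    * theta1  — neck→head vs anti-gravity (0° when the head sits upright).
    * theta2  — shoulder→elbow, sagittal projection, vs gravity (0° when the
      arm hangs).
    * theta3  — three-point flexion at the elbow (shoulder–elbow–wrist);
      180° at full extension.
    * theta4  — neck→spine-base vs gravity (0° for an upright trunk).
    * theta5  — knee→hip, sagittal projection, vs gravity (180° standing,
      ~90° seated with a level thigh).
    * theta6  — three-point flexion at the knee (hip–knee–ankle).
    * theta7  — ankle→knee, sagittal projection, vs forward-horizontal
      (~90° for a vertical shin).
    """
    defs = {
        "theta1": AngleDefinition("theta1", "segment_reference", ("neck", "head"),
                                  reference="anti_gravity"),
        "theta4": AngleDefinition("theta4", "segment_reference",
                                  ("neck", "spine_base"), reference="gravity"),
    }
    for side, suffix in (("left", "1"), ("right", "2")):
        defs[f"theta2_{suffix}"] = AngleDefinition(
            f"theta2_{suffix}", "segment_reference",
            (f"shoulder_{side}", f"elbow_{side}"),
            reference="gravity", sagittal=True)
        defs[f"theta3_{suffix}"] = AngleDefinition(
            f"theta3_{suffix}", "three_point",
            (f"elbow_{side}", f"shoulder_{side}", f"wrist_{side}"))
        defs[f"theta5_{suffix}"] = AngleDefinition(
            f"theta5_{suffix}", "segment_reference",
            (f"knee_{side}", f"hip_{side}"),
            reference="gravity", sagittal=True)
        defs[f"theta6_{suffix}"] = AngleDefinition(
            f"theta6_{suffix}", "three_point",
            (f"knee_{side}", f"hip_{side}", f"ankle_{side}"))
        defs[f"theta7_{suffix}"] = AngleDefinition(
            f"theta7_{suffix}", "segment_reference",
            (f"ankle_{side}", f"knee_{side}"),
            reference="forward_horizontal", sagittal=True)
    return {a: defs[a] for a in ANGLE_IDS}


def definitions_from_config(overrides: dict | None) -> dict[str, AngleDefinition]:
    """Default definitions with per-angle overrides from a config mapping.

    ``overrides`` is keyed by angle id; each entry may set ``mode``,
    ``joints``, ``reference`` and ``sagittal`` (YAML/JSON friendly).
    """
    defs = default_definitions()
    for angle_id, spec in (overrides or {}).items():
        if angle_id not in defs:
            raise ValueError(f"unknown angle id {angle_id!r}")
        base = defs[angle_id]
        kwargs = {k: spec[k] for k in ("mode", "reference", "sagittal") if k in spec}
        if "joints" in spec:
            kwargs["joints"] = tuple(spec["joints"])
        defs[angle_id] = replace(base, **kwargs)
    return defs


def vector_angle(vertex, p1, p2) -> float:
    """Angle (degrees) at ``vertex`` between vectors vertex→p1 and vertex→p2."""
    vertex = np.asarray(vertex, float)
    u = np.asarray(p1, float) - vertex
    v = np.asarray(p2, float) - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError(
            "zero-length bone vector at the angle vertex"
        )
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def segment_reference_angle(a, b, reference, sagittal: bool = False) -> float:
    """Angle (degrees) between segment a→b and a reference direction.

    ``reference`` is a name from :data:`REFERENCES` or an explicit 3-vector.
    With ``sagittal=True`` the segment is first projected onto the y–z plane.
    """
    ref = REFERENCES[reference] if isinstance(reference, str) else np.asarray(
        reference, float)
    v = np.asarray(b, float) - np.asarray(a, float)
    if sagittal:
        v = v.copy()
        v[0] = 0.0
    nv = np.linalg.norm(v)
    nr = np.linalg.norm(ref)
    if nv < _EPS:
        raise DegenerateGeometryError(
            "segment collapses to zero length"
            + (" after sagittal projection" if sagittal else "")
        )
    c = np.clip(np.dot(v, ref) / (nv * nr), -1.0, 1.0)
    return math.degrees(math.acos(c))


def extract_angles(
    frame: SkeletonFrame, defs: dict[str, AngleDefinition] | None = None
) -> AngleVector:
    """Compute the 12 joint angles for one frame."""
    defs = defs or default_definitions()
    missing = [a for a in ANGLE_IDS if a not in defs]
    if missing:
        raise ValueError(f"definition set does not cover: {missing}")
    values: dict[str, float] = {}
    for angle_id in ANGLE_IDS:
        d = defs[angle_id]
        try:
            if d.mode == "three_point":
                vtx, p1, p2 = (frame[j] for j in d.joints)
                values[angle_id] = vector_angle(vtx, p1, p2)
            else:
                a, b = (frame[j] for j in d.joints)
                values[angle_id] = segment_reference_angle(
                    a, b, d.reference, d.sagittal)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"{angle_id} ({'/'.join(d.joints)}): {exc}"
            ) from None
    return AngleVector(timestamp=frame.timestamp, values=values)


def sequence_angles(
    seq: MotionSequence, defs: dict[str, AngleDefinition] | None = None
) -> pd.DataFrame:
    """Per-frame angle table for a sequence: timestamp + the 12 angle columns."""
    rows = [extract_angles(f, defs) for f in seq.frames]
    return angles_to_dataframe(rows)


def angles_to_dataframe(vectors: list[AngleVector]) -> pd.DataFrame:
    data = {"timestamp": [v.timestamp for v in vectors]}
    for a in ANGLE_IDS:
        data[a] = [v.values[a] for v in vectors]
    return pd.DataFrame(data)


def mirror_frame(frame: SkeletonFrame) -> SkeletonFrame:
    """Left/right mirror of a frame: negate x and swap paired joint labels."""
    positions = {}
    for joint, p in frame.positions.items():
        if joint.endswith("_left"):
            target = joint[:-5] + "_right"
        elif joint.endswith("_right"):
            target = joint[:-6] + "_left"
        else:
            target = joint
        q = p.copy()
        q[0] = -q[0]
        positions[target] = q
    return SkeletonFrame(timestamp=frame.timestamp, positions=positions)


# --- seat-surface geometry -------------------------------------------------

@dataclass(frozen=True)
class SeatGeometry:
    """Thigh length ``x`` and seat-surface height ``y`` (both mm)."""

    thigh_length: float
    seat_height: float

    def __post_init__(self) -> None:
        if not self.thigh_length > 0:
            raise ValueError("thigh length must be positive")
        if self.seat_height < 0:
            raise ValueError("seat height must be non-negative")


def seat_thigh_angle(thigh_length: float, seat_height: float) -> float:
    """Seated thigh angle theta5 = 90° − arctan(y/x), in (0°, 90°].

    ``thigh_length`` (x) and ``seat_height`` (y) in mm; the knee is the pivot
    of the sit-to-stand arc and the thigh its radius.
    """
    if thigh_length <= 0:
        raise ValueError("thigh length must be positive")
    if seat_height < 0:
        raise ValueError("seat height must be non-negative")
    return 90.0 - math.degrees(math.atan(seat_height / thigh_length))


def seat_height_for_angle(theta5: float, thigh_length: float) -> float:
    """Inverse seat geometry: the seat height (mm) realizing ``theta5``.

    ``theta5`` must lie in (0°, 90°]; returns ``x · tan(90° − theta5)``.
    """
    if not (0.0 < theta5 <= 90.0):
        raise ValueError("theta5 must lie in (0, 90] degrees")
    if thigh_length <= 0:
        raise ValueError("thigh length must be positive")
    return thigh_length * math.tan(math.radians(90.0 - theta5))
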