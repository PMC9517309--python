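"""Seat comfort model: mapping anthropometry and angle thresholds to seat
design parameters, and rating a concrete seat specification.

Ten furniture elements (backrest E1–E3, armrest F1–F2, seat surface G1–G4,
legs H1) are linked to a body measure and, where meaningful, to one of the
12 joint angles.  Elements with a geometric pathway from the seat dimension
to a joint angle are rated by whether the induced angle falls inside the
user's activity-threshold range; the remainder are rated by a dimensional
tolerance against the mapped body measure.

Seat-height geometry uses the seated-thigh relation
``theta5 = 90° − arctan(y/x)`` (thigh length x, seat height y, knee pivot).
Kinematic thigh/knee angle ranges (measured against gravity, ≈90–180° over a
sit-to-stand) are converted to this seated convention by subtracting 90°,
i.e. measuring thigh elevation from the seated horizontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .angles import ANGLE_IDS, seat_height_for_angle, seat_thigh_angle
from .behavior import ThresholdTable
from .skeleton import Anthropometry

ELEMENT_CODES = ("E1", "E2", "E3", "F1", "F2", "G1", "G2", "G3", "G4", "H1")


@dataclass(frozen=True)
class MappingEntry:
    code: str
    name: str
    body_value: str | None   # L/Z measure code
    angle_id: str | None


@dataclass
class ComfortMapping:
    """The element → body-measure → joint-angle mapping (10 rows)."""

    entries: list[MappingEntry]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("element codes must be unique")
        for e in self.entries:
            if e.angle_id is not None and e.angle_id not in ANGLE_IDS:
                raise ValueError(f"{e.code}: unknown angle id {e.angle_id!r}")

    def __getitem__(self, code: str) -> MappingEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(code)


def default_mapping() -> ComfortMapping:
    """The published 10-row element mapping.

    Shoulder width has no direct L/Z catalogue entry and is proxied by L14
    (maximum body width).  The elbow-angle links on F2/G1 are carried
    verbatim from the published table even though armrest spacing and seat
    width induce no elbow angle geometrically; those elements are rated
    dimensionally (see :func:`evaluate_seat`).
    """
    return ComfortMapping(entries=[
        MappingEntry("E1", "backrest inclination", "Z2", "theta1"),
        MappingEntry("E2", "backrest height", "Z2", "theta4"),
        MappingEntry("E3", "backrest width", "L14", None),
        MappingEntry("F1", "armrest height", "Z11", None),
        MappingEntry("F2", "armrest spacing", "Z13", "theta3_1"),
        MappingEntry("G1", "seat width", "Z14", "theta3_2"),
        MappingEntry("G2", "seat depth", "Z3", None),
        MappingEntry("G3", "seat height", "Z7", "theta5_1"),
        MappingEntry("G4", "seat inclination", "Z7", "theta5_2"),
        MappingEntry("H1", "chair leg height", "Z7", "theta6_1"),
    ])


@dataclass
class SeatSpec:
    """Concrete seat design parameters (lengths mm, inclinations degrees)."""

    backrest_inclination: float
    backrest_height: float
    backrest_width: float
    armrest_height: float
    armrest_spacing: float
    seat_width: float
    seat_depth: float
    seat_height: float
    seat_inclination: float
    chair_leg_height: float

    def __post_init__(self) -> None:
        for name in ("backrest_height", "backrest_width", "armrest_height",
                     "armrest_spacing", "seat_width", "seat_depth",
                     "seat_height", "chair_leg_height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("backrest_inclination", "seat_inclination"):
            v = getattr(self, name)
            if not (0.0 <= v < 90.0):
                raise ValueError(f"{name} must lie in [0, 90) degrees")

    _DIMENSIONS = {
        "E1": "backrest_inclination", "E2": "backrest_height",
        "E3": "backrest_width", "F1": "armrest_height",
        "F2": "armrest_spacing", "G1": "seat_width", "G2": "seat_depth",
        "G3": "seat_height", "G4": "seat_inclination",
        "H1": "chair_leg_height",
    }

    def dimension(self, code: str) -> float:
        return getattr(self, self._DIMENSIONS[code])


@dataclass
class ElementRating:
    code: str
    name: str
    rating: int
    induced_angle: float | None = None
    user_range: tuple[float, float] | None = None
    within_range: bool | None = None
    dimension: float | None = None
    body_reference: float | None = None


@dataclass
class ComfortReport:
    elements: dict[str, ElementRating]

    def __getitem__(self, code: str) -> ElementRating:
        return self.elements[code]

    def overall(self) -> float:
        return sum(e.rating for e in self.elements.values()) / len(self.elements)

    def summary(self) -> str:
        lines = ["Seat comfort report", "-" * 58,
                 f"{'code':<6}{'element':<22}{'rating':>7}  detail"]
        for code in ELEMENT_CODES:
            if code not in self.elements:
                continue
            e = self.elements[code]
            if e.induced_angle is not None:
                lo, hi = e.user_range
                detail = (f"angle {e.induced_angle:.1f} deg vs "
                          f"[{lo:.1f}, {hi:.1f}]")
            else:
                detail = (f"{e.dimension:.0f} mm vs body {e.body_reference:.0f} mm")
            lines.append(f"{e.code:<6}{e.name:<22}{e.rating:>7}  {detail}")
        lines.append(f"overall mean rating: {self.overall():.2f} / 5")
        return "\n".join(lines)


def kinematic_to_seated_band(kin_range: tuple[float, float]) -> tuple[float, float]:
    """Convert a kinematic thigh/knee angle range (vs gravity, ≈90–180°) to
    the seated-geometry convention: theta_seated = theta_kin − 90°, clipped
    to (0°, 90°]."""
    lo, hi = kin_range
    if lo > hi:
        raise ValueError("range must be ordered [lower, upper]")
    clip = lambda v: min(90.0, max(1e-6, v - 90.0))
    return (clip(lo), clip(hi))


def recommend_seat_height(
    anthro: Anthropometry,
    theta5_range: tuple[float, float],
    thigh_length: float | None = None,
) -> tuple[float, float]:
    """Seat-height interval (mm) realizing a seated thigh-angle comfort band.

    ``theta5_range`` is [lower, upper] in the seated convention (0°, 90°];
    the map ``y = x·tan(90° − theta5)`` is monotone decreasing in theta5, so
    the returned interval is [height(upper), height(lower)].  Thigh length
    defaults to the anthropometric Z9 − Z7.
    """
    lo, hi = theta5_range
    if lo > hi:
        raise ValueError("range must be ordered [lower, upper]")
    if not (0.0 < lo and hi <= 90.0):
        raise ValueError("theta5 range must lie within (0, 90] degrees")
    x = anthro.thigh_length() if thigh_length is None else thigh_length
    return (seat_height_for_angle(hi, x), seat_height_for_angle(lo, x))


def _angle_rating(angle: float, user_range: tuple[float, float]) -> int:
    """5 inside the range, −1 per started 25% of range-width outside, floor 1."""
    lo, hi = user_range
    if lo <= angle <= hi:
        return 5
    width = max(hi - lo, 1.0)  # 1-degree floor guards degenerate ranges
    dist = (lo - angle) if angle < lo else (angle - hi)
    return max(1, 5 - math.ceil(dist / (0.25 * width)))


def _dimension_rating(value: float, reference: float) -> int:
    """5 within ±10% of the body reference, −1 per further started 10%."""
    dev = abs(value - reference) / reference
    if dev <= 0.10:
        return 5
    return max(1, 5 - math.ceil((dev - 0.10) / 0.10))


def evaluate_seat(
    spec: SeatSpec,
    anthro: Anthropometry,
    thresholds: ThresholdTable,
    mapping: ComfortMapping | None = None,
    cohort: str = "elderly",
    thigh_length: float | None = None,
) -> ComfortReport:
    """Rate a seat specification against a user's activity thresholds.

    Geometric angle proxies (all other elements are rated dimensionally):

    * E1 — induced neck angle = backrest inclination.
    * E2 — induced trunk angle = arccos(min(h, Z2)/Z2): a backrest shorter
      than the sitting shoulder height forces a matching trunk recline.
    * G3 — induced seated thigh angle from seat height via the knee-pivot
      relation; compared to the theta5-1 band (converted to the seated
      convention).
    * G4 — as G3 with the seat inclination added (a tilted seat rotates the
      thigh with it); compared to the theta5-2 band.
    * H1 — shin analogue of G3: induced angle 90° − arctan(leg height / Z7)
      compared to the theta6-1 band.
    """
    mapping = mapping or default_mapping()
    x = anthro.thigh_length() if thigh_length is None else thigh_length
    table = thresholds.ranges.get(cohort)
    if table is None:
        raise ValueError(f"thresholds carry no cohort {cohort!r}")

    elements: dict[str, ElementRating] = {}
    for entry in mapping.entries:
        code = entry.code
        dim = spec.dimension(code)
        induced: float | None = None
        band: tuple[float, float] | None = None

        if code == "E1" and entry.angle_id:
            induced, band = spec.backrest_inclination, table.get(entry.angle_id)
        elif code == "E2" and entry.angle_id:
            z2 = anthro["Z2"]
            induced = math.degrees(math.acos(min(spec.backrest_height, z2) / z2))
            band = table.get(entry.angle_id)
        elif code == "G3" and entry.angle_id:
            induced = seat_thigh_angle(x, spec.seat_height)
            band = kinematic_to_seated_band(table[entry.angle_id]) \
                if entry.angle_id in table else None
        elif code == "G4" and entry.angle_id:
            induced = seat_thigh_angle(x, spec.seat_height) + spec.seat_inclination
            band = kinematic_to_seated_band(table[entry.angle_id]) \
                if entry.angle_id in table else None
        elif code == "H1" and entry.angle_id:
            z7 = anthro["Z7"]
            induced = 90.0 - math.degrees(math.atan(spec.chair_leg_height / z7))
            band = kinematic_to_seated_band(table[entry.angle_id]) \
                if entry.angle_id in table else None

        if induced is not None:
            if band is None:
                raise ValueError(
                    f"element {code} maps angle {entry.angle_id} but the "
                    f"threshold table has no {cohort!r} range for it")
            rating = _angle_rating(induced, band)
            elements[code] = ElementRating(
                code=code, name=entry.name, rating=rating,
                induced_angle=induced, user_range=band,
                within_range=band[0] <= induced <= band[1])
        else:
            ref = anthro[entry.body_value] if entry.body_value else dim
            rating = _dimension_rating(dim, ref)
            elements[code] = ElementRating(
                code=code, name=entry.name, rating=rating,
                dimension=dim, body_reference=ref)
    return ComfortReport(elements=elements)
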