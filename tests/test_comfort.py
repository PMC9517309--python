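import math

import pytest

from sit2stand import reference
from sit2stand.angles import seat_thigh_angle
from sit2stand.behavior import ThresholdTable
from sit2stand.comfort import (
    ComfortMapping,
    MappingEntry,
    SeatSpec,
    default_mapping,
    evaluate_seat,
    kinematic_to_seated_band,
    recommend_seat_height,
)


@pytest.fixture
def seat():
    return SeatSpec(backrest_inclination=10.0, backrest_height=560.0,
                    backrest_width=480.0, armrest_height=230.0,
                    armrest_spacing=460.0, seat_width=400.0, seat_depth=440.0,
                    seat_height=420.0, seat_inclination=3.0,
                    chair_leg_height=120.0)


@pytest.fixture
def thresholds():
    """Threshold table in the package's kinematic conventions, covering the
    angles the default mapping rates geometrically."""
    elderly = {
        "theta1": (4.0, 47.0),
        "theta4": (6.0, 34.0),
        "theta5_1": (95.0, 178.0),
        "theta5_2": (95.0, 178.0),
        "theta6_1": (95.0, 178.0),
    }
    return ThresholdTable(ranges={"elderly": elderly})


def test_default_mapping_shape():
    mapping = default_mapping()
    assert len(mapping.entries) == 10
    assert mapping["G4"].angle_id == "theta5_2"
    assert mapping["G3"].angle_id == "theta5_1"
    assert mapping["E3"].angle_id is None
    assert len({e.code for e in mapping.entries}) == 10


def test_duplicate_codes_rejected():
    e = MappingEntry("E1", "x", None, None)
    with pytest.raises(ValueError, match="unique"):
        ComfortMapping(entries=[e, e])


def test_recommend_seat_height_endpoints(elderly_anthro):
    lo, hi = recommend_seat_height(elderly_anthro, (45.0, 90.0),
                                   thigh_length=400.0)
    assert lo == pytest.approx(0.0, abs=1e-9)
    assert hi == pytest.approx(400.0, abs=1e-9)


def test_recommend_seat_height_degenerate(elderly_anthro):
    lo, hi = recommend_seat_height(elderly_anthro, (60.0, 60.0),
                                   thigh_length=450.0)
    assert lo == hi == pytest.approx(450 * math.tan(math.radians(30)), abs=1e-6)
    assert lo == pytest.approx(259.8, abs=0.1)


def test_recommend_rejects_bad_range(elderly_anthro):
    with pytest.raises(ValueError):
        recommend_seat_height(elderly_anthro, (80.0, 60.0))
    with pytest.raises(ValueError):
        recommend_seat_height(elderly_anthro, (0.0, 60.0))


def test_recommend_round_trips_through_geometry(elderly_anthro):
    band = (25.0, 70.0)
    x = elderly_anthro.thigh_length()
    lo, hi = recommend_seat_height(elderly_anthro, band)
    assert seat_thigh_angle(x, hi) == pytest.approx(band[0], abs=1e-9)
    assert seat_thigh_angle(x, lo) == pytest.approx(band[1], abs=1e-9)


def test_seat_height_at_band_midpoint_rates_5(seat, thresholds, elderly_anthro):
    band = kinematic_to_seated_band(thresholds.range("elderly", "theta5_1"))
    lo, hi = recommend_seat_height(elderly_anthro, band)
    seat.seat_height = 0.5 * (lo + hi)
    report = evaluate_seat(seat, elderly_anthro, thresholds)
    assert report["G3"].rating == 5
    assert report["G3"].within_range


def test_far_outside_band_rates_low(seat, elderly_anthro):
    """An induced thigh angle one full range-width below the band scores <= 2."""
    narrow = ThresholdTable(ranges={"elderly": {
        "theta1": (4.0, 47.0), "theta4": (6.0, 34.0),
        "theta5_1": (155.0, 175.0), "theta5_2": (95.0, 178.0),
        "theta6_1": (95.0, 178.0)}})
    band = kinematic_to_seated_band(narrow.range("elderly", "theta5_1"))
    width = band[1] - band[0]
    target_angle = band[0] - width  # still a valid seated angle
    x = elderly_anthro.thigh_length()
    seat.seat_height = x * math.tan(math.radians(90 - target_angle))
    report = evaluate_seat(seat, elderly_anthro, narrow)
    assert report["G3"].rating <= 2
    assert not report["G3"].within_range


def test_dimensional_rating_within_tolerance(seat, thresholds, elderly_anthro):
    seat.backrest_width = elderly_anthro["L14"] * 1.05  # within ±10%
    report = evaluate_seat(seat, elderly_anthro, thresholds)
    assert report["E3"].rating == 5
    seat.backrest_width = elderly_anthro["L14"] * 1.45
    report = evaluate_seat(seat, elderly_anthro, thresholds)
    assert report["E3"].rating < 5


def test_rating_monotone_toward_band_midpoint(seat, thresholds, elderly_anthro):
    """Moving the induced angle toward the band midpoint never lowers G3."""
    x = elderly_anthro.thigh_length()
    band = kinematic_to_seated_band(thresholds.range("elderly", "theta5_1"))
    mid = 0.5 * (band[0] + band[1])
    angles = [max(0.5, band[0] - 3 * (band[1] - band[0])) + f * 0.5
              for f in range(40)]
    angles = [a for a in angles if a <= mid]
    ratings = []
    for ang in sorted(angles):
        seat.seat_height = x * math.tan(math.radians(90 - ang))
        ratings.append(evaluate_seat(seat, elderly_anthro, thresholds)["G3"].rating)
    assert all(b >= a for a, b in zip(ratings, ratings[1:]))
    assert all(1 <= r <= 5 for r in ratings)


def test_missing_threshold_names_element(seat, elderly_anthro):
    table = ThresholdTable(ranges={"elderly": {
        "theta1": (4.0, 47.0), "theta4": (6.0, 34.0),
        "theta5_2": (95.0, 178.0), "theta6_1": (95.0, 178.0)}})
    with pytest.raises(ValueError, match="G3"):
        evaluate_seat(seat, elderly_anthro, table)


def test_elderly_need_higher_minimum_seat_than_control(elderly_anthro):
    """On the published thigh-angle ranges the elderly comfort band maps to a
    strictly higher minimum seat height than the control band, for any fixed
    thigh length."""
    e_band = kinematic_to_seated_band(
        reference.PUBLISHED_THRESHOLDS["elderly"]["theta5_2"])
    c_band = kinematic_to_seated_band(
        reference.PUBLISHED_THRESHOLDS["control"]["theta5_2"])
    for x in (380.0, 430.0, 480.0):
        e_lo, _ = recommend_seat_height(elderly_anthro, e_band, thigh_length=x)
        c_lo, _ = recommend_seat_height(elderly_anthro, c_band, thigh_length=x)
        assert e_lo > c_lo


def test_seat_spec_validation():
    with pytest.raises(ValueError, match="seat_height"):
        SeatSpec(backrest_inclination=5, backrest_height=500,
                 backrest_width=450, armrest_height=200, armrest_spacing=500,
                 seat_width=500, seat_depth=420, seat_height=0,
                 seat_inclination=3, chair_leg_height=100)
    with pytest.raises(ValueError, match="inclination"):
        SeatSpec(backrest_inclination=95, backrest_height=500,
                 backrest_width=450, armrest_height=200, armrest_spacing=500,
                 seat_width=500, seat_depth=420, seat_height=400,
                 seat_inclination=3, chair_leg_height=100)
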