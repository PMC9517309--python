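"""Published reference values from the sofa-design study this package
operationalizes.

These constants are *inputs* (printed tables from the source study), not
outputs of this package: the AHP worked example (criterion feature vector and
its maximum eigenvalue), the questionnaire counts, the per-angle activity
threshold ranges observed for the elderly and young-control cohorts, and the
perceptron importance column for the 12 joint angles.  They anchor the worked
examples, the comfort-model direction checks, and regression tests.
"""

from __future__ import annotations

#: AHP criterion-layer worked example (function, shape, colour, material).
CRITERIA = ("B1 function", "B2 shape", "B3 colour", "B4 material")
FEATURE_VECTOR = (1.908, 0.609, 0.329, 1.154)
#: Printed weights (%); only B1 reproduces exactly from the printed vector.
PRINTED_WEIGHTS = (47.700, 15.223, 8.232, 28.845)
LAMBDA_MAX = 4.067
MATRIX_ORDER = 4

#: Questionnaire counts: sent, returned, valid.
SURVEY_COUNTS = (500, 457, 437)

#: Activity-threshold ranges (degrees) per cohort, published convention.
#: The elderly torso-bend range was printed with its bounds reversed and is
#: stored in ascending order.
PUBLISHED_THRESHOLDS: dict[str, dict[str, tuple[float, float]]] = {
    "elderly": {
        "theta1": (3.814, 47.489),
        "theta2_1": (89.643, 89.742),
        "theta2_2": (89.730, 89.742),
        "theta3_1": (74.931, 75.508),
        "theta3_2": (76.759, 91.324),
        "theta4": (131.583, 143.0),
        "theta5_1": (146.745, 179.969),
        "theta5_2": (115.049, 179.456),
        "theta6_1": (130.672, 154.731),
        "theta6_2": (115.049, 179.849),
        "theta7_1": (83.659, 96.340),
        "theta7_2": (81.869, 108.435),
    },
    "control": {
        "theta1": (3.814, 47.489),
        "theta2_1": (89.815, 89.900),
        "theta2_2": (89.820, 89.895),
        "theta3_1": (79.695, 179.774),
        "theta3_2": (89.454, 179.496),
        "theta4": (136.789, 179.334),
        "theta5_1": (135.553, 179.976),
        "theta5_2": (135.779, 179.951),
        "theta6_1": (68.036, 179.754),
        "theta6_2": (75.134, 179.864),
        "theta7_1": (91.975, 112.166),
        "theta7_2": (83.991, 111.448),
    },
}

#: Perceptron importance index per angle (fractions; the column sums to 1.000)
#: and the printed normalized importance (% of the maximum).
PUBLISHED_IMPORTANCE: dict[str, float] = {
    "theta1": 0.112,
    "theta2_1": 0.096,
    "theta2_2": 0.076,
    "theta3_1": 0.090,
    "theta3_2": 0.111,
    "theta4": 0.096,
    "theta5_1": 0.053,
    "theta5_2": 0.122,
    "theta6_1": 0.090,
    "theta6_2": 0.048,
    "theta7_1": 0.076,
    "theta7_2": 0.030,
}
PUBLISHED_NORMALIZED_IMPORTANCE: dict[str, float] = {
    "theta1": 92.1,
    "theta2_1": 78.6,
    "theta2_2": 62.2,
    "theta3_1": 73.7,
    "theta3_2": 91.2,
    "theta4": 78.4,
    "theta5_1": 43.6,
    "theta5_2": 100.0,
    "theta6_1": 73.8,
    "theta6_2": 39.6,
    "theta7_1": 61.9,
    "theta7_2": 24.4,
}

#: Study sample sizes: valid frames collected per cohort and the train/test
#: split used for the perceptron (elderly recordings).
FRAME_COUNTS = {"elderly": 4037, "control": 4746}
PERCEPTRON_SPLIT = (3027, 1010)

#: Prototype seat dimensions: overall W x D x H (mm), seat inclination (deg),
#: armrest spacing (mm).
PROTOTYPE_DIMENSIONS = (705, 985, 1205)
PROTOTYPE_SEAT_INCLINATION = 3.0
PROTOTYPE_ARMREST_SPACING = 545.0
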