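import numpy as np
import pytest

from sit2stand.skeleton import JOINT_NAMES, SkeletonFrame
from sit2stand.simulate import (
    CohortSpec,
    default_keyframes,
    mean_anthropometry,
    simulate_cohort,
    simulate_subject,
)

Z = 2.0  # distance of the synthetic subject from the sensor (m)


def upright_positions() -> dict[str, np.ndarray]:
    """A hand-built standing posture with known angles by construction:

    vertical spine and shins, hanging straight arms, upright head -> theta1 =
    theta2 = theta4 = 0, theta3 = theta5 = theta6 = 180, theta7 = 90.
    """
    P: dict[str, tuple] = {}
    for side, sx in (("left", 0.1), ("right", -0.1)):
        P[f"ankle_{side}"] = (sx, 0.08, Z)
        P[f"knee_{side}"] = (sx, 0.48, Z)
        P[f"hip_{side}"] = (sx, 0.90, Z)
        P[f"foot_{side}"] = (sx, 0.02, Z + 0.15)
    P["spine_base"] = (0.0, 0.90, Z)
    P["spine_mid"] = (0.0, 1.15, Z)
    P["spine_shoulder"] = (0.0, 1.38, Z)
    P["neck"] = (0.0, 1.45, Z)
    P["head"] = (0.0, 1.60, Z)
    for side, sx in (("left", 0.2), ("right", -0.2)):
        P[f"shoulder_{side}"] = (sx, 1.38, Z)
        P[f"elbow_{side}"] = (sx, 1.08, Z)
        P[f"wrist_{side}"] = (sx, 0.82, Z)
        P[f"hand_{side}"] = (sx, 0.74, Z)
        P[f"hand_tip_{side}"] = (sx, 0.70, Z)
        P[f"thumb_{side}"] = (sx, 0.76, Z + 0.03)
    assert set(P) == set(JOINT_NAMES)
    return {k: np.asarray(v, float) for k, v in P.items()}


@pytest.fixture
def upright_frame() -> SkeletonFrame:
    return SkeletonFrame(timestamp=0.0, positions=upright_positions())


@pytest.fixture
def seated_right_thigh_frame() -> SkeletonFrame:
    """Upright frame with the right thigh horizontal (hip level with knee),
    so theta5_2 = 90 by construction."""
    P = upright_positions()
    P["hip_right"] = P["knee_right"] + np.array([0.0, 0.0, -0.4])
    return SkeletonFrame(timestamp=0.0, positions=P)


@pytest.fixture(scope="session")
def elderly_anthro():
    return mean_anthropometry("elderly")


@pytest.fixture(scope="session")
def noise_free_subject(elderly_anthro):
    """One elderly subject, no noise, sampled densely (0.25 s)."""
    return simulate_subject(
        elderly_anthro, default_keyframes("elderly"),
        noise_sd=0.0, interval=0.25, seed=3, subject_id="nf", cohort="elderly",
    )


@pytest.fixture(scope="session")
def small_cohorts():
    """Three subjects per cohort, noise-free, densely sampled."""
    out = {}
    for cohort in ("elderly", "control"):
        spec = CohortSpec(n_subjects=3, cohort=cohort, coordinate_noise_sd=0.0,
                          sample_interval=0.25, seed=11)
        out[cohort] = [seq for _, seq in simulate_cohort(spec)]
    return out
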