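"""Seeded synthetic sit-to-stand skeletal trajectories.

The study's recordings are not deposited, so downstream stages are exercised
on simulated cohorts.  Each subject is a planar (sagittal-plane) kinematic
chain — ankle → knee → hip/spine-base → spine → neck → head, plus symmetric
arms — whose segment lengths come from the subject's anthropometry and whose
posture is driven by joint-angle targets at four stage keyframes:

    pre-rise → hip-raise → mid-rise → upright

Angles ease between consecutive keyframes with a cosine ramp, the chain is
placed in the camera's y–z plane with fixed lateral (x) offsets for paired
joints, and optional isotropic Gaussian noise is added per coordinate.
On a planar chain the knee flexion angle theta6 is implied by the thigh and
shin angles (cos theta6 = sin(theta5 + theta7)), so keyframes are validated
against that identity and theta6 is realized implicitly.

Defaults emulate the study conditions: 21 subjects per cohort, 1 s sampling,
5 mm coordinate noise, and keyframe targets whose extracted ranges differ
between cohorts in the published direction (the elderly torso-bend range is
strictly inside the control range; the elderly initial thigh angle is
larger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .skeleton import (
    Anthropometry,
    MotionSequence,
    SkeletonFrame,
    SITTING_MEASURES,
    STANDING_MEASURES,
)
from .angles import ANGLE_IDS

STAGES = ("pre_rise", "hip_raise", "mid_rise", "upright")

#: Angle ids the planar chain drives directly; theta6 is implied.
_DRIVEN = ("theta1", "theta2", "theta3", "theta4", "theta5", "theta7")


def implied_knee_angle(theta5: float, theta7: float) -> float:
    """Knee flexion theta6 implied by thigh (theta5) and shin (theta7) angles
    on a planar chain: cos(theta6) = sin(theta5 + theta7)."""
    s = math.sin(math.radians(theta5 + theta7))
    return math.degrees(math.acos(max(-1.0, min(1.0, s))))


@dataclass
class StageKeyframe:
    """Target joint angles (degrees) and dwell duration for one stage."""

    stage: str
    targets: dict[str, float]
    duration: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not self.duration > 0:
            raise ValueError("keyframe duration must be positive")
        missing = [a for a in ANGLE_IDS if a not in self.targets]
        if missing:
            raise ValueError(f"keyframe {self.stage}: missing target(s) {missing}")
        for a, v in self.targets.items():
            if not (0.0 <= v <= 180.0):
                raise ValueError(f"keyframe {self.stage}: {a}={v} outside [0, 180]")
        for suffix in ("1", "2"):
            implied = implied_knee_angle(
                self.targets[f"theta5_{suffix}"], self.targets[f"theta7_{suffix}"]
            )
            if abs(self.targets[f"theta6_{suffix}"] - implied) > 0.5:
                raise ValueError(
                    f"keyframe {self.stage}: theta6_{suffix}="
                    f"{self.targets[f'theta6_{suffix}']:.2f} inconsistent with the "
                    f"planar-chain value {implied:.2f} implied by theta5/theta7"
                )


def make_keyframe(
    stage: str,
    duration: float,
    theta1: float,
    theta2: float,
    theta3: float,
    theta4: float,
    theta5: float,
    theta7: float,
    right_offsets: dict[str, float] | None = None,
) -> StageKeyframe:
    """Build a symmetric keyframe from per-joint targets, filling theta6.

    ``right_offsets`` adds a per-angle offset (degrees) to the right-side
    targets to emulate left/right asymmetry.
    """
    off = right_offsets or {}
    targets: dict[str, float] = {"theta1": theta1, "theta4": theta4}
    for base, value in (("theta2", theta2), ("theta3", theta3),
                        ("theta5", theta5), ("theta7", theta7)):
        targets[f"{base}_1"] = value
        targets[f"{base}_2"] = value + off.get(base, 0.0)
    for suffix in ("1", "2"):
        targets[f"theta6_{suffix}"] = implied_knee_angle(
            targets[f"theta5_{suffix}"], targets[f"theta7_{suffix}"]
        )
    return StageKeyframe(stage=stage, targets=targets, duration=duration)


def default_keyframes(cohort: str) -> list[StageKeyframe]:
    """Default stage keyframes per cohort.

    Fixture parameters, not claims about the real cohorts: the elderly
    posture script is slower, keeps a narrower torso-bend excursion (strictly
    inside the control excursion) and starts with a larger thigh angle,
    matching the direction of the published group differences.
    """
    if cohort == "elderly":
        return [
            make_keyframe("pre_rise", 4.0, theta1=12, theta2=10, theta3=95,
                          theta4=18, theta5=96, theta7=85),
            make_keyframe("hip_raise", 3.0, theta1=30, theta2=20, theta3=80,
                          theta4=32, theta5=105, theta7=78),
            make_keyframe("mid_rise", 3.0, theta1=18, theta2=15, theta3=120,
                          theta4=22, theta5=145, theta7=84),
            make_keyframe("upright", 2.0, theta1=6, theta2=6, theta3=168,
                          theta4=8, theta5=176, theta7=88),
        ]
    if cohort == "control":
        return [
            make_keyframe("pre_rise", 2.5, theta1=8, theta2=8, theta3=100,
                          theta4=6, theta5=92, theta7=88),
            make_keyframe("hip_raise", 2.0, theta1=25, theta2=25, theta3=85,
                          theta4=42, theta5=100, theta7=75),
            make_keyframe("mid_rise", 2.0, theta1=15, theta2=18, theta3=130,
                          theta4=20, theta5=150, theta7=82),
            make_keyframe("upright", 1.5, theta1=4, theta2=5, theta3=175,
                          theta4=3, theta5=178, theta7=90),
        ]
    raise ValueError(f"unknown cohort {cohort!r}")


# Anthropometry distributions (mm): mean and sd per measure.  Elderly means
# reflect a ~1.62 m stature; the young control cohort is scaled ~5% taller.
_ELDERLY_MEANS = {
    "L1": 1620, "L2": 310, "L3": 240, "L4": 830, "L5": 390, "L6": 1505,
    "L7": 1330, "L8": 1010, "L9": 640, "L10": 1990, "L11": 440, "L12": 1610,
    "L13": 430, "L14": 450,
    "Z1": 855, "Z2": 570, "Z3": 440, "Z4": 130, "Z5": 480, "Z6": 745,
    "Z7": 390, "Z8": 340, "Z9": 820, "Z10": 240, "Z11": 230, "Z12": 800,
    "Z13": 450, "Z14": 380,
}


def default_anthropometry_distribution(cohort: str) -> dict[str, tuple[float, float]]:
    """Per-measure (mean, sd) in mm; sd is 3% of the mean."""
    scale = 1.0 if cohort == "elderly" else 1.05
    if cohort not in ("elderly", "control"):
        raise ValueError(f"unknown cohort {cohort!r}")
    return {k: (v * scale, 0.03 * v * scale) for k, v in _ELDERLY_MEANS.items()}


def mean_anthropometry(cohort: str = "elderly") -> Anthropometry:
    dist = default_anthropometry_distribution(cohort)
    return Anthropometry(
        standing={m: dist[m][0] for m in STANDING_MEASURES},
        sitting={m: dist[m][0] for m in SITTING_MEASURES},
    )


@dataclass
class CohortSpec:
    """Generation recipe for one simulated cohort."""

    n_subjects: int
    cohort: str
    anthropometry: dict[str, tuple[float, float]] | None = None
    keyframes: list[StageKeyframe] | None = None
    coordinate_noise_sd: float = 0.005  # meters
    sample_interval: float = 1.0  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.coordinate_noise_sd < 0:
            raise ValueError("coordinate noise sd must be >= 0")
        if not self.sample_interval > 0:
            raise ValueError("sample interval must be positive")
        if self.anthropometry is None:
            self.anthropometry = default_anthropometry_distribution(self.cohort)
        if self.keyframes is None:
            self.keyframes = default_keyframes(self.cohort)
        if len(self.keyframes) != 4:
            raise ValueError("exactly 4 stage keyframes are required")


def _segments(anthro: Anthropometry) -> dict[str, float]:
    """Kinematic-chain segment lengths in meters derived from anthropometry."""
    mm = 1e-3
    trunk = anthro["Z2"] * mm  # spine-base to neck
    return {
        "shank": anthro["L5"] * mm,
        "thigh": anthro.thigh_length() * mm,
        "trunk": trunk,
        "head": 0.14 * anthro["L1"] / 1700 * 1.0,
        "upper_arm": anthro["L2"] * mm,
        "forearm": anthro["L3"] * mm,
        "hand": 0.35 * anthro["L3"] * mm,
        "lat_leg": 0.5 * anthro["Z14"] * mm * 0.5,   # hip/knee/ankle x offset
        "lat_arm": 0.5 * anthro["L14"] * mm * 0.85,  # shoulder..hand x offset
        "foot": 0.15,
        "ankle_height": 0.08,
    }


def _rot_sagittal(v: np.ndarray, phi_deg: float) -> np.ndarray:
    """Rotate a y–z-plane vector forward (toward +z) by ``phi_deg``."""
    phi = math.radians(phi_deg)
    c, s = math.cos(phi), math.sin(phi)
    return np.array([0.0, v[1] * c + v[2] * s, -v[1] * s + v[2] * c])


def _pose(targets: dict[str, float], seg: dict[str, float]) -> dict[str, np.ndarray]:
    """Forward kinematics: joint positions (meters) from angle targets."""

    def sag(y: float, z: float) -> np.ndarray:
        return np.array([0.0, y, z])

    pos: dict[str, np.ndarray] = {}
    t1 = math.radians(targets["theta1"])
    t4 = math.radians(targets["theta4"])

    lat_leg, lat_arm = seg["lat_leg"], seg["lat_arm"]
    sides = {"left": ("1", +1.0), "right": ("2", -1.0)}

    # Trunk column first (x = 0); legs anchor it at the hip center below.
    trunk_dir = sag(math.cos(t4), math.sin(t4))

    hip_center = None
    leg_pts: dict[str, dict[str, np.ndarray]] = {}
    for side, (suffix, sgn) in sides.items():
        t5 = math.radians(targets[f"theta5_{suffix}"])
        t7 = math.radians(targets[f"theta7_{suffix}"])
        ankle = np.array([sgn * lat_leg, seg["ankle_height"], 0.0])
        knee = ankle + seg["shank"] * sag(math.sin(t7), math.cos(t7))
        hip = knee + seg["thigh"] * sag(-math.cos(t5), -math.sin(t5))
        foot = ankle + np.array([0.0, -0.05, seg["foot"]])
        leg_pts[side] = {"ankle": ankle, "knee": knee, "hip": hip, "foot": foot}
    hip_center = 0.5 * (leg_pts["left"]["hip"] + leg_pts["right"]["hip"])
    hip_center[0] = 0.0

    pos["spine_base"] = hip_center
    pos["spine_mid"] = hip_center + 0.5 * seg["trunk"] * trunk_dir
    pos["spine_shoulder"] = hip_center + 0.92 * seg["trunk"] * trunk_dir
    pos["neck"] = hip_center + seg["trunk"] * trunk_dir
    pos["head"] = pos["neck"] + seg["head"] * sag(math.cos(t1), math.sin(t1))

    for side, (suffix, sgn) in sides.items():
        lp = leg_pts[side]
        pos[f"ankle_{side}"] = lp["ankle"]
        pos[f"knee_{side}"] = lp["knee"]
        pos[f"foot_{side}"] = lp["foot"]
        hip = lp["hip"].copy()
        hip[0] = sgn * lat_leg
        pos[f"hip_{side}"] = hip

        t2 = math.radians(targets[f"theta2_{suffix}"])
        theta3 = targets[f"theta3_{suffix}"]
        shoulder = pos["spine_shoulder"] + np.array([sgn * lat_arm, 0.0, 0.0])
        upper_dir = sag(-math.cos(t2), math.sin(t2))
        elbow = shoulder + seg["upper_arm"] * upper_dir
        fore_dir = _rot_sagittal(upper_dir, 180.0 - theta3)
        wrist = elbow + seg["forearm"] * fore_dir
        hand = wrist + 0.4 * seg["hand"] * fore_dir
        pos[f"shoulder_{side}"] = shoulder
        pos[f"elbow_{side}"] = elbow
        pos[f"wrist_{side}"] = wrist
        pos[f"hand_{side}"] = hand
        pos[f"hand_tip_{side}"] = wrist + seg["hand"] * fore_dir
        pos[f"thumb_{side}"] = hand + np.array([0.0, 0.01, 0.02])

    # place the whole body ~2 m in front of the sensor
    for k in pos:
        pos[k] = pos[k] + np.array([0.0, -0.6, 2.0])
    return pos


def _ease(u: float) -> float:
    """Cosine ease-in/out on [0, 1] (monotone, C1 at the endpoints)."""
    return 0.5 * (1.0 - math.cos(math.pi * u))


def interpolated_targets(
    keyframes: list[StageKeyframe], t: float
) -> dict[str, float]:
    """Angle targets at time ``t`` (cosine easing between stage keyframes).

    Keyframe ``i`` is reached at the cumulative start of its stage and eases
    to keyframe ``i+1`` over its own duration; past the last keyframe the
    upright posture holds.  theta6 is re-derived from the interpolated
    theta5/theta7 so every interpolated posture stays chain-consistent.
    """
    starts = [0.0]
    for kf in keyframes[:-1]:
        starts.append(starts[-1] + kf.duration)
    if t <= 0:
        base = dict(keyframes[0].targets)
    elif t >= starts[-1]:
        base = dict(keyframes[-1].targets)
    else:
        i = max(j for j, s in enumerate(starts) if s <= t)
        u = _ease((t - starts[i]) / keyframes[i].duration)
        a, b = keyframes[i].targets, keyframes[i + 1].targets
        base = {k: (1 - u) * a[k] + u * b[k] for k in a}
    for suffix in ("1", "2"):
        base[f"theta6_{suffix}"] = implied_knee_angle(
            base[f"theta5_{suffix}"], base[f"theta7_{suffix}"]
        )
    return base


def total_duration(keyframes: list[StageKeyframe]) -> float:
    return sum(kf.duration for kf in keyframes)


def simulate_subject(
    anthro: Anthropometry,
    keyframes: list[StageKeyframe],
    noise_sd: float = 0.005,
    interval: float = 1.0,
    seed: int = 0,
    subject_id: str = "sim",
    cohort: str = "elderly",
) -> MotionSequence:
    """Simulate one subject's sit-to-stand recording.

    Deterministic for a given seed; with ``noise_sd = 0`` the frames are the
    exact keyframe-interpolated chain postures.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if not interval > 0:
        raise ValueError("sample interval must be positive")
    for kf in keyframes:
        # re-validate (keyframes may be hand-built dataclasses)
        StageKeyframe(kf.stage, kf.targets, kf.duration)
    seg = _segments(anthro)
    rng = np.random.default_rng(seed)
    T = total_duration(keyframes)
    times = np.arange(0.0, T + 1e-9, interval)
    frames = []
    for t in times:
        targets = interpolated_targets(keyframes, float(t))
        pos = _pose(targets, seg)
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=(len(pos), 3))
            pos = {k: v + noise[i] for i, (k, v) in enumerate(pos.items())}
        frames.append(SkeletonFrame(timestamp=float(t), positions=pos))
    return MotionSequence(subject_id=subject_id, cohort=cohort, frames=frames)


def _draw_anthropometry(
    dist: dict[str, tuple[float, float]], rng: np.random.Generator
) -> Anthropometry:
    values = {}
    for code, (mean, sd) in dist.items():
        v = rng.normal(mean, sd)
        values[code] = max(v, 0.2 * mean)  # keep measures physically positive
    # enforce type invariants on the draw
    values["L4"] = min(values["L4"], 0.9 * values["L1"])
    values["Z5"] = min(values["Z5"], 0.9 * (values["Z1"] + values["Z9"]))
    return Anthropometry(
        standing={m: values[m] for m in STANDING_MEASURES},
        sitting={m: values[m] for m in SITTING_MEASURES},
    )


def simulate_cohort(spec: CohortSpec) -> list[tuple[Anthropometry, MotionSequence]]:
    """Simulate a cohort; returns (anthropometry, sequence) per subject.

    Per-subject randomness is split off a single seed sequence, so any
    subject is reproducible independently of cohort size.
    """
    root = np.random.SeedSequence(spec.seed)
    anthro_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.generate_state(spec.n_subjects) % (2**31)
    out = []
    for i in range(spec.n_subjects):
        anthro = _draw_anthropometry(spec.anthropometry, anthro_rng)
        seq = simulate_subject(
            anthro,
            spec.keyframes,
            noise_sd=spec.coordinate_noise_sd,
            interval=spec.sample_interval,
            seed=int(subject_seeds[i]),
            subject_id=f"{spec.cohort}_{i:03d}",
            cohort=spec.cohort,
        )
        out.append((anthro, seq))
    return out
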