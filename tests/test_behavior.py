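import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sit2stand.angles import ANGLE_IDS, AngleVector, extract_angles
from sit2stand.behavior import (
    SitToStandModel,
    cluster_postures,
    coarse_labels,
    extract_thresholds,
    rank_importance,
    stage_report,
    thresholds_from_angles,
)
from sit2stand.simulate import (
    _pose,
    _segments,
    default_keyframes,
    interpolated_targets,
    make_keyframe,
    simulate_subject,
)
from sit2stand.skeleton import MotionSequence, SkeletonFrame


def _vec(t, base=90.0, **over):
    values = {a: base for a in ANGLE_IDS}
    values.update(over)
    return AngleVector(timestamp=t, values=values)


def _angle_df(n, seed, informative="theta5_2"):
    """Uniform-noise angle table whose labels depend on one angle only."""
    rng = np.random.default_rng(seed)
    data = {"timestamp": np.arange(n, dtype=float)}
    for a in ANGLE_IDS:
        data[a] = rng.uniform(0.0, 180.0, n)
    signal = rng.uniform(90.0, 180.0, n)
    data[informative] = signal
    labels = np.digitize(signal, [120.0, 150.0])
    return pd.DataFrame(data), labels


# --- clustering ------------------------------------------------------------

def test_single_cluster_centroid_is_mean():
    vecs = [_vec(float(i), base=60.0 + i) for i in range(5)]
    cs = cluster_postures(vecs, k=1, seed=0)
    np.testing.assert_allclose(cs.centroids[0],
                               np.mean([v.as_array() for v in vecs], axis=0))


def test_two_separated_blobs_fully_recovered():
    rng = np.random.default_rng(0)
    vecs, truth = [], []
    for i in range(60):
        base = 60.0 if i % 2 == 0 else 100.0  # blobs 40 degrees apart
        vals = {a: base + rng.normal(0, 1.0) for a in ANGLE_IDS}
        vals = {a: float(np.clip(v, 0, 180)) for a, v in vals.items()}
        vecs.append(AngleVector(timestamp=float(i), values=vals))
        truth.append(i % 2)
    cs = cluster_postures(vecs, k=2, seed=1)
    assert adjusted_rand_score(truth, cs.assignments) == 1.0


def test_identical_vectors_degenerate_input():
    vecs = [_vec(float(i)) for i in range(6)]
    cs = cluster_postures(vecs, k=2, seed=0)
    assert len(cs.assignments) == 6
    assert set(cs.assignments) <= {0, 1}


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError, match="k must"):
        cluster_postures([_vec(0.0), _vec(1.0)], k=3)


def test_centroid_equals_member_mean_and_order():
    df, _ = _angle_df(80, seed=4)
    cs = cluster_postures(df, k=4, seed=2)
    for c in range(4):
        members = df.loc[cs.assignments == c, list(ANGLE_IDS)].to_numpy()
        np.testing.assert_allclose(cs.centroids[c], members.mean(axis=0),
                                   atol=1e-9)
    means = [cs.mean_timestamp(c) for c in cs.stage_order]
    assert means == sorted(means)


def test_clustering_invariant_to_frame_order():
    """On separable data the recovered centroids do not depend on the order
    the frames arrive in (both runs reach the same optimum)."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(90):
        base = (40.0, 90.0, 140.0)[i % 3]
        rows.append({"timestamp": float(i),
                     **{a: base + rng.normal(0, 1.0) for a in ANGLE_IDS}})
    df = pd.DataFrame(rows)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = cluster_postures(df, k=3, seed=5)
    b = cluster_postures(shuffled, k=3, seed=5)
    assert np.sort(a.centroids, axis=0) == pytest.approx(
        np.sort(b.centroids, axis=0), abs=1e-6)


# --- thresholds ------------------------------------------------------------

def _frames_with_theta1(values, elderly_anthro):
    """Frames realized on the kinematic chain with prescribed theta1."""
    seg = _segments(elderly_anthro)
    base = default_keyframes("elderly")[0].targets
    frames = []
    for i, t1 in enumerate(values):
        targets = dict(base)
        targets["theta1"] = t1
        frames.append(SkeletonFrame(timestamp=float(i),
                                    positions=_pose(targets, seg)))
    return MotionSequence("s", "elderly", frames=frames)


def test_threshold_is_min_max(elderly_anthro):
    seq = _frames_with_theta1([5.0, 12.0, 9.0], elderly_anthro)
    table = extract_thresholds([seq])
    lo, hi = table.range("elderly", "theta1")
    assert (lo, hi) == (pytest.approx(5.0, abs=1e-9),
                        pytest.approx(12.0, abs=1e-9))


def test_constant_sequence_collapses_bounds(elderly_anthro):
    seq = _frames_with_theta1([8.0, 8.0], elderly_anthro)
    lo, hi = extract_thresholds([seq]).range("elderly", "theta1")
    assert lo == hi


def test_noise_free_thresholds_match_interpolation_oracle(small_cohorts):
    """With zero noise the extracted table equals the min/max of the
    keyframe-interpolated angle targets at the sampled instants."""
    table = extract_thresholds(
        small_cohorts["elderly"] + small_cohorts["control"])
    for cohort in ("elderly", "control"):
        kfs = default_keyframes(cohort)
        times = [f.timestamp for f in small_cohorts[cohort][0].frames]
        targets = [interpolated_targets(kfs, t) for t in times]
        for a in ANGLE_IDS:
            expected = ([tg[a] for tg in targets])
            lo, hi = table.range(cohort, a)
            assert lo == pytest.approx(min(expected), abs=1e-9)
            assert hi == pytest.approx(max(expected), abs=1e-9)


def test_degenerate_frames_skipped(elderly_anthro):
    seq = _frames_with_theta1([5.0, 12.0], elderly_anthro)
    broken = seq.frames[0]
    broken.positions["head"] = broken.positions["neck"].copy()
    table = extract_thresholds([seq])
    assert table.skipped_frames == 1
    lo, hi = table.range("elderly", "theta1")
    assert (lo, hi) == (pytest.approx(12.0), pytest.approx(12.0))


# --- importance ------------------------------------------------------------

def test_planted_informative_angle_dominates():
    df, labels = _angle_df(240, seed=1)
    res = rank_importance(df, labels, seed=1)
    assert res.top_angle() == "theta5_2"
    assert res.normalized["theta5_2"] == 100.0
    assert res.importances["theta5_2"] == max(res.importances.values())


def test_importances_sum_to_one():
    df, labels = _angle_df(160, seed=2)
    res = rank_importance(df, labels, seed=2)
    assert sum(res.importances.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in res.importances.values())


def test_pure_noise_angles_carry_negligible_importance():
    """Pure-noise columns get near-zero accuracy drops, an order of magnitude
    below the planted informative angle's drop."""
    df, labels = _angle_df(600, seed=3)
    res = rank_importance(df, labels, seed=3)
    null_angles = [a for a in ANGLE_IDS if a != "theta5_2"]
    max_null = max(res.raw_drops[a] for a in null_angles)
    assert max_null <= 0.05
    assert res.raw_drops["theta5_2"] >= 10 * max_null


def test_single_class_labels_rejected():
    df, _ = _angle_df(50, seed=4)
    with pytest.raises(ValueError, match="two label classes"):
        rank_importance(df, np.zeros(50), seed=0)


def test_split_bounds():
    df, labels = _angle_df(50, seed=5)
    with pytest.raises(ValueError, match="split"):
        rank_importance(df, labels, split=1.2)


# --- stage reports ---------------------------------------------------------

def test_stage_report_orders_by_time():
    df, _ = _angle_df(80, seed=6)
    cs = cluster_postures(df, k=4, seed=0)
    summary = stage_report(cs)
    means = [s["mean_timestamp"] for s in summary.stages]
    assert means == sorted(means)
    assert [s["stage"] for s in summary.stages] == [1, 2, 3, 4]


def test_fine_to_coarse_is_a_partition():
    df, _ = _angle_df(120, seed=7)
    cs = cluster_postures(df, k=9, seed=0)
    summary = stage_report(cs, coarse=3)
    assert set(summary.fine_to_coarse) == set(range(9))
    assert set(summary.fine_to_coarse.values()) == {0, 1, 2}
    labels = coarse_labels(cs, coarse=3)
    assert len(labels) == 120 and set(labels) == {0, 1, 2}


def test_four_stage_structure_recovered(elderly_anthro):
    """A noise-free simulated transition clusters into 4 temporally ordered
    stages whose centroid order tracks the keyframe script."""
    seq = simulate_subject(elderly_anthro, default_keyframes("elderly"),
                           noise_sd=0.0, interval=0.1, seed=0)
    vecs = [extract_angles(f) for f in seq.frames]
    cs = cluster_postures(vecs, k=4, seed=0)
    summary = stage_report(cs)
    assert len(summary.stages) == 4
    theta5_first = summary.stages[0]["centroid"]["theta5_1"]
    theta5_last = summary.stages[-1]["centroid"]["theta5_1"]
    assert theta5_last > theta5_first  # stands up over time


# --- fitted-model surface --------------------------------------------------

def test_model_fit_and_summary(small_cohorts):
    model = SitToStandModel.from_sequences(
        small_cohorts["elderly"] + small_cohorts["control"])
    res = model.fit(k=6, coarse=3, seed=0, n_permutations=5)
    assert set(res.thresholds.ranges) == {"elderly", "control"}
    text = res.summary()
    assert "theta5_2" in text and "activity thresholds" in text
    res2 = model.fit(k=6, coarse=3, seed=0, n_permutations=5)
    assert res.importance.importances == res2.importance.importances

    import matplotlib
    matplotlib.use("Agg")
    assert res.plot_stages() is not None
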