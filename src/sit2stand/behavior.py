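"""Posture clustering, activity thresholds and angle-importance ranking.

Per-frame 12-angle vectors are clustered with k-means into center postures;
per-cohort activity thresholds are the [min, max] each angle traverses over
all frames; and the influence of each angle on the stage structure is ranked
with a small two-layer perceptron (one tanh hidden layer) via permutation
importance on a held-out split.

The stage is exposed both as plain operations and as a fitted-model pair
:class:`SitToStandModel` / :class:`SitToStandResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .angles import (
    ANGLE_IDS,
    AngleDefinition,
    AngleVector,
    DegenerateGeometryError,
    angles_to_dataframe,
    extract_angles,
)
from .skeleton import COHORTS, MotionSequence

logger = logging.getLogger(__name__)


# --- clustering ------------------------------------------------------------

@dataclass
class PostureClusterSet:
    """k-means posture clusters over 12-dimensional angle vectors.

    ``stage_order`` lists cluster ids sorted by the mean timestamp of their
    member frames, i.e. in the temporal order the postures occur.
    """

    k: int
    centroids: np.ndarray          # (k, 12), degrees
    assignments: np.ndarray        # (n,), cluster id per frame
    timestamps: np.ndarray         # (n,), seconds
    stage_order: list[int]
    inertia: float

    def mean_timestamp(self, cluster: int) -> float:
        return float(self.timestamps[self.assignments == cluster].mean())

    def centroid_vector(self, cluster: int) -> AngleVector:
        values = dict(zip(ANGLE_IDS, self.centroids[cluster]))
        return AngleVector(timestamp=self.mean_timestamp(cluster), values=values)


def _angles_matrix(vectors) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(vectors, pd.DataFrame):
        return vectors[list(ANGLE_IDS)].to_numpy(float), vectors["timestamp"].to_numpy(float)
    df = angles_to_dataframe(list(vectors))
    return df[list(ANGLE_IDS)].to_numpy(float), df["timestamp"].to_numpy(float)


def cluster_postures(vectors, k: int, seed: int = 0) -> PostureClusterSet:
    """k-means over angle vectors (k-means++ init, 10 restarts, tol 1e-6).

    Deterministic under ``seed``; empty clusters are re-seeded from the
    farthest points (scikit-learn's relocation rule).
    """
    X, ts = _angles_matrix(vectors)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must satisfy 1 <= k <= n_frames ({n}), got {k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6,
                    random_state=seed).fit(X)
    labels = km.labels_.astype(int)
    # recompute centroids as exact member means (duplicated points can leave
    # a fitted center slightly off the mean after relocation)
    centroids = np.vstack([
        X[labels == c].mean(axis=0) if np.any(labels == c) else km.cluster_centers_[c]
        for c in range(k)
    ])
    order = sorted(range(k), key=lambda c: ts[labels == c].mean()
                   if np.any(labels == c) else np.inf)
    return PostureClusterSet(k=k, centroids=centroids, assignments=labels,
                             timestamps=ts, stage_order=order,
                             inertia=float(km.inertia_))


# --- activity thresholds ---------------------------------------------------

@dataclass
class ThresholdTable:
    """Per-cohort, per-angle [lower, upper] activity range in degrees."""

    ranges: dict[str, dict[str, tuple[float, float]]]
    skipped_frames: int = 0

    def range(self, cohort: str, angle_id: str) -> tuple[float, float]:
        return self.ranges[cohort][angle_id]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cohort, table in self.ranges.items():
            for angle_id in ANGLE_IDS:
                if angle_id in table:
                    lo, hi = table[angle_id]
                    rows.append({"cohort": cohort, "angle": angle_id,
                                 "lower": lo, "upper": hi})
        return pd.DataFrame(rows)


def extract_thresholds(
    sequences: list[MotionSequence],
    defs: dict[str, AngleDefinition] | None = None,
) -> ThresholdTable:
    """Activity thresholds: per cohort and angle, [min, max] over all frames.

    Frames with degenerate geometry are skipped (count reported); a cohort
    whose frames are all degenerate raises.
    """
    per_cohort: dict[str, list[AngleVector]] = {}
    skipped = 0
    seen_cohorts = set()
    for seq in sequences:
        seen_cohorts.add(seq.cohort)
        for frame in seq.frames:
            try:
                av = extract_angles(frame, defs)
            except DegenerateGeometryError:
                skipped += 1
                continue
            per_cohort.setdefault(seq.cohort, []).append(av)
    if skipped:
        logger.warning("extract_thresholds skipped %d degenerate frame(s)", skipped)
    if not sequences:
        raise ValueError("at least one sequence is required")
    ranges: dict[str, dict[str, tuple[float, float]]] = {}
    for cohort in sorted(seen_cohorts):
        if cohort not in per_cohort:
            raise ValueError(f"all frames degenerate for cohort {cohort!r}")
        X = np.vstack([av.as_array() for av in per_cohort[cohort]])
        ranges[cohort] = {
            a: (float(X[:, i].min()), float(X[:, i].max()))
            for i, a in enumerate(ANGLE_IDS)
        }
    return ThresholdTable(ranges=ranges, skipped_frames=skipped)


def thresholds_from_angles(df: pd.DataFrame) -> ThresholdTable:
    """Thresholds from an angle table carrying a ``cohort`` column."""
    ranges = {}
    for cohort, grp in df.groupby("cohort"):
        ranges[str(cohort)] = {
            a: (float(grp[a].min()), float(grp[a].max())) for a in ANGLE_IDS
        }
    return ThresholdTable(ranges=ranges)


# --- importance ranking ----------------------------------------------------

@dataclass
class ImportanceResult:
    """Permutation importance of each angle for stage classification.

    ``importances`` sum to 1; ``normalized`` rescales so the maximum is 100%.
    ``permutation_se`` is the standard error of the per-permutation accuracy
    drops, useful to judge whether an importance is distinguishable from 0.
    """

    importances: dict[str, float]
    normalized: dict[str, float]
    raw_drops: dict[str, float]
    permutation_se: dict[str, float]
    train_count: int
    test_count: int
    test_accuracy: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.importances.items(), key=lambda kv: -kv[1])

    def top_angle(self) -> str:
        return self.ranked()[0][0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "angle": list(ANGLE_IDS),
            "importance": [self.importances[a] for a in ANGLE_IDS],
            "normalized_importance": [self.normalized[a] for a in ANGLE_IDS],
        })


def normalize_importance(raw: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    """Sum-to-1 importances and max-100% normalized importances from raw scores."""
    total = sum(raw.values())
    if total <= 0:
        # no feature moved the accuracy; report a flat profile
        importances = {a: 1.0 / len(raw) for a in raw}
    else:
        importances = {a: v / total for a, v in raw.items()}
    peak = max(importances.values())
    normalized = {a: v / peak * 100.0 for a, v in importances.items()}
    return importances, normalized


def rank_importance(
    vectors,
    labels,
    split: float = 0.75,
    hidden_units: int = 4,
    seed: int = 0,
    n_permutations: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ImportanceResult:
    """Rank angle importance with a two-layer tanh perceptron.

    Frames are split ``split`` : ``1-split`` into train/test; angles are
    z-scored with training statistics; the network has one hidden tanh layer
    of ``hidden_units`` cells with a softmax output and is trained by
    full-batch gradient descent with an adaptive learning rate.  Importance
    of an angle is its mean decrease in held-out accuracy over
    ``n_permutations`` shuffles of that column, clipped at zero and
    normalized to sum to one.
    """
    X, _ = _angles_matrix(vectors)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("vectors and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("at least two label classes are required")
    if not (0.0 < split < 1.0):
        raise ValueError("split must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_train = max(2, int(round(split * n)))
    if n_train >= n:
        n_train = n - 1
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split does not contain two classes")

    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="sgd",
        learning_rate="adaptive",
        learning_rate_init=0.05,
        batch_size=min(n_train, 20000),
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Xs[train_idx], y[train_idx])
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        notes.append("perceptron did not converge within max_iter; "
                     "best-effort importances reported")
        logger.warning(notes[-1])

    Xtest, ytest = Xs[test_idx], y[test_idx]
    base_acc = float((clf.predict(Xtest) == ytest).mean())
    raw: dict[str, float] = {}
    se: dict[str, float] = {}
    for j, angle_id in enumerate(ANGLE_IDS):
        drops = np.empty(n_permutations)
        for p in range(n_permutations):
            Xp = Xtest.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xtest)), j]
            drops[p] = base_acc - float((clf.predict(Xp) == ytest).mean())
        raw[angle_id] = max(0.0, float(drops.mean()))
        se[angle_id] = float(drops.std(ddof=1) / np.sqrt(n_permutations))
    importances, normalized = normalize_importance(raw)
    return ImportanceResult(
        importances=importances,
        normalized=normalized,
        raw_drops=raw,
        permutation_se=se,
        train_count=len(train_idx),
        test_count=len(test_idx),
        test_accuracy=base_acc,
        converged=converged,
        warnings=notes,
    )


# --- stage summaries -------------------------------------------------------

@dataclass
class StageSummary:
    """Clusters in temporal order, optionally agglomerated to coarse stages."""

    stages: list[dict]
    fine_to_coarse: dict[int, int] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            row = {"stage": s["stage"], "cluster": s["cluster"],
                   "mean_timestamp": s["mean_timestamp"], "count": s["count"]}
            row.update({a: s["centroid"][a] for a in ANGLE_IDS})
            rows.append(row)
        return pd.DataFrame(rows)


def stage_report(clusters: PostureClusterSet, coarse: int | None = None) -> StageSummary:
    """Order clusters by mean timestamp; optionally merge fine clusters into
    ``coarse`` stages by Ward agglomeration of the centroids."""
    fine_to_coarse = None
    if coarse is not None:
        if not (1 <= coarse <= clusters.k):
            raise ValueError("coarse must satisfy 1 <= coarse <= k")
        if coarse == clusters.k:
            fine_to_coarse = {c: c for c in range(clusters.k)}
        else:
            Z = linkage(clusters.centroids, method="ward")
            merged = fcluster(Z, t=coarse, criterion="maxclust")
            fine_to_coarse = {c: int(merged[c]) - 1 for c in range(clusters.k)}
    stages = []
    for rank, c in enumerate(clusters.stage_order, start=1):
        mask = clusters.assignments == c
        entry = {
            "stage": rank,
            "cluster": int(c),
            "mean_timestamp": clusters.mean_timestamp(c),
            "count": int(mask.sum()),
            "centroid": dict(zip(ANGLE_IDS, clusters.centroids[c])),
        }
        if fine_to_coarse is not None:
            entry["coarse_stage"] = fine_to_coarse[c]
        stages.append(entry)
    return StageSummary(stages=stages, fine_to_coarse=fine_to_coarse)


def coarse_labels(clusters: PostureClusterSet, coarse: int) -> np.ndarray:
    """Per-frame coarse stage labels, renumbered in temporal order."""
    summary = stage_report(clusters, coarse=coarse)
    mapping = summary.fine_to_coarse
    raw = np.array([mapping[c] for c in clusters.assignments])
    # renumber coarse ids by mean timestamp so label 0 is the earliest stage
    means = {g: clusters.timestamps[raw == g].mean() for g in np.unique(raw)}
    order = {g: i for i, g in enumerate(sorted(means, key=means.get))}
    return np.array([order[g] for g in raw])


# --- fitted-model surface --------------------------------------------------

class SitToStandModel:
    """Sit-to-stand behavior model over per-frame joint-angle vectors.

    Built from an angle table (``timestamp`` + the 12 angle columns, plus an
    optional ``cohort`` column) or directly from motion sequences.  Fitting
    clusters the postures, derives per-cohort activity thresholds and ranks
    angle importance for the recovered stage structure.
    """

    def __init__(self, angles: pd.DataFrame):
        missing = [c for c in ("timestamp", *ANGLE_IDS) if c not in angles.columns]
        if missing:
            raise ValueError(f"angle table missing column(s): {missing}")
        self.angles = angles.reset_index(drop=True)

    @classmethod
    def from_sequences(
        cls,
        sequences: list[MotionSequence],
        defs: dict[str, AngleDefinition] | None = None,
    ) -> "SitToStandModel":
        parts = []
        for seq in sequences:
            rows = []
            for frame in seq.frames:
                try:
                    rows.append(extract_angles(frame, defs))
                except DegenerateGeometryError:
                    continue
            df = angles_to_dataframe(rows)
            df.insert(0, "subject_id", seq.subject_id)
            df["cohort"] = seq.cohort
            parts.append(df)
        return cls(pd.concat(parts, ignore_index=True))

    def fit(
        self,
        k: int = 9,
        coarse: int = 4,
        split: float = 0.75,
        hidden_units: int = 4,
        seed: int = 0,
        n_permutations: int = 20,
    ) -> "SitToStandResults":
        clusters = cluster_postures(self.angles, k=k, seed=seed)
        labels = coarse_labels(clusters, coarse=coarse)
        importance = rank_importance(
            self.angles, labels, split=split, hidden_units=hidden_units,
            seed=seed, n_permutations=n_permutations,
        )
        if "cohort" in self.angles.columns:
            thresholds = thresholds_from_angles(self.angles)
        else:
            thresholds = ThresholdTable(
                ranges={"elderly": {
                    a: (float(self.angles[a].min()), float(self.angles[a].max()))
                    for a in ANGLE_IDS
                }}
            )
        summary = stage_report(clusters, coarse=coarse)
        return SitToStandResults(
            model=self, clusters=clusters, stage_labels=labels,
            thresholds=thresholds, importance=importance,
            stage_summary=summary, params=dict(
                k=k, coarse=coarse, split=split, hidden_units=hidden_units,
                seed=seed, n_permutations=n_permutations,
            ),
        )


@dataclass
class SitToStandResults:
    """Fitted sit-to-stand behavior analysis."""

    model: SitToStandModel
    clusters: PostureClusterSet
    stage_labels: np.ndarray
    thresholds: ThresholdTable
    importance: ImportanceResult
    stage_summary: StageSummary
    params: dict

    def summary(self) -> str:
        lines = [
            "Sit-to-stand behavior analysis",
            "=" * 46,
            f"frames: {len(self.model.angles)}   fine clusters: {self.params['k']}"
            f"   coarse stages: {self.params['coarse']}",
            f"perceptron: {self.params['hidden_units']} tanh hidden units, "
            f"train/test {self.importance.train_count}/{self.importance.test_count}, "
            f"test accuracy {self.importance.test_accuracy:.3f}",
            "",
            f"{'angle':<10}{'importance':>12}{'normalized %':>14}",
        ]
        for a in ANGLE_IDS:
            lines.append(
                f"{a:<10}{self.importance.importances[a]:>12.3f}"
                f"{self.importance.normalized[a]:>14.1f}"
            )
        lines.append("")
        lines.append("activity thresholds (degrees):")
        for cohort, table in self.thresholds.ranges.items():
            lines.append(f"  {cohort}:")
            for a in ANGLE_IDS:
                lo, hi = table[a]
                lines.append(f"    {a:<10}[{lo:8.3f}, {hi:8.3f}]")
        return "\n".join(lines)

    def plot_stages(self, ax=None):
        """Plot each angle's trajectory colored by coarse stage."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4.5))
        ts = self.model.angles["timestamp"].to_numpy()
        for a in ANGLE_IDS:
            ax.scatter(ts, self.model.angles[a], c=self.stage_labels,
                       s=6, cmap="viridis")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("joint angle (deg)")
        ax.set_title("joint-angle trajectories by transition stage")
        return ax
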