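"""Unsupervised ethogramming: features, k-means clusters, labels, embeddings.

Per-frame kinematic features (every node's speed followed by every node's
x/y position in cm) are z-scored and partitioned with k-means (k = 4 by
default, matching the four behaviors seen in the assay: resting, scurrying,
left and right leg movement). A heuristic then attaches semantic names to
the clusters from their unstandardized speed summaries, and the clusters can
be embedded in 2-D with PCA or UMAP for visualization. Raw cluster ids are
always retained alongside the semantic map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .pose_io import PoseTrack, SkeletonDef
from .trackmetrics import ArenaGeometry

__all__ = [
    "FeatureMatrix",
    "EmbeddingParams",
    "SemanticLabeling",
    "EthogramResult",
    "build_features",
    "cluster_frames",
    "label_clusters",
    "embed_2d",
    "summarize_bouts",
    "run_ethogram",
]

BEHAVIOR_NAMES: tuple[str, ...] = (
    "resting",
    "scurrying",
    "left leg movement",
    "right leg movement",
)


@dataclass
class FeatureMatrix:
    """Z-scored per-frame features with the transform recorded for inversion.

    ``values`` is (n_retained_frames, 3 * n_nodes): per-node speed (cm/s)
    columns, then per-node x and y position (cm). Only frames with every
    feature present are retained; ``frame_index`` maps rows back to frames.
    """

    values: np.ndarray
    columns: list[str]
    frame_index: np.ndarray
    means: np.ndarray
    sds: np.ndarray  # raw column SDs; zero marks a constant column
    skeleton: SkeletonDef
    fps: float

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    def destandardize(self) -> np.ndarray:
        sd_safe = np.where(self.sds == 0, 1.0, self.sds)
        return self.values * sd_safe + self.means

    def speed_columns(self, nodes: list[str]) -> np.ndarray:
        idx = [self.columns.index(f"speed:{n}") for n in nodes]
        return self.destandardize()[:, idx]


@dataclass(frozen=True)
class EmbeddingParams:
    """2-D embedding settings (Euclidean metric throughout)."""

    method: str = "pca"  # {pca, umap}
    n_components: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    spread: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.method not in ("pca", "umap"):
            raise ValueError(f"unknown embedding method {self.method!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not 0 <= self.min_dist <= self.spread:
            raise ValueError("min_dist must lie in [0, spread]")


def build_features(
    track: PoseTrack,
    geometry: ArenaGeometry,
    position_frame: str = "egocentric",
    standardize: bool = True,
) -> FeatureMatrix:
    """Kinematic feature matrix: speeds then positions, z-scored per column.

    Row i describes frame i using the speed of the step i -> i+1 and the
    position at frame i; frames missing any node at i or i+1 are dropped.
    Constant columns are left at 0 after centering.

    ``position_frame`` selects the position representation: ``egocentric``
    (default) expresses each node relative to the body anchor, so the
    position block describes posture rather than location on the runway —
    otherwise where the animal happens to be dominates the clustering over
    how it is moving; ``arena`` keeps absolute runway coordinates.
    ``standardize=False`` skips the z-scoring (means/sds still recorded).
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames to build features")
    if position_frame not in ("egocentric", "arena"):
        raise ValueError(f"unknown position_frame {position_frame!r}")
    ppcm = geometry.pixels_per_cm
    disp_px = np.diff(track.coords, axis=0)
    speed = np.linalg.norm(disp_px, axis=2) / ppcm * track.fps  # (n-1, n_nodes)
    if position_frame == "egocentric":
        j = track.skeleton.index(track.skeleton.anchor_body)
        rel = (track.coords[:-1] - track.coords[:-1, j : j + 1, :]) / ppcm
        pos_x, pos_y = rel[:, :, 0], rel[:, :, 1]
    else:
        pos_x = geometry.x_to_cm(track.coords[:-1, :, 0])
        pos_y = geometry.y_to_cm(track.coords[:-1, :, 1])
    raw = np.concatenate([speed, pos_x, pos_y], axis=1)
    keep = ~np.isnan(raw).any(axis=1)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 frames with complete features")
    raw = raw[keep]
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    if standardize:
        sd_safe = np.where(sds == 0, 1.0, sds)
        values = (raw - means) / sd_safe
    else:
        values = raw
        means = np.zeros_like(means)
        sds = np.ones_like(sds)
    names = list(track.skeleton.node_names)
    columns = (
        [f"speed:{n}" for n in names]
        + [f"x:{n}" for n in names]
        + [f"y:{n}" for n in names]
    )
    return FeatureMatrix(
        values=values,
        columns=columns,
        frame_index=np.flatnonzero(keep),
        means=means,
        sds=sds,
        skeleton=track.skeleton,
        fps=track.fps,
    )


def cluster_frames(features: FeatureMatrix, k: int = 4, seed: int = 42) -> np.ndarray:
    """K-means partition of the feature rows; deterministic under the seed."""
    if features.n_rows < k:
        raise ValueError(f"need at least k={k} rows, have {features.n_rows}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(features.values)


@dataclass
class SemanticLabeling:
    """Cluster id -> behavior name, with flags for ambiguous summaries.

    ``tie_broken`` marks an arbitrary ordering between indistinguishable
    cluster summaries; ``degenerate`` marks a session whose clusters do not
    actually differ in body speed (e.g., an animal that only rested), where
    the semantic names carry no meaning and raw ids should be preferred.
    """

    mapping: dict[int, str]
    tie_broken: bool = False
    degenerate: bool = False


def label_clusters(
    labels: np.ndarray,
    features: FeatureMatrix,
    skeleton: SkeletonDef | None = None,
) -> SemanticLabeling:
    """Heuristic semantic names for k = 4 clusters.

    Resting is the cluster with the lowest mean midline-body speed and
    scurrying the highest; the remaining two split on signed left-minus-right
    mean leg speed (positive -> left leg movement). When two cluster
    summaries are indistinguishable the tie breaks toward the lower cluster
    id and ``tie_broken`` is set.
    """
    skeleton = skeleton if skeleton is not None else features.skeleton
    uniq = np.unique(labels)
    if len(uniq) != 4:
        raise ValueError(
            f"semantic labeling requires exactly 4 clusters, got {len(uniq)}; "
            "keep raw cluster ids instead"
        )
    body_nodes = [n for n in skeleton.node_names
                  if skeleton.limb_sides[n] == "midline"]
    legs_l = skeleton.leg_nodes("left")
    legs_r = skeleton.leg_nodes("right")
    body_speed = features.speed_columns(body_nodes).mean(axis=1)
    lr_speed = (
        features.speed_columns(legs_l).mean(axis=1)
        - features.speed_columns(legs_r).mean(axis=1)
    )
    body_mean = {int(c): float(body_speed[labels == c].mean()) for c in uniq}
    lr_mean = {int(c): float(lr_speed[labels == c].mean()) for c in uniq}

    order = sorted(body_mean, key=lambda c: (body_mean[c], c))
    tie_broken = len(set(body_mean.values())) < 4
    resting, scurrying = order[0], order[-1]
    middle = [c for c in order[1:-1]]
    # positive left-minus-right leg speed -> left leg movement
    middle_sorted = sorted(middle, key=lambda c: (-lr_mean[c], c))
    if lr_mean[middle_sorted[0]] == lr_mean[middle_sorted[1]]:
        tie_broken = True
        middle_sorted = sorted(middle)
    mapping = {
        resting: "resting",
        scurrying: "scurrying",
        middle_sorted[0]: "left leg movement",
        middle_sorted[1]: "right leg movement",
    }
    # clusters whose body-speed summaries barely differ relative to the
    # within-cluster spread carry no behavioral signal
    within_sd = float(
        np.sqrt(np.mean([body_speed[labels == c].var() for c in uniq]))
    )
    spread = body_mean[scurrying] - body_mean[resting]
    degenerate = spread < 0.5 * max(within_sd, 1e-12)
    return SemanticLabeling(
        mapping=mapping, tie_broken=tie_broken, degenerate=degenerate
    )


def embed_2d(features: FeatureMatrix, params: EmbeddingParams) -> np.ndarray:
    """Embed the feature rows in 2-D with PCA or UMAP.

    PCA is the deterministic default (projection onto the top principal
    axes, unique up to axis sign); UMAP uses the configured neighborhood
    hyperparameters with a fixed seed.
    """
    if features.n_rows < params.n_components + 1:
        raise ValueError("too few rows to embed")
    if params.method == "pca":
        pca = PCA(n_components=params.n_components, random_state=params.seed)
        return pca.fit_transform(features.values)
    import umap  # deferred: numba-backed import is slow

    reducer = umap.UMAP(
        n_components=params.n_components,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        spread=params.spread,
        metric="euclidean",
        random_state=params.seed,
    )
    return np.asarray(reducer.fit_transform(features.values))


def summarize_bouts(
    labels: np.ndarray,
    fps: float,
    semantic_map: dict[int, str] | None = None,
) -> tuple[list[tuple[int, int, int]], dict[str, float]]:
    """Run-length encode labels into bouts and tally time per behavior.

    Bouts are half-open (start, end, label) runs over retained-frame index
    space; time per behavior is label count / fps. Keys of the time map are
    semantic names when a map is given, else stringified cluster ids.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    bouts = [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]
    counts = pd.Series(labels).value_counts()
    name = (lambda c: semantic_map[c]) if semantic_map else (lambda c: str(c))
    time_per_behavior = {name(int(c)): float(n / fps) for c, n in counts.items()}
    return bouts, time_per_behavior


@dataclass
class EthogramResult:
    """Full ethogram of one session."""

    labels: np.ndarray  # per-retained-frame cluster id
    frame_index: np.ndarray
    k: int
    semantic_map: dict[int, str] | None
    tie_broken: bool
    bouts: list[tuple[int, int, int]]
    time_per_behavior_s: dict[str, float]
    embedding: np.ndarray
    seed: int
    fps: float

    @property
    def semantic_labels(self) -> np.ndarray | None:
        if self.semantic_map is None:
            return None
        return np.array([self.semantic_map[int(c)] for c in self.labels],
                        dtype=object)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "fps": self.fps,
            "semantic_map": (
                {str(k): v for k, v in self.semantic_map.items()}
                if self.semantic_map
                else None
            ),
            "tie_broken": self.tie_broken,
            "bouts": self.bouts,
            "time_per_behavior_s": self.time_per_behavior_s,
            "n_retained_frames": int(self.labels.size),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": self.frame_index,
                "cluster": self.labels,
                "embed_1": self.embedding[:, 0],
                "embed_2": self.embedding[:, 1],
            }
        )
        sem = self.semantic_labels
        if sem is not None:
            df["behavior"] = sem
        return df


def run_ethogram(
    track: PoseTrack,
    geometry: ArenaGeometry,
    k: int = 4,
    seed: int = 42,
    embedding: EmbeddingParams | None = None,
) -> EthogramResult:
    """Features -> clusters -> semantic names -> bouts -> 2-D embedding."""
    embedding = embedding if embedding is not None else EmbeddingParams(seed=seed)
    features = build_features(track, geometry)
    labels = cluster_frames(features, k=k, seed=seed)
    semantic_map: dict[int, str] | None = None
    tie_broken = False
    if k == 4 and len(np.unique(labels)) == 4:
        sem = label_clusters(labels, features)
        semantic_map, tie_broken = sem.mapping, sem.tie_broken
    bouts, time_per = summarize_bouts(labels, track.fps, semantic_map)
    coords = embed_2d(features, embedding)
    return EthogramResult(
        labels=labels,
        frame_index=features.frame_index,
        k=k,
        semantic_map=semantic_map,
        tie_broken=tie_broken,
        bouts=bouts,
        time_per_behavior_s=time_per,
        embedding=coords,
        seed=seed,
        fps=track.fps,
    )
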