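"""Feature construction, clustering, semantic labeling, embedding, bouts."""

import numpy as np
import pytest

from roachtrack.ethogram import (
    EmbeddingParams,
    build_features,
    cluster_frames,
    embed_2d,
    label_clusters,
    run_ethogram,
    summarize_bouts,
)
from roachtrack.synthetic import SessionConfig, generate_session
from roachtrack.trackmetrics import DEFAULT_ARENA

from conftest import make_track


@pytest.fixture(scope="module")
def default_session():
    return generate_session(SessionConfig(seed=1))


@pytest.fixture(scope="module")
def default_features(default_session):
    return build_features(default_session.track, DEFAULT_ARENA)


class TestBuildFeatures:
    def test_stationary_track_zero_speed_columns(self, simple_arena):
        coords = np.tile([[50.0, 40.0], [60.0, 40.0]], (20, 1, 1))
        track = make_track(coords, fps=10.0)
        feats = build_features(track, simple_arena, standardize=False)
        speed_cols = [i for i, c in enumerate(feats.columns)
                      if c.startswith("speed:")]
        np.testing.assert_allclose(feats.values[:, speed_cols], 0.0)

    def test_standardized_columns_centered_unit_or_constant(
        self, default_features
    ):
        means = default_features.values.mean(axis=0)
        sds = default_features.values.std(axis=0)
        assert np.abs(means).max() < 1e-9
        assert np.all((np.abs(sds - 1) < 1e-9) | (sds == 0))

    def test_frames_with_missing_node_dropped(self, simple_arena):
        rng = np.random.default_rng(0)
        coords = rng.uniform(10, 390, size=(30, 2, 2))
        coords[5, 1, :] = np.nan
        track = make_track(coords, fps=10.0)
        feats = build_features(track, simple_arena)
        # frame 5 lacks a node; frame 4's speed also needs frame 5
        assert 5 not in feats.frame_index
        assert 4 not in feats.frame_index
        assert feats.values.shape[1] == 3 * 2

    def test_too_few_frames_rejected(self, simple_arena):
        track = make_track(np.zeros((1, 2, 2)), fps=10.0)
        with pytest.raises(ValueError):
            build_features(track, simple_arena)

    def test_destandardize_inverts(self, default_features):
        raw = default_features.destandardize()
        sd_safe = np.where(default_features.sds == 0, 1.0,
                           default_features.sds)
        back = (raw - default_features.means) / sd_safe
        np.testing.assert_allclose(back, default_features.values, atol=1e-9)


class _FakeFeatures:
    """Minimal FeatureMatrix stand-in for clustering unit tests."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    @property
    def n_rows(self):
        return self.values.shape[0]


class TestClusterFrames:
    def test_separable_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(40, 3))
        b = rng.normal(5, 0.1, size=(40, 3))
        labels = cluster_frames(_FakeFeatures(np.vstack([a, b])), k=2, seed=1)
        assert len(set(labels[:40])) == 1
        assert len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_rows_zero_inertia(self):
        values = np.arange(12, dtype=float).reshape(4, 3)
        labels = cluster_frames(_FakeFeatures(values), k=4, seed=0)
        assert len(set(labels)) == 4

    def test_duplicate_rows_co_clustered(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 4))
        values = np.vstack([base, base[3]])  # row 3 duplicated at the end
        labels = cluster_frames(_FakeFeatures(values), k=3, seed=0)
        # brute-force nearest-centroid check on the final partition
        cents = np.array([values[labels == c].mean(0) for c in range(3)])
        nearest = np.argmin(
            ((values[:, None, :] - cents[None]) ** 2).sum(-1), axis=1
        )
        assert labels[3] == labels[-1] == nearest[3]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_frames(_FakeFeatures(np.zeros((2, 2))), k=4, seed=0)

    def test_deterministic_under_seed(self, default_features):
        a = cluster_frames(default_features, k=4, seed=42)
        b = cluster_frames(default_features, k=4, seed=42)
        np.testing.assert_array_equal(a, b)


class TestLabelClusters:
    def test_recovers_all_four_behaviors(self, default_session,
                                         default_features):
        labels = cluster_frames(default_features, k=4, seed=42)
        sem = label_clusters(labels, default_features)
        assert sorted(sem.mapping.values()) == sorted(
            ["resting", "scurrying", "left leg movement",
             "right leg movement"]
        )
        assert not sem.degenerate
        pred = np.array([sem.mapping[int(c)] for c in labels])
        truth = default_session.truth_state_names[
            default_features.frame_index
        ]
        assert (pred == truth).mean() >= 0.9

    def test_wrong_k_rejected(self, default_features):
        labels = cluster_frames(default_features, k=3, seed=42)
        with pytest.raises(ValueError, match="raw cluster ids"):
            label_clusters(labels, default_features)

    def test_all_resting_session_flagged_degenerate(self):
        # force a session that never leaves resting
        from roachtrack.synthetic import RegimeParams, default_regimes

        regs = default_regimes()
        regs["resting"] = RegimeParams(0.05, 0.02, 0.02, "none", 0.999999)
        ds = generate_session(SessionConfig(duration_s=30.0, fps=30.0,
                                            seed=5, regimes=regs))
        assert (ds.truth_states == 0).all()
        feats = build_features(ds.track, DEFAULT_ARENA)
        labels = cluster_frames(feats, k=4, seed=42)
        sem = label_clusters(labels, feats)
        assert sem.degenerate


class TestEmbed2D:
    def test_pca_exact_planar_data(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 5))
        weights = rng.normal(size=(50, 2))
        values = weights @ basis  # rank-2 data in 5-D
        emb = embed_2d(_FakeFeatures(values), EmbeddingParams(method="pca"))
        # projection retains all variance: reconstruction error ~ 0
        total = (values - values.mean(0)).var(axis=0).sum()
        kept = emb.var(axis=0).sum()
        assert kept == pytest.approx(total, rel=1e-9)

    def test_pca_component_variance_ordering(self, default_features):
        emb = embed_2d(default_features, EmbeddingParams(method="pca"))
        v = emb.var(axis=0)
        assert v[0] >= v[1]

    def test_pca_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 4))
        emb = embed_2d(_FakeFeatures(values), EmbeddingParams(method="pca"))
        centered = values - values.mean(0)
        evals, evecs = np.linalg.eigh(centered.T @ centered / 5)
        oracle = centered @ evecs[:, ::-1][:, :2]
        for j in range(2):  # axes defined up to sign
            assert (
                np.allclose(emb[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(emb[:, j], -oracle[:, j], atol=1e-8)
            )

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(_FakeFeatures(np.zeros((2, 3))),
                     EmbeddingParams(method="pca"))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingParams(method="tsne")
        with pytest.raises(ValueError):
            EmbeddingParams(min_dist=2.0, spread=1.0)

    def test_umap_smoke(self):
        rng = np.random.default_rng(0)
        values = np.vstack(
            [rng.normal(0, 0.3, (40, 5)), rng.normal(4, 0.3, (40, 5))]
        )
        emb = embed_2d(
            _FakeFeatures(values),
            EmbeddingParams(method="umap", n_neighbors=10, seed=42),
        )
        assert emb.shape == (80, 2)
        assert np.isfinite(emb).all()


class TestBouts:
    def test_run_length_encoding(self):
        bouts, time_per = summarize_bouts(np.array([0, 0, 1, 1, 1, 0]),
                                          fps=2.0)
        assert bouts == [(0, 2, 0), (2, 5, 1), (5, 6, 0)]
        assert time_per == {"0": 1.5, "1": 1.5}

    def test_single_label_session(self):
        bouts, _ = summarize_bouts(np.zeros(7, dtype=int), fps=1.0)
        assert bouts == [(0, 7, 0)]

    def test_time_conservation_random_labels(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=333)
        bouts, time_per = summarize_bouts(labels, fps=30.0)
        assert sum(time_per.values()) == pytest.approx(333 / 30.0)
        assert sum(e - s for s, e, _ in bouts) == 333
        assert all(
            bouts[i][2] != bouts[i + 1][2] for i in range(len(bouts) - 1)
        )

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            summarize_bouts(np.array([]), fps=1.0)


class TestEndToEnd:
    def test_run_ethogram_deterministic(self, default_session):
        a = run_ethogram(default_session.track, DEFAULT_ARENA, seed=42)
        b = run_ethogram(default_session.track, DEFAULT_ARENA, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.embedding, b.embedding)
        assert a.semantic_map == b.semantic_map
        assert sum(a.time_per_behavior_s.values()) == pytest.approx(
            a.labels.size / a.fps
        )
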