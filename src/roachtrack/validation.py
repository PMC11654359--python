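"""End-to-end validation studies run on the synthetic generator.

These routines exercise the full pipeline (simulate -> score -> compare)
under known ground truth: exact occupancy recovery on noiseless sessions,
ethogram recovery at generator defaults, Type-I error calibration of the
gated comparison tree under a null cohort, and power/direction for the
port-aversion contrast under the study's 3 x 6 x 14-day design.

Simulated sessions here use the 3,600-frame variant of the 2-minute session
(120 s at 30 fps) except where noted; ethogram recovery uses the generator's
60 fps default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import stats as st
from .ethogram import build_features, cluster_frames, label_clusters
from .synthetic import SessionConfig, generate_cohort, generate_session
from .trackmetrics import DEFAULT_ARENA, score_occupancy

__all__ = [
    "occupancy_recovery",
    "ethogram_recovery",
    "null_rejection_rate",
    "aversion_detection_rate",
]


def _subseeds(seed: int, key: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def occupancy_recovery(n_sessions: int = 100, seed: int = 0) -> dict:
    """Noiseless sessions: conservation and exact truth recovery.

    Returns the number of sessions violating the seconds-conservation
    identity and the number of seconds (out of all scored) where the
    occupancy scorer disagrees with generator ground truth.
    """
    violations = 0
    mismatched = 0
    total_seconds = 0
    for s in _subseeds(seed, 1, n_sessions):
        cfg = SessionConfig(fps=30.0, seed=s, noise_sd_px=0.0,
                            missing_rate=0.0)
        ds = generate_session(cfg)
        occ = score_occupancy(ds.track, DEFAULT_ARENA)
        total = sum(occ.seconds_per_zone.values()) + occ.missing_seconds
        if total != occ.duration_s or occ.duration_s != 120:
            violations += 1
        mismatched += int((occ.per_second != ds.truth_occupancy).sum())
        total_seconds += occ.duration_s
    return {
        "n_sessions": n_sessions,
        "conservation_violations": violations,
        "mismatched_seconds": mismatched,
        "total_seconds": total_seconds,
    }


def ethogram_recovery(n_sessions: int = 5, seed: int = 0,
                      k_seed: int = 42) -> dict:
    """Mean frame-wise agreement of semantic labels with generator truth."""
    agreements = []
    for s in _subseeds(seed, 2, n_sessions):
        ds = generate_session(SessionConfig(seed=s))
        feats = build_features(ds.track, DEFAULT_ARENA)
        labels = cluster_frames(feats, k=4, seed=k_seed)
        sem = label_clusters(labels, feats)
        pred = np.array([sem.mapping[int(c)] for c in labels])
        truth = ds.truth_state_names[feats.frame_index]
        agreements.append(float((pred == truth).mean()))
    return {
        "n_sessions": n_sessions,
        "per_session": agreements,
        "mean_agreement": float(np.mean(agreements)),
    }


def _port_time_samples(
    rep_seed: int, effects: dict[str, float], days: int
) -> list[st.GroupSample]:
    """Per-animal port-zone seconds (averaged across days) by group."""
    base = SessionConfig(fps=30.0, seed=rep_seed)
    per_animal: dict[tuple[str, int], list[float]] = {}
    for ds in generate_cohort(base, n_per_group=6, group_effects=effects,
                              days=days):
        occ = score_occupancy(ds.track, DEFAULT_ARENA)
        per_animal.setdefault((ds.group, ds.animal), []).append(
            occ.seconds_per_zone[DEFAULT_ARENA.port_zone]
        )
    groups: dict[str, list[float]] = {}
    for (g, _a), vals in per_animal.items():
        groups.setdefault(g, []).append(float(np.mean(vals)))
    return [st.GroupSample(g, np.asarray(v)) for g, v in groups.items()]


def null_rejection_rate(n_reps: int = 200, seed: int = 0,
                        days: int = 3, alpha: float = 0.05) -> dict:
    """Fraction of pairwise tests rejected under a no-effect cohort.

    All three groups share port_bias = 0; the full gated pipeline runs on
    port-zone time and the adjusted pairwise rejections are pooled.
    """
    effects = {"air": 0.0, "vehicle": 0.0, "nicotine": 0.0}
    rejected = 0
    total = 0
    for s in _subseeds(seed, 3, n_reps):
        report = st.gated_compare(_port_time_samples(s, effects, days),
                                  alpha=alpha)
        rejected += len(report.significant_pairs())
        total += len(report.pairwise)
    return {
        "n_reps": n_reps,
        "days": days,
        "rejection_rate": rejected / total,
        "n_pairwise_tests": total,
    }


def aversion_detection_rate(n_reps: int = 50, seed: int = 0,
                            days: int = 14, alpha: float = 0.05) -> dict:
    """Power to flag vehicle < air for port-zone time under port aversion.

    Vehicle animals carry port_bias -0.6 (aversion), nicotine +0.2, air 0;
    a replicate counts as detected when the air-vehicle pair is significant
    after adjustment and the vehicle group's mean is lower.
    """
    effects = {"air": 0.0, "vehicle": -0.6, "nicotine": 0.2}
    detected = 0
    for s in _subseeds(seed, 4, n_reps):
        report = st.gated_compare(_port_time_samples(s, effects, days),
                                  alpha=alpha)
        for pair in report.pairwise:
            if set(pair.pair) == {"air", "vehicle"}:
                diff = (pair.mean_diff if pair.pair[0] == "vehicle"
                        else -pair.mean_diff)
                if pair.p_adj < alpha and diff < 0:
                    detected += 1
    return {
        "n_reps": n_reps,
        "days": days,
        "detection_rate": detected / n_reps,
    }
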