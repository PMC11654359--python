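"""Figure rendering for session and cohort reports.

Every figure has a machine-readable CSV/JSON twin written by the CLI; these
functions only draw what those files contain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .ethogram import EthogramResult
from .pose_io import PoseTrack
from .trackmetrics import ArenaGeometry, zones_of_x

__all__ = [
    "plot_tracks_by_quadrant",
    "plot_velocity_track",
    "plot_heatmap",
    "plot_embedding",
    "plot_behavior_bars",
]


def _node_path(track: PoseTrack, node: str) -> np.ndarray:
    xy = track.node_xy(node)
    return xy[~np.isnan(xy[:, 0])]


def plot_tracks_by_quadrant(
    track: PoseTrack, geometry: ArenaGeometry, node: str | None = None
):
    """Body-anchor trajectory colored by quadrant, with zone boundaries."""
    node = node or track.skeleton.anchor_body
    xy = _node_path(track, node)
    zones = zones_of_x(xy[:, 0], geometry)
    fig, ax = plt.subplots(figsize=(10, 2.5))
    for z in range(1, geometry.n_zones + 1):
        sel = zones == z
        ax.plot(xy[sel, 0], xy[sel, 1], ".", ms=1, label=f"Q{z}")
    for edge in geometry.zone_edges_px:
        ax.axvline(edge, color="k", lw=0.5)
    ax.set_xlim(geometry.x_min_px, geometry.x_max_px)
    ax.set_ylim(geometry.y_max_px, geometry.y_min_px)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.legend(markerscale=8, fontsize=7, ncol=geometry.n_zones)
    fig.tight_layout()
    return fig


def plot_velocity_track(
    track: PoseTrack, geometry: ArenaGeometry, node: str | None = None
):
    """Trajectory colored by instantaneous speed (cm/s)."""
    node = node or track.skeleton.anchor_body
    xy = track.node_xy(node)
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = disp / geometry.pixels_per_cm * track.fps
    ok = ~np.isnan(speed)
    fig, ax = plt.subplots(figsize=(10, 2.5))
    sc = ax.scatter(xy[:-1][ok, 0], xy[:-1][ok, 1], c=speed[ok], s=2,
                    cmap="viridis")
    fig.colorbar(sc, ax=ax, label="speed (cm/s)")
    ax.set_xlim(geometry.x_min_px, geometry.x_max_px)
    ax.set_ylim(geometry.y_max_px, geometry.y_min_px)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.tight_layout()
    return fig


def plot_heatmap(grid: np.ndarray, geometry: ArenaGeometry):
    """Occupancy heat map (warmer = more frames spent)."""
    fig, ax = plt.subplots(figsize=(10, 2.5))
    im = ax.imshow(
        grid,
        origin="upper",
        aspect="auto",
        cmap="inferno",
        extent=(geometry.x_min_px, geometry.x_max_px,
                geometry.y_max_px, geometry.y_min_px),
    )
    fig.colorbar(im, ax=ax, label="frames")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.tight_layout()
    return fig


def plot_embedding(result: EthogramResult):
    """2-D cluster embedding scatter, colored by behavior."""
    fig, ax = plt.subplots(figsize=(5, 5))
    sem = result.semantic_labels
    if sem is not None:
        for name in sorted(set(sem)):
            sel = sem == name
            ax.scatter(result.embedding[sel, 0], result.embedding[sel, 1],
                       s=3, label=name)
        ax.legend(fontsize=7, markerscale=4)
    else:
        ax.scatter(result.embedding[:, 0], result.embedding[:, 1],
                   c=result.labels, s=3, cmap="tab10")
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    fig.tight_layout()
    return fig


def plot_behavior_bars(time_per_behavior: dict[str, dict[str, float]]):
    """Stacked time-per-behavior bars, one bar per group/session."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bars = list(time_per_behavior)
    behaviors = sorted({b for d in time_per_behavior.values() for b in d})
    bottom = np.zeros(len(bars))
    for beh in behaviors:
        heights = np.array(
            [time_per_behavior[k].get(beh, 0.0) for k in bars]
        )
        ax.bar(bars, heights, bottom=bottom, label=beh)
        bottom += heights
    ax.set_ylabel("time (s)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
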