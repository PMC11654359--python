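"""Spatial metrics from pose tracks: zone occupancy, kinematics, heat maps.

The assay arena is a straight runway split along its long (x) axis into
``n_zones`` equal quadrants; an exposure port sits in ``port_zone``. Zone
occupancy replicates manual scoring: each whole second of video is assigned
the quadrant that contains the head anchor for the majority of that second's
frames. Distance and velocity use the metathorax (central body) anchor and a
single pixels-per-centimeter calibration derived from the runway's known
physical length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pose_io import PoseTrack

__all__ = [
    "ArenaGeometry",
    "DEFAULT_ARENA",
    "ZoneOccupancySeries",
    "KinematicsResult",
    "assign_zone",
    "zones_of_x",
    "majority_zone_per_second",
    "score_occupancy",
    "compute_kinematics",
    "occupancy_heatmap",
]

MISSING_ZONE = 0  # per-second label for seconds with no detected anchor

IN_TO_CM = 2.54


@dataclass(frozen=True)
class ArenaGeometry:
    """Runway rectangle in image pixels plus its physical calibration.

    Defaults describe a 24 x 4 inch (60.96 x 10.16 cm) linear track with four
    equal quadrants and the exposure port in quadrant 4. ``pixels_per_cm`` is
    derived from the long axis only (isotropic pixels assumed).
    """

    x_min_px: float
    x_max_px: float
    y_min_px: float
    y_max_px: float
    length_cm: float = 24 * IN_TO_CM
    width_cm: float = 4 * IN_TO_CM
    n_zones: int = 4
    port_zone: int = 4

    def __post_init__(self) -> None:
        if not (self.x_max_px > self.x_min_px and self.y_max_px > self.y_min_px):
            raise ValueError("arena extents must be non-degenerate")
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("physical dimensions must be positive")
        if self.n_zones < 2:
            raise ValueError("need at least 2 zones")
        if not 1 <= self.port_zone <= self.n_zones:
            raise ValueError("port_zone out of range")

    @property
    def pixels_per_cm(self) -> float:
        return (self.x_max_px - self.x_min_px) / self.length_cm

    @property
    def zone_edges_px(self) -> np.ndarray:
        """n_zones + 1 boundaries partitioning [x_min_px, x_max_px)."""
        return np.linspace(self.x_min_px, self.x_max_px, self.n_zones + 1)

    def x_to_cm(self, x_px: np.ndarray) -> np.ndarray:
        return (np.asarray(x_px) - self.x_min_px) / self.pixels_per_cm

    def y_to_cm(self, y_px: np.ndarray) -> np.ndarray:
        return (np.asarray(y_px) - self.y_min_px) / self.pixels_per_cm


#: Calibration matching a 1080p top-down recording of the default runway
#: (~29.5 px/cm; 1800 px of track length, 300 px of width).
DEFAULT_ARENA = ArenaGeometry(
    x_min_px=60.0, x_max_px=1860.0, y_min_px=390.0, y_max_px=690.0
)


def zones_of_x(x_px: np.ndarray, geometry: ArenaGeometry) -> np.ndarray:
    """Vector zone assignment; NaN maps to MISSING_ZONE (0).

    Positions left of the runway clamp to zone 1, at/right of the end clamp
    to ``n_zones``; each zone is a half-open interval [edge_k, edge_{k+1}).
    """
    x = np.asarray(x_px, dtype=np.float64)
    width = (geometry.x_max_px - geometry.x_min_px) / geometry.n_zones
    with np.errstate(invalid="ignore"):
        k = np.floor((x - geometry.x_min_px) / width).astype(np.int64, copy=False)
        zones = np.clip(k + 1, 1, geometry.n_zones)
    zones = np.where(np.isnan(x), MISSING_ZONE, zones)
    return zones.astype(np.int64)


def assign_zone(x_px: float, geometry: ArenaGeometry) -> int:
    """Zone label (1..n_zones) of a single x pixel coordinate."""
    if not np.isfinite(x_px):
        raise ValueError(f"x must be finite, got {x_px!r}")
    return int(zones_of_x(np.array([x_px]), geometry)[0])


@dataclass
class ZoneOccupancySeries:
    """Per-second quadrant labels and their per-quadrant totals.

    ``per_second[s]`` is the zone (1..n_zones) occupied during second ``s``,
    or 0 when the anchor was never detected in that second. The conservation
    identity ``sum(seconds_per_zone.values()) + missing_seconds ==
    duration_s`` holds for every series.
    """

    per_second: np.ndarray
    n_zones: int

    def __post_init__(self) -> None:
        self.per_second = np.asarray(self.per_second, dtype=np.int64)
        if self.per_second.size and not (
            (self.per_second >= 0) & (self.per_second <= self.n_zones)
        ).all():
            raise ValueError("zone labels out of range")

    @property
    def duration_s(self) -> int:
        return int(self.per_second.size)

    @property
    def seconds_per_zone(self) -> dict[int, int]:
        counts = np.bincount(self.per_second, minlength=self.n_zones + 1)
        return {z: int(counts[z]) for z in range(1, self.n_zones + 1)}

    @property
    def missing_seconds(self) -> int:
        return int(np.count_nonzero(self.per_second == MISSING_ZONE))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"second": np.arange(self.duration_s), "zone": self.per_second}
        )


def majority_zone_per_second(
    zone_per_frame: np.ndarray, fps: float, n_zones: int
) -> np.ndarray:
    """Collapse per-frame zone labels to whole-second labels by majority vote.

    Second ``s`` covers frames ``floor(s*fps) .. floor((s+1)*fps) - 1``. Only
    frames with a detected anchor (label > 0) vote; a second with no votes is
    labeled 0. Ties go to the previous second's label when it is among the
    tied zones, else to the lowest tied zone index. A trailing partial second
    is ignored.
    """
    zone_per_frame = np.asarray(zone_per_frame)
    n_frames = zone_per_frame.size
    n_seconds = int(np.floor(n_frames / fps))
    labels = np.zeros(n_seconds, dtype=np.int64)
    prev = 0
    for s in range(n_seconds):
        lo = int(np.floor(s * fps))
        hi = int(np.floor((s + 1) * fps))
        votes = zone_per_frame[lo:hi]
        counts = np.bincount(votes[votes > 0], minlength=n_zones + 1)
        if counts.sum() == 0:
            labels[s] = MISSING_ZONE
            continue
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if prev in tied:
            labels[s] = prev
        else:
            labels[s] = int(tied[0])
        prev = labels[s]
    return labels


def score_occupancy(
    track: PoseTrack,
    geometry: ArenaGeometry,
    anchor: str | None = None,
) -> ZoneOccupancySeries:
    """Per-second quadrant occupancy of the anchor node (default: head).

    Mirrors manual 1-s-interval scoring: each whole second is labeled with
    the quadrant holding the anchor for the majority of its detected frames.
    """
    anchor = anchor if anchor is not None else track.skeleton.anchor_head
    x = track.node_xy(anchor)[:, 0]  # raises KeyError for unknown anchor
    zones = zones_of_x(x, geometry)
    per_second = majority_zone_per_second(zones, track.fps, geometry.n_zones)
    return ZoneOccupancySeries(per_second=per_second, n_zones=geometry.n_zones)


@dataclass
class KinematicsResult:
    """Per-node speeds plus distance traveled per quadrant.

    ``node_speed_cm_s`` has one row per frame step (n_frames - 1) and one
    column per node; a step with either endpoint missing is NaN. Distance is
    accumulated from the distance node's per-step displacement into the zone
    of the step's starting frame.
    """

    node_speed_cm_s: pd.DataFrame
    distance_per_zone_cm: dict[int, float]
    total_distance_cm: float
    mean_speed_cm_s: pd.Series
    overall_mean_speed_cm_s: float
    distance_node: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"distance_zone_{z}_cm", "value": v}
            for z, v in sorted(self.distance_per_zone_cm.items())
        ]
        rows.append({"metric": "total_distance_cm", "value": self.total_distance_cm})
        rows.append(
            {"metric": "overall_mean_speed_cm_s",
             "value": self.overall_mean_speed_cm_s}
        )
        rows += [
            {"metric": f"mean_speed_{n}_cm_s", "value": v}
            for n, v in self.mean_speed_cm_s.items()
        ]
        return pd.DataFrame(rows)


def compute_kinematics(
    track: PoseTrack,
    geometry: ArenaGeometry,
    distance_node: str | None = None,
) -> KinematicsResult:
    """Speeds for every node and distance per quadrant for the body anchor.

    Speed at step i is the Euclidean displacement between frames i and i+1,
    converted to cm via the arena calibration and multiplied by fps.
    """
    distance_node = (
        distance_node if distance_node is not None else track.skeleton.anchor_body
    )
    j_dist = track.skeleton.index(distance_node)
    ppcm = geometry.pixels_per_cm
    disp_px = np.linalg.norm(np.diff(track.coords, axis=0), axis=2)
    speed = disp_px / ppcm * track.fps  # (n_frames-1, n_nodes), NaN-propagating
    speed_df = pd.DataFrame(speed, columns=list(track.skeleton.node_names))

    step_cm = disp_px[:, j_dist] / ppcm
    start_zone = zones_of_x(track.coords[:-1, j_dist, 0], geometry)
    valid = ~np.isnan(step_cm) & (start_zone > 0)
    dist = {z: 0.0 for z in range(1, geometry.n_zones + 1)}
    if valid.any():
        sums = np.bincount(
            start_zone[valid], weights=step_cm[valid], minlength=geometry.n_zones + 1
        )
        for z in range(1, geometry.n_zones + 1):
            dist[z] = float(sums[z])
    total = float(sum(dist.values()))

    with np.errstate(invalid="ignore"):
        mean_per_node = pd.Series(
            np.nanmean(speed, axis=0) if speed.size else np.full(track.n_nodes, np.nan),
            index=list(track.skeleton.node_names),
        )
        overall = float(np.nanmean(speed)) if speed.size else float("nan")
    return KinematicsResult(
        node_speed_cm_s=speed_df,
        distance_per_zone_cm=dist,
        total_distance_cm=total,
        mean_speed_cm_s=mean_per_node,
        overall_mean_speed_cm_s=overall,
        distance_node=distance_node,
    )


def occupancy_heatmap(
    track: PoseTrack,
    geometry: ArenaGeometry,
    node: str | None = None,
    bins_x: int = 60,
    bins_y: int = 10,
) -> np.ndarray:
    """2-D grid of frame counts over the arena rectangle (rows = y bins).

    Points outside the rectangle (an anchor poking past a wall) are clipped
    onto the nearest edge bin so that the grid total equals the number of
    frames with the node present.
    """
    if bins_x < 1 or bins_y < 1:
        raise ValueError("bins must be >= 1")
    node = node if node is not None else track.skeleton.anchor_body
    xy = track.node_xy(node)
    ok = ~np.isnan(xy[:, 0])
    x = np.clip(xy[ok, 0], geometry.x_min_px,
                np.nextafter(geometry.x_max_px, -np.inf))
    y = np.clip(xy[ok, 1], geometry.y_min_px,
                np.nextafter(geometry.y_max_px, -np.inf))
    counts, _, _ = np.histogram2d(
        y, x,
        bins=(bins_y, bins_x),
        range=((geometry.y_min_px, geometry.y_max_px),
               (geometry.x_min_px, geometry.x_max_px)),
    )
    return counts.astype(np.int64)
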