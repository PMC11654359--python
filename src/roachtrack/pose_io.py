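"""Read, validate, repair and export pose-track data.

The on-disk layout follows the HDF5 analysis export of common animal
pose-estimation tools: a ``tracks`` dataset of shape
``(n_tracks, 2, n_nodes, n_frames)`` holding pixel x/y coordinates with NaN
for undetected nodes, and a ``node_names`` string dataset giving node order.
A flat CSV "datasheet" export (one row per frame) is provided for
spreadsheet-based workflows.

Coordinate convention: image pixels, origin at the top-left of the frame,
x increasing rightward along the runway's long axis, y increasing downward.
Frames are 0-indexed. A missing detection is a NaN in *both* members of the
(x, y) pair; a half-missing pair is invalid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SkeletonDef",
    "PoseTrack",
    "DEFAULT_NODE_NAMES",
    "default_skeleton",
    "read_pose_h5",
    "write_pose_h5",
    "export_datasheet",
    "import_datasheet",
    "fill_missing",
]

DEFAULT_FPS = 60.0

#: 27-node cockroach skeleton: head, antennae (base/mid/tip, both sides),
#: maxillary palps (base/tip, both sides), three axial body segments plus
#: anus, and the three leg pairs (joint/tip, both sides).
DEFAULT_NODE_NAMES: tuple[str, ...] = (
    "head",
    "antenna_base_L", "antenna_base_R",
    "antenna_mid_L", "antenna_mid_R",
    "antenna_tip_L", "antenna_tip_R",
    "palp_base_L", "palp_base_R",
    "palp_tip_L", "palp_tip_R",
    "prothorax",
    "metathorax",
    "abdomen",
    "anus",
    "fore_leg_joint_L", "fore_leg_joint_R",
    "fore_leg_tip_L", "fore_leg_tip_R",
    "mid_leg_joint_L", "mid_leg_joint_R",
    "mid_leg_tip_L", "mid_leg_tip_R",
    "hind_leg_joint_L", "hind_leg_joint_R",
    "hind_leg_tip_L", "hind_leg_tip_R",
)


class FormatError(ValueError):
    """A pose file does not conform to the expected HDF5 layout."""


def _infer_sides(node_names: Sequence[str]) -> dict[str, str]:
    sides = {}
    for name in node_names:
        if name.endswith("_L") or name.endswith("_l"):
            sides[name] = "left"
        elif name.endswith("_R") or name.endswith("_r"):
            sides[name] = "right"
        else:
            sides[name] = "midline"
    return sides


@dataclass(frozen=True)
class SkeletonDef:
    """Ordered node list plus the anatomical anchors the pipeline uses.

    ``anchor_head`` is the node used for zone-occupancy scoring;
    ``anchor_body`` (the metathorax, a stable central segment) is used for
    distance and velocity. ``limb_sides`` maps every node to
    ``left``/``right``/``midline``; sided leg nodes drive the semantic
    labeling of behavior clusters.
    """

    node_names: tuple[str, ...]
    anchor_head: str = "head"
    anchor_body: str = "metathorax"
    limb_sides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.node_names)
        object.__setattr__(self, "node_names", names)
        if len(names) == 0:
            raise ValueError("skeleton must have at least one node")
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        if any(not n for n in names):
            raise ValueError("node names must be non-empty")
        if self.anchor_head not in names:
            raise ValueError(f"anchor_head {self.anchor_head!r} not a node")
        if self.anchor_body not in names:
            raise ValueError(f"anchor_body {self.anchor_body!r} not a node")
        if not self.limb_sides:
            object.__setattr__(self, "limb_sides", _infer_sides(names))
        else:
            bad = set(self.limb_sides) - set(names)
            if bad:
                raise ValueError(f"limb_sides refers to unknown nodes: {sorted(bad)}")
            sides = dict(self.limb_sides)
            for n in names:
                sides.setdefault(n, "midline")
            object.__setattr__(self, "limb_sides", sides)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def nodes_on_side(self, side: str) -> list[str]:
        return [n for n in self.node_names if self.limb_sides[n] == side]

    def leg_nodes(self, side: str | None = None) -> list[str]:
        """Leg nodes, optionally restricted to one side."""
        legs = [n for n in self.node_names if "leg" in n]
        if side is None:
            return legs
        return [n for n in legs if self.limb_sides[n] == side]


def default_skeleton() -> SkeletonDef:
    """The 27-node cockroach skeleton with head/metathorax anchors."""
    return SkeletonDef(node_names=DEFAULT_NODE_NAMES)


@dataclass
class PoseTrack:
    """Per-frame (x, y) pixel coordinates for every skeleton node.

    ``coords`` has shape ``(n_frames, n_nodes, 2)``; missing detections are
    NaN in both coordinates of the pair.
    """

    video_id: str
    fps: float
    coords: np.ndarray
    skeleton: SkeletonDef

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_frames, n_nodes, 2)")
        if self.coords.shape[1] != self.skeleton.n_nodes:
            raise ValueError(
                f"coords has {self.coords.shape[1]} nodes but skeleton has "
                f"{self.skeleton.n_nodes}"
            )
        x_nan = np.isnan(self.coords[:, :, 0])
        y_nan = np.isnan(self.coords[:, :, 1])
        if np.any(x_nan != y_nan):
            raise ValueError("a node's x and y must be missing together")
        present = self.coords[~np.isnan(self.coords)]
        if not np.all(np.isfinite(present)):
            raise ValueError("non-missing coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.coords.shape[1])

    @property
    def present(self) -> np.ndarray:
        """Boolean (n_frames, n_nodes) mask of detected nodes."""
        return ~np.isnan(self.coords[:, :, 0])

    def node_xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinates of one node."""
        return self.coords[:, self.skeleton.index(name), :]


def _pair_nan(coords: np.ndarray) -> np.ndarray:
    """Force NaN pairs: if either coordinate is non-finite, blank both."""
    coords = np.array(coords, dtype=np.float64, copy=True)
    bad = ~np.isfinite(coords)
    either = bad.any(axis=-1)
    coords[either] = np.nan
    return coords


def read_pose_h5(
    path: str | Path,
    skeleton_override: SkeletonDef | None = None,
    default_fps: float = DEFAULT_FPS,
) -> PoseTrack:
    """Read a pose track from an HDF5 analysis export.

    Expects datasets ``tracks`` (n_tracks, 2, n_nodes, n_frames) and
    ``node_names``. Only the first track is read (single-animal assay).
    Frame rate is taken from the file's ``fps`` attribute when present,
    otherwise ``default_fps``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in ("tracks", "node_names"):
            if ds not in f:
                raise FormatError(f"{path}: missing dataset {ds!r}")
        raw = np.asarray(f["tracks"])
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in np.asarray(f["node_names"])
        ]
        fps = float(f.attrs.get("fps", default_fps))
        video_id = str(f.attrs.get("video_id", path.stem))
    if raw.ndim != 4 or raw.shape[1] != 2:
        raise FormatError(
            f"{path}: tracks must have shape (n_tracks, 2, n_nodes, n_frames), "
            f"got {raw.shape}"
        )
    if raw.shape[2] != len(names):
        raise FormatError(
            f"{path}: tracks has {raw.shape[2]} nodes but node_names lists "
            f"{len(names)}"
        )
    if skeleton_override is not None:
        if skeleton_override.n_nodes != len(names):
            raise ValueError(
                f"skeleton_override has {skeleton_override.n_nodes} nodes but "
                f"file has {len(names)}"
            )
        skeleton = skeleton_override
    else:
        anchor_head = "head" if "head" in names else names[0]
        anchor_body = "metathorax" if "metathorax" in names else names[-1]
        skeleton = SkeletonDef(
            node_names=tuple(names),
            anchor_head=anchor_head,
            anchor_body=anchor_body,
        )
    # (track0, xy, node, frame) -> (frame, node, xy)
    coords = _pair_nan(np.transpose(raw[0], (2, 1, 0)))
    return PoseTrack(video_id=video_id, fps=fps, coords=coords, skeleton=skeleton)


def write_pose_h5(track: PoseTrack, path: str | Path) -> Path:
    """Write a track in the HDF5 analysis-export layout (round-trippable)."""
    path = Path(path)
    # (frame, node, xy) -> (1, xy, node, frame)
    raw = np.transpose(track.coords, (2, 1, 0))[np.newaxis, ...]
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=raw)
        f.create_dataset(
            "node_names",
            data=np.array([n.encode() for n in track.skeleton.node_names]),
        )
        f.attrs["fps"] = track.fps
        f.attrs["video_id"] = track.video_id
    return path


def export_datasheet(track: PoseTrack, path: str | Path) -> Path:
    """Write a flat CSV: one row per frame, per-node x/y columns.

    Columns: ``video_id, frame, time_s`` then ``<node>_x, <node>_y`` for each
    node in skeleton order. Missing detections become empty cells.
    """
    path = Path(path)
    n = track.n_frames
    data: dict[str, object] = {
        "video_id": np.repeat(track.video_id, n),
        "frame": np.arange(n),
        "time_s": np.arange(n) / track.fps,
    }
    for j, name in enumerate(track.skeleton.node_names):
        data[f"{name}_x"] = track.coords[:, j, 0]
        data[f"{name}_y"] = track.coords[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def import_datasheet(
    path: str | Path,
    skeleton: SkeletonDef | None = None,
    fps: float | None = None,
) -> PoseTrack:
    """Rebuild a PoseTrack from a datasheet written by :func:`export_datasheet`.

    Frame rate is inferred from the ``time_s`` column unless given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    node_names = [c[:-2] for c in df.columns if c.endswith("_x")]
    if skeleton is None:
        anchor_head = "head" if "head" in node_names else node_names[0]
        anchor_body = "metathorax" if "metathorax" in node_names else node_names[-1]
        skeleton = SkeletonDef(tuple(node_names), anchor_head, anchor_body)
    if fps is None:
        if len(df) > 1:
            fps = float((len(df) - 1) / df["time_s"].iloc[-1])
        else:
            fps = DEFAULT_FPS
    coords = np.stack(
        [df[[f"{n}_x", f"{n}_y"]].to_numpy(dtype=np.float64) for n in node_names],
        axis=1,
    )
    video_id = str(df["video_id"].iloc[0]) if len(df) else path.stem
    return PoseTrack(video_id=video_id, fps=fps, coords=_pair_nan(coords),
                     skeleton=skeleton)


def fill_missing(track: PoseTrack, max_gap_frames: int) -> PoseTrack:
    """Linearly interpolate short interior gaps in each node's trajectory.

    Interior missing runs of length <= ``max_gap_frames`` are filled by
    linear interpolation between the flanking detections; longer runs and
    leading/trailing runs are left missing. Present values are never altered,
    and the operation is idempotent.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    coords = track.coords.copy()
    if max_gap_frames > 0 and track.n_frames > 0:
        for j in range(track.n_nodes):
            missing = np.isnan(coords[:, j, 0])
            if not missing.any() or missing.all():
                continue
            # run-length encode the missing mask
            d = np.diff(np.concatenate([[0], missing.astype(np.int8), [0]]))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                if s == 0 or e == len(missing):
                    continue  # leading/trailing runs stay missing
                if e - s > max_gap_frames:
                    continue
                left = coords[s - 1, j, :]
                right = coords[e, j, :]
                t = np.arange(1, e - s + 1) / (e - s + 1)
                coords[s:e, j, :] = left + t[:, None] * (right - left)
    return dataclasses.replace(track, coords=coords)
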