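import numpy as np
import pytest

from roachtrack.pose_io import PoseTrack, SkeletonDef
from roachtrack.trackmetrics import ArenaGeometry


@pytest.fixture
def simple_arena() -> ArenaGeometry:
    """400 px of track, 4 zones of 100 px, 10 px/cm."""
    return ArenaGeometry(
        x_min_px=0.0, x_max_px=400.0, y_min_px=0.0, y_max_px=80.0,
        length_cm=40.0, width_cm=8.0,
    )


@pytest.fixture
def two_node_skeleton() -> SkeletonDef:
    return SkeletonDef(("head", "metathorax"))


def make_track(
    coords: np.ndarray,
    fps: float = 10.0,
    skeleton: SkeletonDef | None = None,
    video_id: str = "test",
) -> PoseTrack:
    coords = np.asarray(coords, dtype=np.float64)
    if skeleton is None:
        names = tuple(f"n{i}" for i in range(coords.shape[1]))
        if coords.shape[1] == 1:
            skeleton = SkeletonDef(names, anchor_head="n0", anchor_body="n0")
        else:
            skeleton = SkeletonDef(
                names, anchor_head="n0", anchor_body=names[-1]
            )
    return PoseTrack(video_id=video_id, fps=fps, coords=coords,
                     skeleton=skeleton)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def constant_track(two_node_skeleton):
    """120 s at 10 fps, both nodes fixed at the center of zone 1."""
    coords = np.tile([[50.0, 40.0], [52.0, 40.0]], (1200, 1, 1))
    return make_track(coords, fps=10.0, skeleton=two_node_skeleton)
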