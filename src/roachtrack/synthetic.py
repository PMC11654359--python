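"""Synthetic linear-track locomotion sessions with known ground truth.

The generator emulates the assay's study conditions — a single cockroach
free-running for 2 minutes on a 24 x 4 inch runway recorded top-down — so
that every pipeline stage can be tested against known truth. Behavior is a
four-state first-order Markov chain (resting, scurrying, left leg movement,
right leg movement) with state-conditioned body kinematics; the body
centroid performs along-axis runs with wall reflection and an optional drift
toward (+) or away from (-) the exposure port; the 27 skeleton nodes ride on
the centroid with fixed anatomical offsets plus state-conditioned sinusoidal
limb oscillation. Observations add Gaussian pixel noise and independent
detection dropout. Everything is deterministic under the seed.

The generator is a test harness, not a calibrated biomechanical model: the
per-state speed distributions are stand-ins chosen so that the air-group
session-average body speed matches the ~2 cm/s scale the assay reports, and
must not be treated as study estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_io import PoseTrack, SkeletonDef, default_skeleton, write_pose_h5
from .trackmetrics import ArenaGeometry, DEFAULT_ARENA, majority_zone_per_second, zones_of_x

__all__ = [
    "STATE_NAMES",
    "RegimeParams",
    "default_regimes",
    "SessionConfig",
    "SyntheticDataset",
    "generate_session",
    "generate_cohort",
    "corrupt",
    "save_dataset",
    "write_cohort",
]

STATE_NAMES: tuple[str, ...] = (
    "resting",
    "scurrying",
    "left leg movement",
    "right leg movement",
)

GROUPS: tuple[str, ...] = ("air", "vehicle", "nicotine")


@dataclass(frozen=True)
class RegimeParams:
    """Kinematic parameters of one behavioral state.

    ``dwell`` is the Markov self-transition probability per frame;
    ``limb_side`` selects which legs oscillate (none/both/left/right) with
    amplitude ``limb_amp_cm``.
    """

    body_speed_mean: float  # cm/s
    body_speed_sd: float  # cm/s
    limb_amp_cm: float
    limb_side: str  # {none, both, left, right}
    dwell: float

    def __post_init__(self) -> None:
        if self.body_speed_mean < 0 or self.body_speed_sd < 0:
            raise ValueError("speeds must be >= 0")
        if not 0 < self.dwell < 1:
            raise ValueError("dwell must be in (0, 1)")
        if self.limb_side not in ("none", "both", "left", "right"):
            raise ValueError(f"bad limb_side {self.limb_side!r}")


def default_regimes() -> dict[str, RegimeParams]:
    """Default four-state regimes.

    Chosen so that (a) resting is the most common state, (b) scurrying body
    speed far exceeds resting, and (c) the stationary-mix session-average
    body speed is ~2 cm/s, the scale the assay reports for air-exposed
    animals (which also reproduces its ~240 cm of distance per 2-min
    session).
    """
    return {
        "resting": RegimeParams(0.05, 0.02, 0.02, "none", 0.993),
        "scurrying": RegimeParams(6.0, 0.6, 0.2, "both", 0.99),
        "left leg movement": RegimeParams(0.3, 0.1, 0.8, "left", 0.99),
        "right leg movement": RegimeParams(0.3, 0.1, 0.8, "right", 0.99),
    }


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to simulate one session deterministically."""

    duration_s: float = 120.0
    fps: float = 60.0
    arena: ArenaGeometry = DEFAULT_ARENA
    skeleton: SkeletonDef = field(default_factory=default_skeleton)
    regimes: Mapping[str, RegimeParams] = field(default_factory=default_regimes)
    port_bias: float = 0.0  # -1 (full aversion) .. +1 (full attraction)
    noise_sd_px: float = 0.25
    missing_rate: float = 0.01
    seed: int = 0
    limb_freq_hz: float = 4.0
    heading_flip_prob: float = 0.02  # per-frame chance of re-choosing heading

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if not -1 <= self.port_bias <= 1:
            raise ValueError("port_bias must lie in [-1, 1]")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        missing = set(STATE_NAMES) - set(self.regimes)
        if missing:
            raise ValueError(f"regimes missing states: {sorted(missing)}")
        if (
            self.regimes["scurrying"].body_speed_mean
            <= self.regimes["resting"].body_speed_mean
        ):
            raise ValueError("scurrying must be faster than resting")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class SyntheticDataset:
    """A simulated session: observed track plus its ground truth."""

    track: PoseTrack
    truth_occupancy: np.ndarray  # per-second zone labels (1..n_zones)
    truth_states: np.ndarray  # per-frame state index into STATE_NAMES
    group: str = "air"
    animal: int = 0
    day: int = 0
    config: SessionConfig | None = None

    @property
    def truth_state_names(self) -> np.ndarray:
        return np.array(STATE_NAMES, dtype=object)[self.truth_states]


# Fixed anatomical node offsets from the metathorax, in cm, for the default
# skeleton (animal ~7 cm long facing +x; y offsets are lateral).
_BASE_OFFSETS_CM: dict[str, tuple[float, float]] = {
    "head": (2.5, 0.0),
    "antenna_base_L": (2.8, -0.3), "antenna_base_R": (2.8, 0.3),
    "antenna_mid_L": (4.0, -1.0), "antenna_mid_R": (4.0, 1.0),
    "antenna_tip_L": (5.2, -1.8), "antenna_tip_R": (5.2, 1.8),
    "palp_base_L": (2.6, -0.2), "palp_base_R": (2.6, 0.2),
    "palp_tip_L": (3.2, -0.5), "palp_tip_R": (3.2, 0.5),
    "prothorax": (1.5, 0.0),
    "metathorax": (0.0, 0.0),
    "abdomen": (-1.5, 0.0),
    "anus": (-2.5, 0.0),
    "fore_leg_joint_L": (1.2, -1.2), "fore_leg_joint_R": (1.2, 1.2),
    "fore_leg_tip_L": (1.8, -2.0), "fore_leg_tip_R": (1.8, 2.0),
    "mid_leg_joint_L": (0.0, -1.3), "mid_leg_joint_R": (0.0, 1.3),
    "mid_leg_tip_L": (-0.3, -2.2), "mid_leg_tip_R": (-0.3, 2.2),
    "hind_leg_joint_L": (-1.3, -1.4), "hind_leg_joint_R": (-1.3, 1.4),
    "hind_leg_tip_L": (-1.8, -2.4), "hind_leg_tip_R": (-1.8, 2.4),
}


def _node_offsets_cm(skeleton: SkeletonDef) -> np.ndarray:
    """(n_nodes, 2) rest offsets; unknown node names sit at the centroid."""
    return np.array(
        [_BASE_OFFSETS_CM.get(n, (0.0, 0.0)) for n in skeleton.node_names]
    )


def _simulate_states(
    n: int, regimes: Mapping[str, RegimeParams], rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov chain over the four states; starts resting."""
    dwell = np.array([regimes[s].dwell for s in STATE_NAMES])
    u = rng.random(n)
    # on leaving a state, the next state is uniform over the other three
    pick = rng.integers(0, 3, size=n)
    states = np.empty(n, dtype=np.int64)
    states[0] = 0
    others = [[j for j in range(4) if j != i] for i in range(4)]
    s = 0
    for i in range(1, n):
        if u[i] >= dwell[s]:
            s = others[s][pick[i]]
        states[i] = s
    return states


def _simulate_centroid(
    states: np.ndarray,
    config: SessionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Along-axis run-and-reflect motion plus a small lateral walk (cm)."""
    n = states.size
    regimes = config.regimes
    fps = config.fps
    length = config.arena.length_cm
    width = config.arena.width_cm
    means = np.array([regimes[s].body_speed_mean for s in STATE_NAMES])
    sds = np.array([regimes[s].body_speed_sd for s in STATE_NAMES])
    speed = np.maximum(means[states] + sds[states] * rng.standard_normal(n), 0.0)

    port_center = (
        (config.arena.port_zone - 0.5) / config.arena.n_zones * length
    )
    p_toward = 0.5 * (1.0 + config.port_bias)
    flip = rng.random(n) < config.heading_flip_prob
    u_dir = rng.random(n)

    # all subjects start in the middle of quadrant 1
    zone_w = length / config.arena.n_zones
    x = np.empty(n)
    x[0] = zone_w * 0.5
    heading = 1.0 if rng.random() < 0.5 else -1.0
    for i in range(1, n):
        if flip[i]:
            toward = 1.0 if x[i - 1] < port_center else -1.0
            heading = toward if u_dir[i] < p_toward else -toward
        xi = x[i - 1] + heading * speed[i] / fps
        if xi < 0.0:
            xi = -xi
            heading = 1.0
        elif xi > length:
            xi = 2.0 * length - xi
            heading = -1.0
        x[i] = xi

    # lateral wander: reflected random walk around the runway midline
    moving = means[states] > 0.1
    y_step_sd = np.where(moving, 0.15, 0.02) / fps
    dy = rng.standard_normal(n) * y_step_sd
    dy[0] = 0.0
    margin = 1.2
    lo, hi = margin, width - margin
    y_raw = (width / 2 - lo) + np.cumsum(dy)
    span = hi - lo
    y = lo + np.abs((y_raw + span) % (2 * span) - span)  # triangle-fold
    return x, y


def generate_session(config: SessionConfig) -> SyntheticDataset:
    """Simulate one session: observed PoseTrack plus ground truth.

    Ground-truth occupancy is the per-second majority-vote quadrant of the
    *noiseless* head trajectory, so with ``noise_sd_px = 0`` and
    ``missing_rate = 0`` the occupancy scorer reproduces it exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    arena = config.arena
    skeleton = config.skeleton
    n_nodes = skeleton.n_nodes

    states = _simulate_states(n, config.regimes, rng)
    cx, cy = _simulate_centroid(states, config, rng)

    offsets = _node_offsets_cm(skeleton)  # (n_nodes, 2)

    # state- and side-conditioned appendage oscillation per frame/node:
    # the active side's legs swing at full amplitude and its antenna/palp
    # nodes at half amplitude (unilateral grooming-like activity)
    legs = {
        side: [skeleton.index(nm) for nm in skeleton.leg_nodes(side)]
        for side in ("left", "right")
    }
    sensors = {
        side: [
            skeleton.index(nm)
            for nm in skeleton.nodes_on_side(side)
            if "leg" not in nm
        ]
        for side in ("left", "right")
    }
    # the metathorax anchor stays put (it is chosen for stability); the
    # other axial nodes rock with appendage activity
    midline = [
        skeleton.index(nm)
        for nm in skeleton.node_names
        if skeleton.limb_sides[nm] == "midline" and nm != skeleton.anchor_body
    ]
    amp = np.zeros((n, n_nodes))
    for si, sname in enumerate(STATE_NAMES):
        reg = config.regimes[sname]
        rows = states == si
        sides = {"both": ("left", "right"), "none": ()}.get(
            reg.limb_side, (reg.limb_side,)
        )
        for side in sides:
            amp[np.ix_(rows, legs[side])] = reg.limb_amp_cm
            amp[np.ix_(rows, sensors[side])] = 0.5 * reg.limb_amp_cm
        if sides:
            # appendage activity rocks the body axis slightly
            amp[np.ix_(rows, midline)] = 0.25 * reg.limb_amp_cm

    t = np.arange(n) / config.fps
    phase = rng.uniform(0, 2 * np.pi, size=n_nodes)
    # each appendage swings at its own rate (desynchronized gait components)
    freq = config.limb_freq_hz * rng.uniform(0.75, 1.25, size=n_nodes)
    osc = amp * np.sin(2 * np.pi * freq[None, :] * t[:, None] + phase)
    # oscillate along both axes with a fixed per-node direction mix
    mix = rng.uniform(0.4, 0.9, size=n_nodes)
    osc_x = osc * mix
    osc_y = osc * np.sqrt(1 - mix**2)

    # antennae and palps always tremble faintly (active sensing)
    sensor_idx = [
        skeleton.index(nm)
        for nm in skeleton.node_names
        if "antenna" in nm or "palp" in nm
    ]
    jitter = np.zeros((n, n_nodes, 2))
    if sensor_idx:
        jitter[:, sensor_idx, :] = rng.standard_normal((n, len(sensor_idx), 2)) * 0.01

    true_cm = np.empty((n, n_nodes, 2))
    true_cm[:, :, 0] = cx[:, None] + offsets[None, :, 0] + osc_x + jitter[:, :, 0]
    true_cm[:, :, 1] = cy[:, None] + offsets[None, :, 1] + osc_y + jitter[:, :, 1]

    ppcm = arena.pixels_per_cm
    true_px = np.empty_like(true_cm)
    true_px[:, :, 0] = arena.x_min_px + true_cm[:, :, 0] * ppcm
    true_px[:, :, 1] = arena.y_min_px + true_cm[:, :, 1] * ppcm

    obs = true_px + rng.standard_normal(true_px.shape) * config.noise_sd_px
    if config.missing_rate > 0:
        dropped = rng.random((n, n_nodes)) < config.missing_rate
        obs[dropped] = np.nan

    head_x_px = true_px[:, skeleton.index(skeleton.anchor_head), 0]
    truth_occ = majority_zone_per_second(
        zones_of_x(head_x_px, arena), config.fps, arena.n_zones
    )

    track = PoseTrack(
        video_id=f"synthetic-{config.seed}",
        fps=config.fps,
        coords=obs,
        skeleton=skeleton,
    )
    return SyntheticDataset(
        track=track,
        truth_occupancy=truth_occ,
        truth_states=states,
        config=config,
    )


def generate_cohort(
    base: SessionConfig,
    n_per_group: int,
    group_effects: Mapping[str, float],
    days: int = 1,
) -> list[SyntheticDataset]:
    """One dataset per animal x day, with group-level port bias applied.

    Per-session seeds are derived deterministically (and collision-free)
    from the base seed via ``numpy.random.SeedSequence`` spawn keys.
    """
    if n_per_group < 1 or days < 1:
        raise ValueError("n_per_group and days must be >= 1")
    unknown = set(group_effects) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group keys: {sorted(unknown)}")
    datasets: list[SyntheticDataset] = []
    for gi, (group, bias) in enumerate(group_effects.items()):
        for animal in range(n_per_group):
            for day in range(1, days + 1):
                ss = np.random.SeedSequence(
                    entropy=base.seed, spawn_key=(gi, animal, day)
                )
                child_seed = int(ss.generate_state(1)[0] % (2**31))
                cfg = dataclasses.replace(base, port_bias=bias, seed=child_seed)
                ds = generate_session(cfg)
                ds.group = group
                ds.animal = animal
                ds.day = day
                ds.track.video_id = f"{group}-a{animal}-d{day}"
                datasets.append(ds)
    return datasets


def corrupt(
    track: PoseTrack,
    missing_rate: float,
    noise_sd_px: float,
    seed: int,
) -> PoseTrack:
    """Add detection noise and dropout to an existing track."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if noise_sd_px < 0:
        raise ValueError("noise_sd_px must be >= 0")
    if missing_rate == 0 and noise_sd_px == 0:
        return dataclasses.replace(track, coords=track.coords.copy())
    rng = np.random.default_rng(seed)
    coords = track.coords.copy()
    if noise_sd_px > 0:
        coords = coords + rng.standard_normal(coords.shape) * noise_sd_px
    if missing_rate > 0:
        dropped = rng.random(coords.shape[:2]) < missing_rate
        coords[dropped] = np.nan
    return dataclasses.replace(track, coords=coords)


def save_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as pose HDF5 plus a truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = ds.track.video_id
    h5_path = write_pose_h5(ds.track, out_dir / f"{stem}.h5")
    truth_path = out_dir / f"{stem}.truth.json"
    truth = {
        "video_id": ds.track.video_id,
        "group": ds.group,
        "animal": ds.animal,
        "day": ds.day,
        "truth_occupancy": ds.truth_occupancy.tolist(),
        "truth_states": ds.truth_states.tolist(),
        "state_names": list(STATE_NAMES),
    }
    truth_path.write_text(json.dumps(truth))
    return {"track": h5_path, "truth": truth_path}


def write_cohort(
    datasets: Sequence[SyntheticDataset], out_dir: str | Path
) -> Path:
    """Write every dataset plus a cohort manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for ds in datasets:
        paths = save_dataset(ds, out_dir)
        rows.append(
            {
                "video_id": ds.track.video_id,
                "group": ds.group,
                "animal": ds.animal,
                "day": ds.day,
                "seed": ds.config.seed if ds.config else "",
                "track_path": paths["track"].name,
                "truth_path": paths["truth"].name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
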