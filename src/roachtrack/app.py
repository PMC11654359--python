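"""Command-line orchestration of the full analysis workflow.

Subcommands:

``analyze``   one or more pose files -> occupancy, kinematics, ethogram
``simulate``  synthetic session or cohort -> pose HDF5 + truth sidecars
``cohort``    manifest of analyzed sessions -> gated group comparisons
``agree``     manual vs automated seconds-per-quadrant tables -> agreement

A single YAML config holds the arena geometry, anchors, ethogram and
statistics blocks; CLI flags override the basics. Every figure written has a
machine-readable CSV/JSON twin holding the same numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import typer
import yaml

from . import ethogram as eth
from . import figures as figs
from . import stats as st
from . import synthetic as syn
from . import trackmetrics as tm
from .pose_io import PoseTrack, read_pose_h5

logger = logging.getLogger("roachtrack")

app = typer.Typer(add_completion=False, help=__doc__)


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed)."""

    arena: tm.ArenaGeometry = tm.DEFAULT_ARENA
    anchor_head: str | None = None
    anchor_body: str | None = None
    k: int = 4
    seed: int = 42
    embedding: eth.EmbeddingParams = field(default_factory=eth.EmbeddingParams)
    alpha: float = 0.05
    posthoc: str = "tukey"
    control: str | None = "air"
    inputs: list[Path] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)
    output_dir: Path = Path("roachtrack_out")


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "arena" in raw:
        cfg.arena = tm.ArenaGeometry(**raw["arena"])
    anchors = raw.get("anchors", {})
    cfg.anchor_head = anchors.get("head")
    cfg.anchor_body = anchors.get("body")
    etho = raw.get("ethogram", {})
    cfg.k = int(etho.get("k", cfg.k))
    cfg.seed = int(etho.get("seed", cfg.seed))
    if "embedding" in etho:
        cfg.embedding = eth.EmbeddingParams(seed=cfg.seed, **etho["embedding"])
    stats_blk = raw.get("stats", {})
    cfg.alpha = float(stats_blk.get("alpha", cfg.alpha))
    cfg.posthoc = stats_blk.get("posthoc", cfg.posthoc)
    cfg.control = stats_blk.get("control", cfg.control)
    cfg.inputs = [Path(p) for p in raw.get("input", [])]
    cfg.simulate = raw.get("simulate", {})
    if cfg.inputs and cfg.simulate:
        raise ValueError("config must give either input paths or a simulate "
                         "block, not both")
    if "output_dir" in raw:
        cfg.output_dir = Path(raw["output_dir"])
    return cfg


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "run.log", mode="a"),
    ]
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True)


def analyze_session(
    track: PoseTrack,
    cfg: RunConfig,
    out_dir: Path,
    make_figures: bool = False,
) -> dict[str, Path]:
    """Analyze one session and write its report bundle."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    occ = tm.score_occupancy(track, cfg.arena, anchor=cfg.anchor_head)
    p = out_dir / "occupancy.csv"
    occ.to_frame().to_csv(p, index=False)
    written["occupancy"] = p

    summary = pd.DataFrame(
        [{"zone": z, "seconds": s} for z, s in occ.seconds_per_zone.items()]
        + [{"zone": "missing", "seconds": occ.missing_seconds}]
    )
    p = out_dir / "occupancy_summary.csv"
    summary.to_csv(p, index=False)
    written["occupancy_summary"] = p

    kin = tm.compute_kinematics(track, cfg.arena, distance_node=cfg.anchor_body)
    p = out_dir / "kinematics.csv"
    kin.to_frame().to_csv(p, index=False)
    written["kinematics"] = p

    grid = tm.occupancy_heatmap(track, cfg.arena, node=cfg.anchor_body)
    p = out_dir / "heatmap.csv"
    np.savetxt(p, grid, fmt="%d", delimiter=",")
    written["heatmap"] = p

    result = eth.run_ethogram(
        track, cfg.arena, k=cfg.k, seed=cfg.seed, embedding=cfg.embedding
    )
    p = out_dir / "ethogram.json"
    result.to_json(p)
    written["ethogram"] = p
    p = out_dir / "ethogram_frames.csv"
    result.to_frame().to_csv(p, index=False)
    written["ethogram_frames"] = p

    if make_figures:
        for name, fig in (
            ("tracks_by_quadrant", figs.plot_tracks_by_quadrant(track, cfg.arena)),
            ("velocity_track", figs.plot_velocity_track(track, cfg.arena)),
            ("heatmap", figs.plot_heatmap(grid, cfg.arena)),
            ("embedding", figs.plot_embedding(result)),
        ):
            fp = out_dir / f"{name}.png"
            fig.savefig(fp, dpi=120)
            written[f"fig:{name}"] = fp
    logger.info("session %s -> %s", track.video_id, out_dir)
    return written


@app.command()
def analyze(
    config: Path = typer.Option(None, help="YAML run config"),
    input: list[Path] = typer.Option(None, "--input", help="pose HDF5 file(s)"),
    out: Path = typer.Option(None, help="output directory"),
    fps: float = typer.Option(None, help="override frame rate"),
    figures: bool = typer.Option(False, help="also render PNG figures"),
) -> None:
    """Analyze pose files: occupancy, kinematics, ethogram per session."""
    try:
        cfg = load_config(config)
    except Exception as exc:  # config errors fail before any computation
        typer.echo(f"config error: {exc}", err=True)
        raise typer.Exit(code=2)
    inputs = list(input) if input else cfg.inputs
    if not inputs:
        typer.echo("no input files given", err=True)
        raise typer.Exit(code=2)
    out_dir = out or cfg.output_dir
    _setup_logging(out_dir)
    for path in inputs:
        try:
            track = read_pose_h5(path)
        except (OSError, ValueError) as exc:
            logger.error("unreadable input %s: %s", path, exc)
            raise typer.Exit(code=1)
        if fps is not None:
            track = dataclasses.replace(track, fps=fps)
        analyze_session(track, cfg, out_dir / path.stem, make_figures=figures)


@app.command()
def simulate(
    config: Path = typer.Option(None, help="YAML config with simulate block"),
    out: Path = typer.Option(Path("simulated"), help="output directory"),
    seed: int = typer.Option(None, help="override base seed"),
) -> None:
    """Generate synthetic sessions (single or cohort) with truth sidecars."""
    cfg = load_config(config)
    blk = dict(cfg.simulate)
    cohort_blk = blk.pop("cohort", None)
    if seed is not None:
        blk["seed"] = seed
    session_cfg = syn.SessionConfig(arena=cfg.arena, **blk)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    if cohort_blk:
        datasets = syn.generate_cohort(
            session_cfg,
            n_per_group=int(cohort_blk.get("n_per_group", 6)),
            group_effects=cohort_blk.get(
                "group_effects", {"air": 0.0, "vehicle": -0.6, "nicotine": 0.2}
            ),
            days=int(cohort_blk.get("days", 1)),
        )
        manifest = syn.write_cohort(datasets, out)
        logger.info("wrote %d sessions, manifest %s", len(datasets), manifest)
    else:
        ds = syn.generate_session(session_cfg)
        paths = syn.save_dataset(ds, out)
        logger.info("wrote %s", paths["track"])


def _cohort_tables(
    manifest_path: Path, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal (averaged over days) occupancy and distance tables."""
    manifest = pd.read_csv(manifest_path)
    unknown = set(manifest["group"]) - set(syn.GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) in manifest: {sorted(unknown)}")
    base = manifest_path.parent
    rows = []
    for _, rec in manifest.iterrows():
        track = read_pose_h5(base / rec["track_path"])
        occ = tm.score_occupancy(track, cfg.arena, anchor=cfg.anchor_head)
        kin = tm.compute_kinematics(track, cfg.arena, distance_node=cfg.anchor_body)
        for z in range(1, cfg.arena.n_zones + 1):
            rows.append(
                {
                    "group": rec["group"],
                    "animal": rec["animal"],
                    "day": rec["day"],
                    "quadrant": z,
                    "seconds": occ.seconds_per_zone[z],
                    "distance_cm": kin.distance_per_zone_cm[z],
                    "mean_speed_cm_s": kin.overall_mean_speed_cm_s,
                }
            )
    per_session = pd.DataFrame(rows)
    per_animal = (
        per_session.groupby(["group", "animal", "quadrant"], as_index=False)
        .mean(numeric_only=True)
        .drop(columns=["day"])
    )
    return per_session, per_animal


def compare_between_groups(
    per_animal: pd.DataFrame, metric: str, cfg: RunConfig
) -> dict[int, st.ComparisonReport]:
    """Per-quadrant gated comparison of one metric across groups."""
    reports = {}
    for z, sub in per_animal.groupby("quadrant"):
        samples = [
            st.GroupSample(label=g, values=s[metric].to_numpy())
            for g, s in sub.groupby("group")
        ]
        if len(samples) < 2:
            raise ValueError("cohort comparison needs >= 2 groups")
        reports[int(z)] = st.gated_compare(
            samples, alpha=cfg.alpha, posthoc=cfg.posthoc, control=cfg.control
        )
    return reports


def compare_within_groups(
    per_animal: pd.DataFrame, metric: str, cfg: RunConfig
) -> dict[str, st.ComparisonReport]:
    """Per-group gated comparison of one metric across quadrants."""
    reports = {}
    for g, sub in per_animal.groupby("group"):
        samples = [
            st.GroupSample(label=f"Q{int(z)}", values=s[metric].to_numpy())
            for z, s in sub.groupby("quadrant")
        ]
        reports[str(g)] = st.gated_compare(
            samples, alpha=cfg.alpha, posthoc="tukey"
        )
    return reports


@app.command()
def cohort(
    manifest: Path = typer.Option(..., help="cohort manifest CSV"),
    config: Path = typer.Option(None, help="YAML run config"),
    out: Path = typer.Option(Path("cohort_out"), help="output directory"),
    hand: Path = typer.Option(None, help="optional hand-score CSV"),
) -> None:
    """Aggregate a cohort and run gated group comparisons."""
    cfg = load_config(config)
    _setup_logging(out)
    try:
        per_session, per_animal = _cohort_tables(manifest, cfg)
    except ValueError as exc:
        typer.echo(str(exc), err=True)
        raise typer.Exit(code=1)
    if per_animal["group"].nunique() < 2:
        typer.echo("cohort comparison requires at least 2 groups", err=True)
        raise typer.Exit(code=1)
    per_session.to_csv(out / "per_session.csv", index=False)
    per_animal.to_csv(out / "per_animal.csv", index=False)

    frames = []
    for metric in ("seconds", "distance_cm"):
        between = compare_between_groups(per_animal, metric, cfg)
        for z, rep in between.items():
            df = rep.to_frame()
            df.insert(0, "metric", metric)
            df.insert(1, "scope", f"between-groups:Q{z}")
            frames.append(df)
        within = compare_within_groups(per_animal, metric, cfg)
        for g, rep in within.items():
            df = rep.to_frame()
            df.insert(0, "metric", metric)
            df.insert(1, "scope", f"within-group:{g}")
            frames.append(df)
    # overall node velocity between groups (one value per animal)
    vel = per_animal.groupby(["group", "animal"], as_index=False)[
        "mean_speed_cm_s"
    ].mean()
    samples = [
        st.GroupSample(label=g, values=s["mean_speed_cm_s"].to_numpy())
        for g, s in vel.groupby("group")
    ]
    rep = st.gated_compare(samples, alpha=cfg.alpha, posthoc=cfg.posthoc,
                           control=cfg.control)
    df = rep.to_frame()
    df.insert(0, "metric", "mean_speed_cm_s")
    df.insert(1, "scope", "between-groups")
    frames.append(df)

    comparisons = pd.concat(frames, ignore_index=True)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    logger.info("wrote %s", out / "comparisons.csv")

    if hand is not None:
        machine = per_session.rename(columns={"day": "session"})
        machine = machine.assign(
            session=machine["group"].astype(str)
            + "-a" + machine["animal"].astype(str)
            + "-d" + machine["session"].astype(str)
        )[["session", "quadrant", "seconds"]]
        hand_df = pd.read_csv(hand)
        report = st.agreement(hand_df, machine)
        report.to_frame().to_csv(out / "agreement_cells.csv", index=False)
        (out / "agreement.json").write_text(
            json.dumps(
                {
                    "mean_abs_error_pct": report.mean_abs_error_pct,
                    "paired_t_stat": report.paired_t_stat,
                    "paired_t_p": report.paired_t_p,
                },
                indent=2,
            )
        )


@app.command()
def agree(
    hand: Path = typer.Option(..., help="hand-scored seconds CSV"),
    machine: Path = typer.Option(..., help="machine-scored seconds CSV"),
    duration: float = typer.Option(120.0, help="session length in seconds"),
    out: Path = typer.Option(Path("agreement.json"), help="output JSON"),
) -> None:
    """Compare manual and automated seconds-per-quadrant tables."""
    try:
        report = st.agreement(
            pd.read_csv(hand), pd.read_csv(machine), duration_s=duration
        )
    except ValueError as exc:
        typer.echo(str(exc), err=True)
        raise typer.Exit(code=1)
    payload = {
        "mean_abs_error_pct": report.mean_abs_error_pct,
        "paired_t_stat": report.paired_t_stat,
        "paired_t_p": report.paired_t_p,
        "duration_s": report.duration_s,
    }
    out.write_text(json.dumps(payload, indent=2))
    typer.echo(json.dumps(payload))


def main() -> None:  # console-script entry point
    app()


if __name__ == "__main__":
    main()
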