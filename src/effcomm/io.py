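"""File formats, run configuration, logging, and the end-to-end pipeline.

Formats
-------
- Path-spec JSON: ``{"origin": [x, y], "segments": [ids], "frames_per_primitive": k}``
- Trajectory CSV: header ``frame,x,y``, one row per frame, "." decimal.
- World JSON: ``{"bounds": [[xmin, ymin], [xmax, ymax]], "obstacles":
  [[[x, y], ...], ...], "goal_spacing": g, "grid_resolution": h}``; an
  obstacle may also be ``{"shell": ring, "holes": [rings]}`` when a lake
  fully encloses a passable corridor.
- Judgments CSV: ``participant,path_id,condition,rating`` with ratings in 1-7.
- Stimulus-set JSON: study, seed, and items (path id / segments / scale /
  condition / movement class).

All readers validate their schemas and name the offending field and line;
all writers round-trip losslessly at double precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis as an
from . import inverse_planner as ip
from . import path_space as ps
from . import synthetic_data as sd

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_pathspec_json",
    "write_pathspec_json",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_world_json",
    "write_world_json",
    "read_judgments_csv",
    "write_judgments_csv",
    "read_stimulus_set",
    "write_stimulus_set",
    "write_report_json",
    "run_pipeline",
]

logger = logging.getLogger("effcomm")


class ValidationError(ValueError):
    """An input file violates its documented schema."""


def _fmt(v: float) -> str:
    return repr(float(v))


# ---------------------------------------------------------------------------
# Path specs
# ---------------------------------------------------------------------------


def write_pathspec_json(spec: ps.PathSpec, path, frames_per_primitive: int = 3) -> None:
    doc = {
        "origin": [spec.origin[0], spec.origin[1]],
        "segments": list(spec.segments),
        "frames_per_primitive": frames_per_primitive,
        "scale": spec.scale,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_pathspec_json(path) -> tuple[ps.PathSpec, int]:
    """Returns (spec, frames_per_primitive)."""
    doc = json.loads(Path(path).read_text())
    for key in ("origin", "segments"):
        if key not in doc:
            raise ValidationError(f"{path}: missing field {key!r}")
    spec = ps.PathSpec(
        tuple(doc["segments"]),
        origin=tuple(doc["origin"]),
        scale=float(doc.get("scale", 1.0)),
    )
    return spec, int(doc.get("frames_per_primitive", 3))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def write_trajectory_csv(traj: ps.Trajectory, path) -> None:
    lines = ["frame,x,y"]
    for i, (x, y) in enumerate(traj.points):
        lines.append(f"{i},{_fmt(x)},{_fmt(y)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_csv(path, frames_per_primitive: int = 3) -> ps.Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["frame", "x", "y"]:
        raise ValidationError(f"{path}: expected header frame,x,y, got {list(df.columns)}")
    frames = df["frame"].to_numpy()
    expected = np.arange(len(df))
    bad = np.nonzero(frames != expected)[0]
    if bad.size:
        line = int(bad[0]) + 2  # header + 1-based
        raise ValidationError(
            f"{path}: line {line}: frame index {frames[bad[0]]} (expected {bad[0]})"
        )
    return ps.Trajectory(df[["x", "y"]].to_numpy(), frames_per_primitive=frames_per_primitive)


# ---------------------------------------------------------------------------
# Worlds
# ---------------------------------------------------------------------------


def write_world_json(world: ip.World, path) -> None:
    xmin, ymin, xmax, ymax = world.bounds
    obstacles = []
    for poly in world.obstacles:
        shell = [list(xy) for xy in poly.exterior.coords[:-1]]
        if poly.interiors:
            # e.g. lakes fully enclosing a corridor: keep the holes
            obstacles.append(
                {
                    "shell": shell,
                    "holes": [[list(xy) for xy in r.coords[:-1]] for r in poly.interiors],
                }
            )
        else:
            obstacles.append(shell)
    doc = {
        "bounds": [[xmin, ymin], [xmax, ymax]],
        "obstacles": obstacles,
        "goal_spacing": world.goal_spacing,
        "grid_resolution": world.grid_resolution,
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def read_world_json(path) -> ip.World:
    doc = json.loads(Path(path).read_text())
    try:
        (xmin, ymin), (xmax, ymax) = doc["bounds"]
    except (KeyError, TypeError, ValueError):
        raise ValidationError(f"{path}: field 'bounds' must be [[xmin,ymin],[xmax,ymax]]")
    from shapely.geometry import Polygon

    obstacles = []
    for entry in doc.get("obstacles", []):
        if isinstance(entry, dict):
            obstacles.append(Polygon(entry["shell"], holes=entry.get("holes", [])))
        else:
            obstacles.append(Polygon(entry))
    return ip.build_world(
        (xmin, ymin, xmax, ymax),
        obstacles=obstacles,
        goal_spacing=float(doc.get("goal_spacing", 0.5)),
        grid_resolution=float(doc.get("grid_resolution", 0.1)),
    )


# ---------------------------------------------------------------------------
# Judgments
# ---------------------------------------------------------------------------


def write_judgments_csv(judgments: pd.DataFrame, path) -> None:
    judgments.to_csv(path, index=False, lineterminator="\n")


def read_judgments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"participant", "path_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "condition" not in df.columns:
        df["condition"] = ""
    ratings = df["rating"].to_numpy()
    bad = np.nonzero((ratings < 1) | (ratings > 7) | (ratings != np.rint(ratings)))[0]
    if bad.size:
        line = int(bad[0]) + 2
        raise ValidationError(
            f"{path}: line {line}: rating {ratings[bad[0]]} outside the 1-7 Likert scale"
        )
    return df[["participant", "path_id", "condition", "rating"]]


# ---------------------------------------------------------------------------
# Stimulus sets
# ---------------------------------------------------------------------------


def write_stimulus_set(stim: ps.StimulusSet, path) -> None:
    doc = {
        "study": stim.study,
        "seed": stim.seed,
        "items": [
            {
                "path_id": it.path_id,
                "segments": list(it.spec.segments),
                "origin": list(it.spec.origin),
                "scale": it.spec.scale,
                "condition": it.condition,
                "movement_class": it.movement_class,
            }
            for it in stim.items
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_stimulus_set(path) -> ps.StimulusSet:
    doc = json.loads(Path(path).read_text())
    items = []
    for i, rec in enumerate(doc.get("items", [])):
        try:
            spec = ps.PathSpec(
                tuple(rec["segments"]),
                origin=tuple(rec.get("origin", (0.0, 0.0))),
                scale=float(rec.get("scale", 1.0)),
            )
        except (KeyError, ps.InvalidSpecError) as e:
            raise ValidationError(f"{path}: item {i}: {e}") from None
        items.append(
            ps.StimulusItem(
                path_id=str(rec.get("path_id", i)),
                spec=spec,
                condition=rec.get("condition", ""),
                movement_class=rec.get("movement_class"),
            )
        )
    return ps.StimulusSet(doc.get("study", "unknown"), tuple(items), seed=doc.get("seed"))


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

_STAGE_IDS = {"stimuli": 1, "judgments": 2, "bootstrap": 3, "permutation": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run depends on; JSON round-trippable."""

    seed: int = 0
    outdir: Optional[str] = None
    model: ip.ModelConfig = field(default_factory=ip.ModelConfig)
    linking: sd.LinkingParams = field(default_factory=sd.LinkingParams)
    predictor: str = "rarity"  # what drives the synthetic ratings
    exclude_classes: tuple[str, ...] = ("B", "D")
    n_boot: int = 10_000
    n_perm: int = 10_000
    log_level: str = "WARNING"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc["model"] = ip.ModelConfig(**doc.get("model", {}))
        doc["linking"] = sd.LinkingParams(**doc.get("linking", {}))
        doc["exclude_classes"] = tuple(doc.get("exclude_classes", ("B", "D")))
        return cls(**doc)


def score_stimulus_set(
    stim: ps.StimulusSet, config: ip.ModelConfig = ip.ModelConfig()
) -> pd.DataFrame:
    """Communicativeness score per stimulus item (one row per item).

    Items carrying a world (bordered condition) are scored in it; others get
    the default padded empty arena for their trajectory.
    """
    rows = []
    for it in stim.items:
        traj = ps.compose(it.spec, config.frames_per_primitive)
        world = it.world if it.world is not None else ip.world_for_trajectory(traj, config=config)
        curve = ip.world_directedness_curve(world, traj, config)
        rows.append(
            {
                "path_id": it.path_id,
                "condition": it.condition,
                "movement_class": it.movement_class,
                "rarity": ps.rarity(it.spec),
                "score": curve.score,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Stimuli -> rendering -> rarity -> model scores -> synthetic judgments
    -> analysis report, deterministic from ``config.seed``.

    Returns the report dict; when ``config.outdir`` is set, also writes the
    stimulus set, trajectories, scores, judgments, report and a manifest
    hashing every output file.
    """
    logging.basicConfig()
    logger.setLevel(config.log_level)

    logger.info("stage=stimuli building the 23-path set")
    stim = ps.build_study1_set(stage_seed(config.seed, "stimuli"))

    logger.info("stage=model scoring %d paths", len(stim))
    scores = score_stimulus_set(stim, config.model)

    logger.info("stage=judgments simulating %d raters", config.linking.n_participants)
    predictor = scores[config.predictor].to_numpy()
    linking = dataclasses.replace(config.linking, seed=stage_seed(config.seed, "judgments"))
    judgments = sd.simulate_judgments(scores["path_id"].tolist(), predictor, linking)

    logger.info("stage=analysis")
    means = an.path_mean_ratings(judgments).reindex(scores["path_id"]).to_numpy()
    boot_seed = stage_seed(config.seed, "bootstrap")
    r_rarity = an.pearson_bootstrap(
        scores["rarity"], means, n_boot=config.n_boot, seed=boot_seed
    )
    r_score = an.pearson_bootstrap(
        scores["score"], means, n_boot=config.n_boot, seed=boot_seed
    )
    fit = an.calibrate_linear(scores["score"], means)
    discrepancy = an.class_discrepancy(fit, means, scores["movement_class"])
    excluded = scores.loc[
        scores["movement_class"].isin(config.exclude_classes), "path_id"
    ].tolist()
    perm = an.correlation_increase_permutation(
        scores["score"],
        means,
        excluded,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, "permutation"),
        path_ids=scores["path_id"].tolist(),
    )

    report = {
        "seed": config.seed,
        "n_paths": int(len(stim)),
        "rarity_rating_correlation": asdict(r_rarity),
        "score_rating_correlation": asdict(r_score),
        "calibration": {"slope": fit.slope, "intercept": fit.intercept},
        "class_discrepancy": discrepancy,
        "exclusion_permutation": {
            "excluded_classes": list(config.exclude_classes),
            "excluded_paths": excluded,
            "r_all": r_score.r,
            "r_after_exclusion": r_score.r + perm.delta_r_observed,
            "delta_r": perm.delta_r_observed,
            "p_value": perm.p_value,
            "n_perm": perm.n_perm,
            "exhaustive": perm.exhaustive,
        },
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        write_stimulus_set(stim, outdir / "stimuli.json")
        files["stimuli.json"] = _sha256(outdir / "stimuli.json")
        for it in stim.items:
            p = outdir / f"traj_{it.path_id}.csv"
            write_trajectory_csv(ps.compose(it.spec, config.model.frames_per_primitive), p)
            files[p.name] = _sha256(p)
        scores.to_csv(outdir / "scores.csv", index=False, lineterminator="\n")
        files["scores.csv"] = _sha256(outdir / "scores.csv")
        write_judgments_csv(judgments, outdir / "judgments.csv")
        files["judgments.csv"] = _sha256(outdir / "judgments.csv")
        write_report_json(report, outdir / "report.json")
        files["report.json"] = _sha256(outdir / "report.json")
        manifest = {"config": asdict(config), "files": dict(sorted(files.items()))}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
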