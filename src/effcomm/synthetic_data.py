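"""Synthetic participant judgments and bordered ("lake") worlds.

Real communicativeness ratings are 1-7 Likert responses collected per
participant and path.  This module generates stand-in data with the
statistical structure the analysis stage assumes — a monotone dependence of
ratings on a per-path predictor (rarity or model score), participant-level
intercept noise, and trial noise — so the whole pipeline can be exercised
and validated without any external download.  The ordinal link is a rounded
and clamped Gaussian; it is a pipeline-testing stand-in, not a model of the
human data.  It also builds the bordered worlds of the border manipulation:
obstacle polygons flanking a trajectory so the same movement becomes
consistent with efficient world-directed travel through a corridor.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .inverse_planner import World, build_world
from .path_space import StimulusSet, Trajectory, build_study1_set, compose, rarity

__all__ = [
    "LinkingParams",
    "GeometryError",
    "simulate_judgments",
    "make_bordered_world",
    "generate_fixtures",
]


class GeometryError(ValueError):
    """Corridor construction failed (margin incompatible with the path)."""


@dataclass(frozen=True)
class LinkingParams:
    """Parameters of the synthetic rating model.

    rating = clamp(round(a + b * z(predictor) + u_p + eps), 1, 7), with
    participant intercepts u_p ~ N(0, tau^2) and trial noise eps ~ N(0,
    sigma^2); z standardizes the predictor over paths.  Defaults give a
    strong but noisy monotone link at the study's sample size (n = 30
    raters), landing mean-rating correlations in the high-correlation
    regime the point-display experiments report.
    """

    intercept: float = 4.0
    slope: float = 1.2
    participant_sd: float = 0.5
    trial_sd: float = 1.0
    n_participants: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.participant_sd < 0 or self.trial_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


def simulate_judgments(
    paths: Sequence[str],
    predictor: Sequence[float],
    params: LinkingParams = LinkingParams(),
    conditions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate a participant x path Likert judgment table.

    Parameters
    ----------
    paths : sequence of str
        Path identifiers.
    predictor : sequence of float
        Per-path predictor values (rarity or model score); standardized
        internally.
    params : LinkingParams
        Linking-model parameters, including the RNG seed.
    conditions : sequence of str, optional
        Per-path condition tags copied into the table.

    Returns
    -------
    DataFrame with columns participant, path_id, condition, rating.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("empty path list")
    x = np.asarray(predictor, dtype=float)
    if x.shape != (len(paths),):
        raise ValueError("predictor must supply one value per path")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rng = np.random.default_rng(params.seed)
    n, m = params.n_participants, len(paths)
    u = rng.normal(0.0, params.participant_sd, size=n)
    eps = rng.normal(0.0, params.trial_sd, size=(n, m))
    latent = params.intercept + params.slope * z[None, :] + u[:, None] + eps
    ratings = np.clip(np.rint(latent), 1, 7).astype(int)
    cond = list(conditions) if conditions is not None else [""] * m
    return pd.DataFrame(
        {
            "participant": np.repeat(np.arange(n), m),
            "path_id": np.tile(np.asarray(paths, dtype=object), n),
            "condition": np.tile(np.asarray(cond, dtype=object), n),
            "rating": ratings.ravel(),
        }
    )


def make_bordered_world(
    traj: Trajectory,
    margin: float = 0.4,
    padding: float = 1.0,
    goal_spacing: float = 0.5,
    grid_resolution: float = 0.1,
) -> World:
    """Build a world whose obstacle "lakes" closely flank the trajectory.

    The passable region is the trajectory polyline buffered by ``margin``;
    everything else inside the (padded) arena becomes obstacle polygons.
    Raises :class:`GeometryError` if any frame point ends up closer than
    ``margin / 2`` to an obstacle (the corridor pinched shut).
    """
    from shapely.geometry import LineString, box

    if margin <= 0:
        raise ValueError("margin must be > 0")
    pts = traj.points
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    corridor = LineString(pts).buffer(margin)
    lakes = box(lo[0], lo[1], hi[0], hi[1]).difference(corridor)
    polys = []
    if not lakes.is_empty:
        geoms = getattr(lakes, "geoms", [lakes])
        polys = [g for g in geoms if g.area > 1e-12]
    world = build_world(
        (lo[0], lo[1], hi[0], hi[1]),
        obstacles=polys,
        goal_spacing=goal_spacing,
        grid_resolution=grid_resolution,
    )
    if polys:
        from shapely.geometry import MultiPolygon, Point

        union = MultiPolygon(polys) if len(polys) > 1 else polys[0]
        dmin = min(union.distance(Point(p)) for p in pts)
        if dmin < margin * 0.5:
            raise GeometryError(
                f"corridor pinched: a frame point is {dmin:.3f} from the lakes "
                f"(need >= {margin * 0.5:.3f}); increase the margin"
            )
    return world


def generate_fixtures(outdir, seed: int = 0) -> dict:
    """Write a small end-to-end fixture bundle and return its manifest.

    The bundle contains the 23-path stimulus set, its rendered trajectories,
    a synthetic judgment table (n_participants x 23 rows), bordered-world
    JSON for the two highest-rarity paths, and a manifest recording every
    seed, parameter and file hash.  Byte-identical across runs with the
    same seed.
    """
    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_stim, s_judge = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    stim = build_study1_set(s_stim)
    files: dict[str, str] = {}

    stim_path = outdir / "study1_stimuli.json"
    eio.write_stimulus_set(stim, stim_path)
    files["study1_stimuli.json"] = _sha256(stim_path)

    rarities = [rarity(it.spec) for it in stim.items]
    for it in stim.items:
        p = outdir / f"traj_{it.path_id}.csv"
        eio.write_trajectory_csv(compose(it.spec), p)
        files[p.name] = _sha256(p)

    params = LinkingParams(seed=s_judge)
    judgments = simulate_judgments([it.path_id for it in stim.items], rarities, params)
    jpath = outdir / "judgments.csv"
    eio.write_judgments_csv(judgments, jpath)
    files["judgments.csv"] = _sha256(jpath)

    order = np.argsort(rarities)[::-1]
    for idx in order[:2]:
        it = stim.items[idx]
        world = make_bordered_world(compose(it.spec))
        p = outdir / f"world_{it.path_id}.json"
        eio.write_world_json(world, p)
        files[p.name] = _sha256(p)

    manifest = {
        "seed": seed,
        "stimulus_seed": s_stim,
        "judgment_seed": s_judge,
        "linking_params": asdict(params),
        "files": dict(sorted(files.items())),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
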