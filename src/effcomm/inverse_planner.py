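"""Bayesian inverse-planning observer for world-directedness.

The observer assumes a noisy-rational agent moving in a bounded 2-D arena
(optionally with impassable "lake" polygons) toward some world-directed goal
drawn uniformly from a lattice of candidate locations.  At each observed
frame step the agent's action is one of K candidate steps of the observed
length at uniformly spaced headings; the probability of each candidate is a
Boltzmann (softmax) function of its total cost to the goal,

    p(a | s, g)  propto  exp(-beta * (|a| + C(s + a, g))),

where C is the obstacle-avoiding cost-to-go and beta the rationality
(inverse temperature).  Marginalizing the trajectory likelihood over goals
with a uniform prior gives a per-frame log marginal likelihood l_t that the
movement is world-directed; the communicativeness score is -l_T at the final
frame.  Rare movements — those no world-directed goal explains well — earn
low l_t and hence high scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .path_space import Trajectory

__all__ = [
    "ModelConfig",
    "World",
    "GoalPosterior",
    "WorldDirectednessCurve",
    "ConfigurationError",
    "InvalidTrajectoryError",
    "DegenerateStateError",
    "build_world",
    "world_for_trajectory",
    "cost_to_go",
    "step_likelihood",
    "trajectory_loglik",
    "world_directedness_curve",
    "communicativeness_score",
    "goal_posterior",
]


class ConfigurationError(ValueError):
    """World or model configuration is geometrically or numerically invalid."""


class InvalidTrajectoryError(ValueError):
    """A trajectory leaves the arena or enters an obstacle."""


class DegenerateStateError(RuntimeError):
    """No admissible candidate action exists at some state."""


LOG_FLOOR = -745.0  # ~ log of the smallest positive double; per-step floor


@dataclass(frozen=True)
class ModelConfig:
    """Observer parameters.

    beta : rationality (inverse temperature) of the Boltzmann policy, >= 0.
    n_headings : number K of candidate actions per step (observed heading
        plus K-1 uniformly spaced alternatives of the same length).
    frames_per_primitive : rendering density the observer scores.
    goal_spacing : pitch of the candidate-goal lattice (arena units).
    grid_resolution : pitch h of the navigation grid used for cost-to-go
        when obstacles are present (8-connected, diagonal cost h*sqrt(2)).
    log_floor : lower bound applied to each per-step log-probability.
    """

    beta: float = 2.0
    n_headings: int = 16
    frames_per_primitive: int = 3
    goal_spacing: float = 0.5
    grid_resolution: float = 0.1
    log_floor: float = LOG_FLOOR

    def __post_init__(self):
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")
        if self.n_headings < 2:
            raise ConfigurationError("n_headings must be >= 2")
        if self.goal_spacing <= 0 or self.grid_resolution <= 0:
            raise ConfigurationError("spacings must be > 0")


@dataclass(frozen=True)
class World:
    """A bounded arena with optional obstacle polygons and a goal lattice."""

    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    obstacles: tuple = ()  # shapely polygons
    goal_spacing: float = 0.5
    grid_resolution: float = 0.1
    goals: np.ndarray = field(default=None, repr=False, compare=False)  # (n_goals, 2)
    _grid: Optional["_NavGrid"] = field(default=None, repr=False, compare=False)

    @property
    def has_obstacles(self) -> bool:
        return len(self.obstacles) > 0

    def contains(self, points: np.ndarray) -> np.ndarray:
        x, y = points[..., 0], points[..., 1]
        xmin, ymin, xmax, ymax = self.bounds
        eps = 1e-9
        return (x >= xmin - eps) & (x <= xmax + eps) & (y >= ymin - eps) & (y <= ymax + eps)

    def blocked(self, points: np.ndarray) -> np.ndarray:
        """True where a point is outside bounds or on/inside an obstacle.

        Obstacle membership includes the boundary: a point exactly on a
        lake's edge is not passable terrain.
        """
        pts = np.atleast_2d(points)
        bad = ~self.contains(pts)
        if self.has_obstacles:
            from shapely import intersects_xy

            for poly in self.obstacles:
                bad |= intersects_xy(poly, pts[:, 0], pts[:, 1])
        return bad


class _NavGrid:
    """8-connected navigation grid with per-goal Dijkstra distance fields."""

    def __init__(self, world: World):
        xmin, ymin, xmax, ymax = world.bounds
        h = world.grid_resolution
        self.h = h
        self.nx = int(round((xmax - xmin) / h)) + 1
        self.ny = int(round((ymax - ymin) / h)) + 1
        self.x0, self.y0 = xmin, ymin
        xs = xmin + h * np.arange(self.nx)
        ys = ymin + h * np.arange(self.ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        centers = np.c_[gx.ravel(), gy.ravel()]
        self.passable = ~world.blocked(centers)
        if not self.passable.any():
            raise ConfigurationError("no passable navigation cells")
        self._centers = centers
        self._passable_tree = None  # lazy KDTree over passable cell centers
        self._graph = self._build_graph()
        self._fields: dict[tuple[float, float], np.ndarray] = {}
        import shapely

        self.obstacle_union = shapely.union_all(list(world.obstacles))

    def _build_graph(self):
        from scipy.sparse import coo_matrix

        nx, ny, h = self.nx, self.ny, self.h
        n = nx * ny
        idx = np.arange(n).reshape(nx, ny)
        rows, cols, vals = [], [], []
        moves = [(1, 0, h), (0, 1, h), (1, 1, h * math.sqrt(2)), (1, -1, h * math.sqrt(2))]
        pas = self.passable.reshape(nx, ny)
        for dx, dy, w in moves:
            sx = slice(None, -dx or None)
            tx = slice(dx, None)
            if dy >= 0:
                sy, ty = slice(None, -dy or None), slice(dy, None)
            else:
                sy, ty = slice(-dy, None), slice(None, dy)
            ok = pas[sx, sy] & pas[tx, ty]
            rows.append(idx[sx, sy][ok])
            cols.append(idx[tx, ty][ok])
            vals.append(np.full(ok.sum(), w))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    def node(self, points: np.ndarray) -> np.ndarray:
        """Nearest passable grid node per point.

        Passable points lying in a blocked cell (e.g. exactly on an obstacle
        boundary) are snapped to the nearest passable cell center instead of
        being stranded on a disconnected node.
        """
        pts = np.atleast_2d(points)
        i = np.clip(np.round((pts[:, 0] - self.x0) / self.h).astype(int), 0, self.nx - 1)
        j = np.clip(np.round((pts[:, 1] - self.y0) / self.h).astype(int), 0, self.ny - 1)
        nodes = i * self.ny + j
        bad = ~self.passable[nodes]
        if bad.any():
            if self._passable_tree is None:
                from scipy.spatial import cKDTree

                self._passable_idx = np.nonzero(self.passable)[0]
                self._passable_tree = cKDTree(self._centers[self._passable_idx])
            _, nearest = self._passable_tree.query(pts[bad])
            nodes[bad] = self._passable_idx[nearest]
        return nodes

    def distance_field(self, goal: np.ndarray) -> np.ndarray:
        key = (round(float(goal[0]), 9), round(float(goal[1]), 9))
        if key not in self._fields:
            from scipy.sparse.csgraph import dijkstra

            src = self.node(goal)[0]
            self._fields[key] = dijkstra(self._graph, directed=False, indices=src)
        return self._fields[key]


def build_world(
    bounds: Sequence[float],
    obstacles: Sequence = (),
    goal_spacing: float = 0.5,
    grid_resolution: float = 0.1,
) -> World:
    """Materialize a world: bounds, obstacle polygons, and the goal lattice.

    ``bounds`` is (xmin, ymin, xmax, ymax); ``obstacles`` are shapely
    polygons or coordinate sequences.  Lattice points inside obstacles are
    excluded; an empty lattice is a configuration error.
    """
    from shapely.geometry import Polygon

    xmin, ymin, xmax, ymax = map(float, bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ConfigurationError("arena bounds must have positive area")
    polys = tuple(p if isinstance(p, Polygon) else Polygon(p) for p in obstacles)
    for p in polys:
        if p.is_empty or p.area <= 0:
            raise ConfigurationError("obstacle polygons must have positive area")
    xs = np.arange(xmin, xmax + 1e-9, goal_spacing)
    ys = np.arange(ymin, ymax + 1e-9, goal_spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    goals = np.c_[gx.ravel(), gy.ravel()]
    world = World(
        bounds=(xmin, ymin, xmax, ymax),
        obstacles=polys,
        goal_spacing=goal_spacing,
        grid_resolution=grid_resolution,
    )
    keep = ~world.blocked(goals)
    goals = goals[keep]
    if goals.shape[0] == 0:
        raise ConfigurationError("goal lattice is empty (obstacles cover the arena)")
    object.__setattr__(world, "goals", goals)
    if polys:
        object.__setattr__(world, "_grid", _NavGrid(world))
    return world


def world_for_trajectory(
    traj: Trajectory,
    obstacles: Sequence = (),
    padding: float = 1.0,
    config: ModelConfig = ModelConfig(),
) -> World:
    """Default arena for a trajectory: its bounding box padded on all sides,
    so goals beyond the path remain representable."""
    lo = traj.points.min(axis=0) - padding
    hi = traj.points.max(axis=0) + padding
    return build_world(
        (lo[0], lo[1], hi[0], hi[1]),
        obstacles=obstacles,
        goal_spacing=config.goal_spacing,
        grid_resolution=config.grid_resolution,
    )


def _visible(world: World, points: np.ndarray, goals: np.ndarray) -> np.ndarray:
    """Line-of-sight mask, shape (n_points, n_goals): the straight segment
    from point to goal misses every obstacle."""
    import shapely

    n_p, n_g = points.shape[0], goals.shape[0]
    coords = np.empty((n_p * n_g, 2, 2))
    coords[:, 0, :] = np.repeat(points, n_g, axis=0)
    coords[:, 1, :] = np.tile(goals, (n_p, 1))
    lines = shapely.linestrings(coords)
    hit = shapely.intersects(lines, world._grid.obstacle_union)
    return ~hit.reshape(n_p, n_g)


def cost_to_go(world: World, point, goal) -> float:
    """Shortest obstacle-avoiding travel cost from ``point`` to ``goal``.

    The exact Euclidean distance is used when the straight segment to the
    goal is unobstructed (always true in an empty world); otherwise the
    8-connected grid shortest path (within the ~9% octile bound of the true
    metric).  Unreachable goals return ``inf``.
    """
    point = np.asarray(point, dtype=float)
    goal = np.asarray(goal, dtype=float)
    if world.blocked(point[None, :])[0] or world.blocked(goal[None, :])[0]:
        raise ConfigurationError("point and goal must be passable")
    if not world.has_obstacles:
        return float(np.linalg.norm(goal - point))
    return float(_cost_to_go_batch(world, point[None, :], goal[None, :])[0, 0])


def _cost_to_go_batch(world: World, points: np.ndarray, goals: np.ndarray) -> np.ndarray:
    """Cost-to-go for every (point, goal) pair; shape (n_points, n_goals).

    Blocked points get +inf rows (they are inadmissible candidate endpoints).
    """
    euclid = np.linalg.norm(points[:, None, :] - goals[None, :, :], axis=-1)
    if not world.has_obstacles:
        return euclid
    out = np.empty_like(euclid)
    vis = _visible(world, points, goals)
    nodes = world._grid.node(points)
    for j, g in enumerate(goals):
        out[:, j] = world._grid.distance_field(g)[nodes]
    out[vis] = euclid[vis]
    out[world.blocked(points), :] = np.inf
    return out


def _candidate_steps(step_obs: np.ndarray, k: int) -> np.ndarray:
    """The observed step plus k-1 same-length steps at uniformly spaced
    headings offset from the observed heading; shape (k, 2)."""
    length = float(np.linalg.norm(step_obs))
    theta0 = math.atan2(step_obs[1], step_obs[0])
    angles = theta0 + 2.0 * math.pi * np.arange(k) / k
    return length * np.c_[np.cos(angles), np.sin(angles)]


def _step_logprobs(
    world: World, s: np.ndarray, step_obs: np.ndarray, goals: np.ndarray, config: ModelConfig
) -> np.ndarray:
    """Log-probability of the observed step under each goal; shape (n_goals,)."""
    cands = _candidate_steps(step_obs, config.n_headings)
    endpoints = s[None, :] + cands
    admissible = ~world.blocked(endpoints)
    if not admissible[0]:
        raise InvalidTrajectoryError("observed step leaves the passable arena")
    if not admissible.any():
        raise DegenerateStateError(f"all candidate actions blocked at {tuple(s)}")
    lengths = np.linalg.norm(cands, axis=1)
    ctg = _cost_to_go_batch(world, endpoints[admissible], goals)  # (n_adm, n_goals)
    cost = lengths[admissible, None] + ctg
    logits = -config.beta * cost
    from scipy.special import logsumexp

    with np.errstate(invalid="ignore"):
        logp = logits - logsumexp(logits, axis=0, keepdims=True)
    # goals unreachable from every candidate produce -inf - -inf = nan;
    # such a goal explains the step no better than the floor allows
    logp = np.where(np.isnan(logp), config.log_floor, logp)
    return np.maximum(logp[0], config.log_floor)  # observed step is candidate 0


def step_likelihood(world: World, s, step_obs, g, config: ModelConfig = ModelConfig()) -> float:
    """Probability of the observed step toward goal ``g`` under the softmax
    policy over the candidate-action set at state ``s``."""
    s = np.asarray(s, dtype=float)
    step_obs = np.asarray(step_obs, dtype=float)
    if np.linalg.norm(step_obs) <= 0:
        raise ValueError("observed step must have positive length")
    g = np.atleast_2d(np.asarray(g, dtype=float))
    return float(np.exp(_step_logprobs(world, s, step_obs, g, config)[0]))


def _per_step_goal_logliks(world: World, traj: Trajectory, config: ModelConfig) -> np.ndarray:
    """Log step-likelihood for every (step, goal); shape (n_steps, n_goals)."""
    pts = traj.points
    if np.any(world.blocked(pts)):
        raise InvalidTrajectoryError("trajectory leaves the arena or enters an obstacle")
    steps = traj.steps()
    out = np.empty((steps.shape[0], world.goals.shape[0]))
    for t in range(steps.shape[0]):
        out[t] = _step_logprobs(world, pts[t], steps[t], world.goals, config)
    return out


def trajectory_loglik(world: World, traj: Trajectory, g, config: ModelConfig = ModelConfig()) -> float:
    """Log-likelihood of the whole trajectory under a single goal ``g``."""
    pts = traj.points
    if np.any(world.blocked(pts)):
        raise InvalidTrajectoryError("trajectory leaves the arena or enters an obstacle")
    g = np.atleast_2d(np.asarray(g, dtype=float))
    total = 0.0
    steps = traj.steps()
    for t in range(steps.shape[0]):
        total += float(_step_logprobs(world, pts[t], steps[t], g, config)[0])
    return total


@dataclass(frozen=True)
class WorldDirectednessCurve:
    """Per-frame log marginal likelihood that a movement is world-directed."""

    frames: np.ndarray  # frame indices 1..T (one per step)
    loglik: np.ndarray  # l_t, non-increasing
    score: float  # -l_T

    def __len__(self) -> int:
        return len(self.frames)


def world_directedness_curve(
    world: World, traj: Trajectory, config: ModelConfig = ModelConfig()
) -> WorldDirectednessCurve:
    """l_t = log sum_g (1/|G|) p(a_{1:t} | g), one value per frame step,
    computed with cumulative per-goal log-likelihoods and log-sum-exp."""
    from scipy.special import logsumexp

    per_step = _per_step_goal_logliks(world, traj, config)  # (T, n_goals)
    cum = np.cumsum(per_step, axis=0)
    prior = -math.log(world.goals.shape[0])
    ll = logsumexp(cum + prior, axis=1)
    return WorldDirectednessCurve(
        frames=np.arange(1, per_step.shape[0] + 1), loglik=ll, score=float(-ll[-1])
    )


def communicativeness_score(curve: WorldDirectednessCurve) -> float:
    """Negative log marginal likelihood at the final frame: higher means the
    trajectory more strongly reveals it has no world-directed goal."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    return float(-curve.loglik[-1])


@dataclass(frozen=True)
class GoalPosterior:
    goals: np.ndarray  # (n_goals, 2)
    weights: np.ndarray  # sum to 1


def goal_posterior(
    world: World, traj: Trajectory, config: ModelConfig = ModelConfig()
) -> GoalPosterior:
    """Posterior over lattice goals given the full trajectory (uniform prior)."""
    from scipy.special import softmax

    per_step = _per_step_goal_logliks(world, traj, config)
    total = per_step.sum(axis=0)
    if np.all(total <= config.log_floor * per_step.shape[0] + 1e-9):
        import warnings

        warnings.warn("all goals at the likelihood floor; returning a uniform posterior")
        w = np.full(total.shape, 1.0 / total.shape[0])
    else:
        w = softmax(total)
    return GoalPosterior(goals=world.goals, weights=w)
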