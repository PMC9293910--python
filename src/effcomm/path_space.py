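"""Primitive motion segments, path composition, symmetry, rarity, and stimulus sets.

Movement stimuli are 2-D trajectories built by chaining primitive segments:
4 cardinal unit steps, 4 diagonal steps, and 8 quarter-circle arcs of radius 1
(start tangent in {N, E, S, W} x turn direction {CW, CCW}).  A path is a
sequence of primitive ids; rendering subdivides each primitive into equal
arc-length frames.  The module also provides the dihedral symmetry group of
the square (rotations/reflections) acting on paths, canonicalization of paths
up to that group, the rarity statistic

    r(p) = 1 - d*(p) / d(p),

where ``d*`` is the straight-line start-to-end distance and ``d`` the distance
actually traveled, a movement-class taxonomy (labels A-H), and builders for
the three point-display stimulus sets used downstream.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Primitive",
    "PathSpec",
    "Trajectory",
    "StimulusItem",
    "StimulusSet",
    "CLASS_LABELS",
    "PRIMITIVES",
    "PRIMITIVE_NAMES",
    "SYMMETRIES",
    "InvalidSpecError",
    "ResourceError",
    "ConstructionError",
    "list_primitives",
    "primitive_by_name",
    "reverse_primitive",
    "compose",
    "path_length",
    "net_displacement",
    "rarity",
    "transform",
    "canonicalize",
    "canonical_key",
    "enumerate_path_space",
    "classify",
    "build_study1_set",
    "build_study2_set",
    "build_study3_set",
]


class InvalidSpecError(ValueError):
    """A path specification references unknown primitives or is empty."""


class ResourceError(RuntimeError):
    """An enumeration request exceeds the supported memory budget."""


class ConstructionError(RuntimeError):
    """A stimulus set could not be built under its stated constraints."""


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

_DIRS = {
    "N": (0, 1),
    "E": (1, 0),
    "S": (0, -1),
    "W": (-1, 0),
    "NE": (1, 1),
    "SE": (1, -1),
    "SW": (-1, -1),
    "NW": (-1, 1),
}


def _rot90(v: tuple[int, int], sign: int) -> tuple[int, int]:
    """Rotate an integer vector by +90 (sign=+1, CCW) or -90 (sign=-1) degrees."""
    x, y = v
    return (-y, x) if sign > 0 else (y, -x)


@dataclass(frozen=True)
class Primitive:
    """One of the 16 elementary motion segments.

    Attributes
    ----------
    id : int
        Stable identifier in 0-15.
    kind : str
        ``"cardinal"``, ``"diagonal"`` or ``"arc"``.
    heading : str
        Start tangent direction (N/E/S/W for cardinals and arcs,
        NE/SE/SW/NW for diagonals).
    turn : str or None
        For arcs, ``"cw"`` or ``"ccw"``; ``None`` otherwise.
    length : float
        Arc length in arena units (1, sqrt(2) or pi/2).
    displacement : tuple of int
        End minus start, always integer-valued on the unit grid.
    """

    id: int
    kind: str
    heading: str
    turn: Optional[str]
    length: float
    displacement: tuple[int, int]

    @property
    def name(self) -> str:
        if self.kind == "arc":
            return f"arc{self.heading}_{self.turn}"
        return self.heading

    def start_tangent(self) -> tuple[int, int]:
        return _DIRS[self.heading]

    def end_tangent(self) -> tuple[int, int]:
        if self.kind != "arc":
            return _DIRS[self.heading]
        return _rot90(_DIRS[self.heading], +1 if self.turn == "ccw" else -1)


def _build_primitives() -> list[Primitive]:
    prims: list[Primitive] = []
    for h in ("N", "E", "S", "W"):
        prims.append(Primitive(len(prims), "cardinal", h, None, 1.0, _DIRS[h]))
    for h in ("NE", "SE", "SW", "NW"):
        prims.append(Primitive(len(prims), "diagonal", h, None, math.sqrt(2.0), _DIRS[h]))
    for turn in ("cw", "ccw"):
        for h in ("N", "E", "S", "W"):
            t = _DIRS[h]
            sign = +1 if turn == "ccw" else -1
            center = _rot90(t, sign)
            # end = center + rot(start - center, sign); start at origin
            start_rel = (-center[0], -center[1])
            end_rel = _rot90(start_rel, sign)
            disp = (center[0] + end_rel[0], center[1] + end_rel[1])
            prims.append(Primitive(len(prims), "arc", h, turn, math.pi / 2.0, disp))
    return prims


PRIMITIVES: tuple[Primitive, ...] = tuple(_build_primitives())
PRIMITIVE_NAMES: dict[str, int] = {p.name: p.id for p in PRIMITIVES}


def list_primitives() -> tuple[Primitive, ...]:
    """Return the 16 primitive motion segments."""
    return PRIMITIVES


def primitive_by_name(name: str) -> Primitive:
    try:
        return PRIMITIVES[PRIMITIVE_NAMES[name]]
    except KeyError:
        raise InvalidSpecError(f"unknown primitive name {name!r}") from None


def _resolve_segment(seg) -> int:
    if isinstance(seg, Primitive):
        return seg.id
    if isinstance(seg, str):
        return primitive_by_name(seg).id
    seg = int(seg)
    if not 0 <= seg < 16:
        raise InvalidSpecError(f"primitive id {seg} out of range 0-15")
    return seg


# Reversal table: traversing a primitive backwards is again a primitive
# (cardinals/diagonals negate; arcs negate the end tangent and flip the turn).
def _build_reversal() -> tuple[int, ...]:
    rev = []
    for p in PRIMITIVES:
        if p.kind == "arc":
            et = p.end_tangent()
            back = (-et[0], -et[1])
            h = next(k for k, v in _DIRS.items() if v == back and len(k) == 1)
            turn = "ccw" if p.turn == "cw" else "cw"
            rev.append(PRIMITIVE_NAMES[f"arc{h}_{turn}"])
        else:
            d = (-p.displacement[0], -p.displacement[1])
            h = next(k for k, v in _DIRS.items() if v == d)
            rev.append(PRIMITIVE_NAMES[h])
    return tuple(rev)


_REVERSE: tuple[int, ...] = _build_reversal()


def reverse_primitive(pid: int) -> int:
    """Id of the primitive that traverses ``pid`` backwards."""
    return _REVERSE[_resolve_segment(pid)]


# ---------------------------------------------------------------------------
# Path specification and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathSpec:
    """An ordered chain of primitive segments starting at ``origin``.

    ``scale`` uniformly rescales the rendered geometry about the origin;
    it is used by the repetition stimuli, where total traveled distance is
    equated across items.
    """

    segments: tuple[int, ...]
    origin: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self):
        segs = tuple(_resolve_segment(s) for s in self.segments)
        if not segs:
            raise InvalidSpecError("a path needs at least one segment")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def primitives(self) -> tuple[Primitive, ...]:
        return tuple(PRIMITIVES[i] for i in self.segments)

    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.primitives)


@dataclass(frozen=True)
class Trajectory:
    """A rendered path: frame points sampled at equal arc length per primitive."""

    points: np.ndarray  # (n_frames, 2)
    frames_per_primitive: int = 3
    source: Optional[PathSpec] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("a trajectory needs at least two (x, y) frame points")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive frame points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.n_frames)

    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive frames, shape (n_frames-1, 2)."""
        return np.diff(self.points, axis=0)


def _render_primitive(prim: Primitive, start: np.ndarray, k: int) -> np.ndarray:
    """Points 1..k along the primitive from ``start`` (start point excluded)."""
    fracs = np.arange(1, k + 1) / k
    if prim.kind != "arc":
        d = np.array(prim.displacement, dtype=float)
        return start + fracs[:, None] * d
    sign = +1.0 if prim.turn == "ccw" else -1.0
    center = start + np.array(_rot90(_DIRS[prim.heading], int(sign)), dtype=float)
    rel = start - center
    a0 = math.atan2(rel[1], rel[0])
    ang = a0 + sign * (math.pi / 2.0) * fracs
    return center + np.c_[np.cos(ang), np.sin(ang)]


def compose(spec: PathSpec, frames_per_primitive: int = 3) -> Trajectory:
    """Render a path spec into a trajectory.

    Each primitive contributes ``frames_per_primitive`` equal-arc-length
    sub-steps; the frame count is ``1 + frames_per_primitive * n_segments``.
    """
    if frames_per_primitive < 1:
        raise ValueError("frames_per_primitive must be >= 1")
    pts = [np.array(spec.origin, dtype=float)]
    pos = pts[0].copy()
    for prim in spec.primitives:
        sub = _render_primitive(prim, pos, frames_per_primitive)
        pts.extend(sub)
        pos = sub[-1]
    arr = np.vstack(pts)
    if spec.scale != 1.0:
        o = np.array(spec.origin, dtype=float)
        arr = o + spec.scale * (arr - o)
    return Trajectory(arr, frames_per_primitive=frames_per_primitive, source=spec)


def path_length(spec: PathSpec) -> float:
    """Total distance traveled d(p): the sum of primitive arc lengths (scaled)."""
    return spec.scale * sum(p.length for p in spec.primitives)


def net_displacement(spec: PathSpec) -> float:
    """Straight-line start-to-end distance d*(p)."""
    dx = sum(p.displacement[0] for p in spec.primitives)
    dy = sum(p.displacement[1] for p in spec.primitives)
    return spec.scale * math.hypot(dx, dy)


def rarity(spec: PathSpec) -> float:
    """Rarity r(p) = 1 - d*(p)/d(p), in [0, 1].

    Zero for maximally efficient (straight) paths, one for closed paths.
    """
    d = path_length(spec)
    if d <= 0.0:
        raise ValueError("rarity is undefined for zero-length paths")
    r = 1.0 - net_displacement(spec) / d
    # clip tiny negative float error for straight chains
    return min(1.0, max(0.0, r))


# ---------------------------------------------------------------------------
# Square symmetries (dihedral group of order 8)
# ---------------------------------------------------------------------------

_SYM_MATRICES: dict[str, np.ndarray] = {
    "identity": np.array([[1, 0], [0, 1]]),
    "rot90": np.array([[0, -1], [1, 0]]),  # 90 deg counterclockwise
    "rot180": np.array([[-1, 0], [0, -1]]),
    "rot270": np.array([[0, 1], [-1, 0]]),
    "reflect_x": np.array([[1, 0], [0, -1]]),  # over the x-axis
    "reflect_y": np.array([[-1, 0], [0, 1]]),
    "reflect_diag": np.array([[0, 1], [1, 0]]),  # over y = x
    "reflect_antidiag": np.array([[0, -1], [-1, 0]]),  # over y = -x
}

# Named compositions used by the repetition-stimulus masking: rotate 90 deg
# CCW then reflect over the x-axis equals the antidiagonal reflection.
_SYM_ALIASES = {
    "rot90ccw_reflect_x": "reflect_antidiag",
    "rot180ccw": "rot180",
}

SYMMETRIES: tuple[str, ...] = tuple(_SYM_MATRICES)


def _sym_matrix(name: str) -> np.ndarray:
    key = _SYM_ALIASES.get(name, name)
    if key not in _SYM_MATRICES:
        raise ValueError(
            f"unsupported symmetry {name!r}; expected one of "
            f"{sorted(_SYM_MATRICES) + sorted(_SYM_ALIASES)}"
        )
    return _SYM_MATRICES[key]


@functools.lru_cache(maxsize=None)
def _sym_permutation(name: str) -> tuple[int, ...]:
    """How a symmetry permutes the 16 primitive ids."""
    m = _sym_matrix(name)
    det = int(round(np.linalg.det(m)))
    perm = []
    for p in PRIMITIVES:
        if p.kind == "arc":
            t = m @ np.array(_DIRS[p.heading])
            h = next(k for k, v in _DIRS.items() if tuple(t) == v and len(k) == 1)
            turn = p.turn if det > 0 else ("ccw" if p.turn == "cw" else "cw")
            perm.append(PRIMITIVE_NAMES[f"arc{h}_{turn}"])
        else:
            d = m @ np.array(p.displacement)
            h = next(k for k, v in _DIRS.items() if tuple(d) == v)
            perm.append(PRIMITIVE_NAMES[h])
    return tuple(perm)


def transform(spec: PathSpec, symmetry: str) -> PathSpec:
    """Apply one of the 8 square symmetries (about the coordinate origin).

    The returned spec renders to exactly the symmetry image of the original
    rendering; rarity, lengths and class labels are invariant.
    """
    perm = _sym_permutation(symmetry)
    m = _sym_matrix(symmetry)
    ox, oy = (m @ np.array(spec.origin, dtype=float)).tolist()
    return PathSpec(tuple(perm[s] for s in spec.segments), origin=(ox, oy), scale=spec.scale)


def _reverse_segments(segments: Sequence[int]) -> tuple[int, ...]:
    return tuple(_REVERSE[s] for s in reversed(segments))


def canonical_key(spec: PathSpec, include_reversal: bool = False) -> tuple[int, ...]:
    """Lexicographically least segment tuple over the symmetry orbit.

    Two specs share a key iff one is a rotation/reflection of the other
    (optionally also allowing traversal reversal).
    """
    candidates = []
    for name in _SYM_MATRICES:
        perm = _sym_permutation(name)
        segs = tuple(perm[s] for s in spec.segments)
        candidates.append(segs)
        if include_reversal:
            candidates.append(_reverse_segments(segs))
    return min(candidates)


def canonicalize(spec: PathSpec, include_reversal: bool = False) -> PathSpec:
    """Canonical representative of the path's symmetry orbit (origin reset)."""
    return PathSpec(canonical_key(spec, include_reversal=include_reversal))


# ---------------------------------------------------------------------------
# Path-space enumeration
# ---------------------------------------------------------------------------

_MAX_ENUM_N = 5  # 16^6 sequences x 8 symmetry copies exceeds the memory budget


def _chaining_mask(seqs: np.ndarray, chaining: str) -> np.ndarray:
    """Boolean mask of admissible sequences under a chaining convention."""
    if chaining == "all":
        return np.ones(seqs.shape[0], dtype=bool)
    if chaining == "no_retrace":
        rev = np.array(_REVERSE)
        ok = np.ones(seqs.shape[0], dtype=bool)
        for i in range(seqs.shape[1] - 1):
            ok &= seqs[:, i + 1] != rev[seqs[:, i]]
        return ok
    if chaining == "tangent":
        start_t = np.array([p.start_tangent() for p in PRIMITIVES])
        end_t = np.array([p.end_tangent() for p in PRIMITIVES])
        ok = np.ones(seqs.shape[0], dtype=bool)
        for i in range(seqs.shape[1] - 1):
            ok &= np.all(start_t[seqs[:, i + 1]] == end_t[seqs[:, i]], axis=1)
        return ok
    raise ValueError(f"unknown chaining convention {chaining!r}")


def enumerate_path_space(
    n: int,
    chaining: str = "all",
    include_reversal: bool = False,
) -> list[PathSpec]:
    """One canonical representative per symmetry orbit of length-``n`` paths.

    Parameters
    ----------
    n : int
        Number of primitive segments per path.
    chaining : str
        Which primitive sequences are admissible: ``"all"`` (every one of
        the 16**n combinations), ``"no_retrace"`` (a segment never exactly
        reverses its predecessor) or ``"tangent"`` (each segment starts in
        the direction its predecessor ended).
    include_reversal : bool
        If true, a path and its reverse traversal share an orbit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > _MAX_ENUM_N:
        raise ResourceError(
            f"enumeration for n={n} needs 16^{n} sequences; supported up to n={_MAX_ENUM_N}"
        )
    grids = np.meshgrid(*([np.arange(16, dtype=np.uint8)] * n), indexing="ij")
    seqs = np.stack([g.ravel() for g in grids], axis=1)  # (16^n, n)
    seqs = seqs[_chaining_mask(seqs, chaining)]
    codes = []
    weights = (16 ** np.arange(n - 1, -1, -1)).astype(np.int64)
    for name in _SYM_MATRICES:
        perm = np.array(_sym_permutation(name), dtype=np.uint8)
        imgs = perm[seqs]
        codes.append(imgs.astype(np.int64) @ weights)
        if include_reversal:
            rev = np.array(_REVERSE, dtype=np.uint8)[imgs[:, ::-1]]
            codes.append(rev.astype(np.int64) @ weights)
    canon = np.min(np.stack(codes, axis=0), axis=0)
    reps = np.unique(canon)
    out = []
    for code in reps:
        segs = []
        for w in weights:
            segs.append(int(code // w))
            code = code % w
        out.append(PathSpec(tuple(segs)))
    return out


# ---------------------------------------------------------------------------
# Movement classes
# ---------------------------------------------------------------------------

CLASS_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

_CLASSIFY_FPP = 12  # fine sampling so arc geometry decides D and F reliably
_TOL = 1e-9


def _self_intersects(points: np.ndarray) -> bool:
    from shapely.geometry import LineString

    return not LineString(points).is_simple


def classify(spec: PathSpec) -> str:
    """Assign one of the eight movement-class labels to a 4-segment path.

    The classes capture how a path relates to efficient goal-directed travel:
    A maximally efficient; B retraces itself back to its origin; C moves
    toward multiple quadrants; D stays within a single quadrant; E partially
    retraces itself; F self-intersects without closing; G repeats a
    component pattern; H closes without retracing.  Predicates are tested in
    the fixed precedence order A, B, G, H, E, F, D, C; the first match wins,
    so every 4-segment path receives exactly one label.
    """
    segs = spec.segments
    if len(segs) != 4:
        raise InvalidSpecError("movement classes are defined for 4-segment paths")
    if rarity(spec) <= _TOL:
        return "A"
    closed = net_displacement(spec) <= _TOL
    if closed and segs[2] == _REVERSE[segs[1]] and segs[3] == _REVERSE[segs[0]]:
        return "B"
    if segs[2] == segs[0] and segs[3] == segs[1]:
        return "G"
    if closed:
        return "H"
    if any(segs[i + 1] == _REVERSE[segs[i]] for i in range(3)):
        return "E"
    # geometric predicates (self-intersection, quadrant membership) run on the
    # canonical representative so the label is symmetry-invariant even when
    # tangential touches sit at floating-point precision
    pts = compose(canonicalize(spec), _CLASSIFY_FPP).points
    if _self_intersects(pts):
        return "F"
    interior = pts[1:]
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        if np.all(sx * interior[:, 0] >= -_TOL) and np.all(sy * interior[:, 1] >= -_TOL):
            return "D"
    return "C"


# ---------------------------------------------------------------------------
# Stimulus sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusItem:
    path_id: str
    spec: PathSpec
    condition: str = ""
    movement_class: Optional[str] = None
    world: Optional[object] = None  # an inverse_planner.World when attached


@dataclass(frozen=True)
class StimulusSet:
    study: str
    items: tuple[StimulusItem, ...]
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.items)

    def specs(self) -> list[PathSpec]:
        return [it.spec for it in self.items]


@functools.lru_cache(maxsize=4)
def _classified_space(n: int = 4) -> dict[str, list[PathSpec]]:
    by_class: dict[str, list[PathSpec]] = {c: [] for c in CLASS_LABELS}
    for spec in enumerate_path_space(n):
        by_class[classify(spec)].append(spec)
    return by_class


def build_study1_set(seed: int) -> StimulusSet:
    """The 23-path point-display set: both maximally efficient paths plus
    three random draws from each of the seven remaining movement classes."""
    by_class = _classified_space(4)
    if len(by_class["A"]) != 2:
        raise ConstructionError(
            f"expected exactly 2 maximally efficient canonical paths, found {len(by_class['A'])}"
        )
    children = np.random.SeedSequence(seed).spawn(len(CLASS_LABELS) - 1)
    items = [
        StimulusItem(f"A{i}", spec, movement_class="A")
        for i, spec in enumerate(sorted(by_class["A"], key=lambda s: s.segments))
    ]
    for label, child in zip(CLASS_LABELS[1:], children):
        pool = sorted(by_class[label], key=lambda s: s.segments)
        if len(pool) < 3:
            raise ConstructionError(f"movement class {label} has only {len(pool)} members")
        rng = np.random.default_rng(child)
        for i, idx in enumerate(rng.choice(len(pool), size=3, replace=False)):
            items.append(StimulusItem(f"{label}{i}", pool[idx], movement_class=label))
    return StimulusSet("study1", tuple(items), seed=seed)


def _study2_basics() -> list[PathSpec]:
    """Seven deterministic 2-primitive basics whose second segment does not
    retrace the first (first seven canonical classes in lexicographic order)."""
    basics = [
        s for s in enumerate_path_space(2) if s.segments[1] != _REVERSE[s.segments[0]]
    ]
    basics.sort(key=lambda s: s.segments)
    return basics[:7]


def build_study2_set() -> StimulusSet:
    """The 21-trajectory repetition set.

    Each of 7 basic two-primitive paths appears with 0, 1 or 2 out-and-back
    repetitions.  One-repetition items (basic + its reversal) are rotated
    90 degrees counterclockwise and reflected over the x-axis; two-repetition
    items (two full out-and-back cycles) are rotated 180 degrees.  Segment
    lengths are rescaled so every item travels the same total distance
    (that of the longest unscaled item).
    """
    raw: list[tuple[str, int, PathSpec]] = []
    for i, basic in enumerate(_study2_basics()):
        segs = basic.segments
        cycle = segs + _reverse_segments(segs)
        raw.append((f"P{i}", 0, basic))
        raw.append((f"P{i}", 1, transform(PathSpec(cycle), "rot90ccw_reflect_x")))
        raw.append((f"P{i}", 2, transform(PathSpec(cycle + cycle), "rot180ccw")))
    target = max(path_length(s) for _, _, s in raw)
    items = []
    for pid, reps, spec in raw:
        scaled = replace(spec, scale=target / path_length(spec))
        items.append(
            StimulusItem(f"{pid}_rep{reps}", scaled, condition=f"repetitions={reps}")
        )
    return StimulusSet("study2", tuple(items))


def _path_means(ratings, items: Sequence[StimulusItem]) -> dict[str, float]:
    """Per-path mean rating from a judgments table, Series or mapping."""
    import pandas as pd

    if isinstance(ratings, pd.DataFrame):
        return ratings.groupby("path_id")["rating"].mean().to_dict()
    if isinstance(ratings, pd.Series):
        return ratings.to_dict()
    return dict(ratings)


def build_study3_set(
    study1_set: StimulusSet,
    synthetic_ratings,
    seed: int,
    rating_threshold: float = 4.25,
    world_factory: Optional[Callable[[Trajectory], object]] = None,
) -> StimulusSet:
    """The bordered/unbordered set: 12 base paths from the 23-path set.

    One path is drawn per movement class (8), then 4 more from the paths
    whose mean communicativeness rating meets ``rating_threshold``.  Each
    base path is emitted twice, tagged ``bordered`` and ``unbordered``; if
    ``world_factory`` is given (e.g. a lake-corridor builder), bordered items
    carry the world it returns for the rendered trajectory.
    """
    means = _path_means(synthetic_ratings, study1_set.items)
    missing = [it.path_id for it in study1_set.items if it.path_id not in means]
    if missing:
        raise ConstructionError(f"ratings missing for paths: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen: list[StimulusItem] = []
    for label in CLASS_LABELS:
        pool = [it for it in study1_set.items if it.movement_class == label]
        chosen.append(pool[rng.integers(len(pool))])
    chosen_ids = {it.path_id for it in chosen}
    high = [
        it
        for it in study1_set.items
        if it.path_id not in chosen_ids and means[it.path_id] >= rating_threshold
    ]
    if len(high) < 4:
        raise ConstructionError(
            f"only {len(high)} unchosen paths have mean rating >= {rating_threshold}; "
            "need 4 (ratings too flat or threshold too high)"
        )
    idx = rng.choice(len(high), size=4, replace=False)
    chosen.extend(high[i] for i in idx)
    items = []
    for it in chosen:
        world = None
        if world_factory is not None:
            world = world_factory(compose(it.spec))
        items.append(
            StimulusItem(it.path_id, it.spec, "bordered", it.movement_class, world)
        )
        items.append(StimulusItem(it.path_id, it.spec, "unbordered", it.movement_class))
    return StimulusSet("study3", tuple(items), seed=seed)
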