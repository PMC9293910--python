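# Methods

`effcomm` implements a computational account of how an observer decides that
a 2-D movement was produced to *communicate* rather than to act on the
physical world. The account has two layers: a simple geometric statistic
(rarity) and a Bayesian inverse-planning observer that scores how strongly a
trajectory reveals the absence of any world-directed goal. A synthetic-data
generator and a small statistical toolkit close the loop so the whole
pipeline is testable without human data.

## Path space

Stimuli are polylines built by chaining primitives drawn from a fixed
alphabet of 16 elementary segments: 4 cardinal unit steps (length 1), 4
diagonal steps (length √2), and 8 quarter-circle arcs of radius 1 (length
π/2), parameterized by start tangent (N/E/S/W) × turn direction (CW/CCW).
All primitive displacements are integer-valued on the unit grid, which keeps
chaining, reversal, and symmetry operations exact. Rendering subdivides
each primitive into `frames_per_primitive` equal-arc-length steps (default
3, so a 4-primitive path yields 12 scored frame steps).

Two paths are the *same shape* if one is a rotation or reflection of the
other; the 8 symmetries of the square act on the primitive alphabet as a
permutation (reflections flip arc turn direction), so canonicalization is
the lexicographic minimum of a path's 8 (optionally 16, with traversal
reversal) id-sequence images. This is exact integer arithmetic — no
geometric tolerance enters the equivalence.

**Enumeration counts.** For 4-primitive paths, Burnside's lemma over the 8
square symmetries acting primitive-wise gives (16⁴ + 4·2⁴)/8 = 8200 orbits:
rotations fix no primitive and each reflection fixes exactly two. The
package therefore enumerates 8200 canonical 4-segment paths under its
default convention ("all combinations admissible"). Counts under the other
supported conventions: 6751 (a segment never exactly reverses its
predecessor), 42 (tangent continuity), 4196 (reversal included in the
equivalence). None of these equals the 4520 sometimes quoted for this kind
of stimulus space; that figure evidently relies on an additional reduction
that is not derivable from the stated construction, so `enumerate_path_space`
reports counts per convention rather than forcing a match.

## Rarity

For a path p with total traveled distance d(p) and straight start-to-end
distance d*(p),

    r(p) = 1 − d*(p) / d(p)  ∈ [0, 1].

r = 0 iff the path is maximally efficient (a straight chain) and r = 1 iff
the path returns to its origin. Rarity, length, and the movement-class
label are invariant under all square symmetries.

## Movement classes

Eight a-priori classes describe how a 4-primitive path relates to efficient
travel. The informal descriptions are made total and deterministic by
testing formal predicates in a fixed precedence order (first match wins):

| order | label | predicate |
|---|---|---|
| 1 | A | r(p) = 0 (maximally efficient) |
| 2 | B | segments are X Y rev(Y) rev(X): retraces itself to its origin |
| 3 | G | the 4 segments are a repeated 2-segment block (a pattern) |
| 4 | H | endpoint = origin without retracing |
| 5 | E | some segment exactly reverses its predecessor, path stays open |
| 6 | F | rendered polyline self-intersects, path stays open |
| 7 | D | all frame points lie in one closed quadrant |
| 8 | C | otherwise (moves toward multiple quadrants) |

The class-E reading — an out-and-back excursion *anywhere* in the path, not
only at its end — was a genuine design choice; it matches the intuition that
a partial retrace mid-path already signals inefficiency. Geometric
predicates (E's complement F, and D) are evaluated on the canonical
representative at 12 frames/primitive so that tangential touches at
floating-point precision cannot make the label depend on orientation.
Self-intersection is delegated to GEOS (`shapely`'s `is_simple`).

## Stimulus sets

* **23-path set** (`build_study1_set`): both maximally efficient canonical
  paths (there are exactly two: the all-cardinal and all-diagonal lines)
  plus 3 seeded random draws from each of classes B–H.
* **Repetition set** (`build_study2_set`): 7 deterministic two-primitive
  basics (first seven canonical classes in lexicographic order whose second
  segment does not retrace the first), each emitted with 0, 1, or 2
  out-and-back repetitions. One-repetition items are rotated 90° CCW and
  reflected over the x-axis, two-repetition items rotated 180°, and each
  item's `scale` is set so all 21 trajectories travel the same total
  distance (that of the longest unscaled item — the equality is stated by
  the design, the common value is not, so the longest item is the natural
  anchor that only stretches, never shrinks).
* **Border set** (`build_study3_set`): 12 base paths from the 23-path set —
  one per class, then 4 more among paths whose mean synthetic rating is at
  least 4.25 — each emitted in `bordered` and `unbordered` conditions. The
  builder takes a `world_factory` callable (the pipeline passes
  `make_bordered_world`) so the path layer stays independent of the
  planning layer.

## The inverse-planning observer

The observer assumes a noisy-rational agent pursuing some world-directed
goal g in an arena W, with goals on a uniform lattice (pitch
`goal_spacing`, default 0.5 arena units) covering the trajectory's bounding
box padded by 1 unit — goals beyond the path must be representable. At
each frame step from state s, the agent chooses among K candidate steps of
the observed length (the observed heading plus K−1 uniformly spaced
alternatives; default K = 16, matching the primitive alphabet's angular
resolution), excluding candidates that leave the arena or enter an
obstacle. Candidate probabilities follow a Boltzmann policy,

    p(a | s, g) ∝ exp(−β (|a| + C(s + a, g))),

with rationality β (default 2.0 per arena unit of cost; β = 0 is a uniform
policy, large β a deterministic shortest-path agent; the default was chosen
once so that the 23-path class ordering is qualitatively sensible — straight
paths near the floor, closed and repetitive paths near the top).
Marginalizing over goals with the uniform prior gives the per-frame log
marginal likelihood of world-directedness

    ℓ_t = log Σ_g (1/|G|) p(a_{1:t} | g),

computed with cumulative per-goal log-likelihoods and log-sum-exp; ℓ_t is
non-increasing by construction. The communicativeness score is s = −ℓ_T at
the final frame. A single fixed world per evaluation means the world prior
is a constant and drops out of all comparisons.

**Cost-to-go C.** Without obstacles, C is the exact Euclidean distance.
With obstacles, C uses a line-of-sight shortcut — the Euclidean distance
whenever the straight segment to the goal misses every obstacle — and
otherwise the shortest path on an 8-connected navigation grid (pitch
`grid_resolution`, default 0.1; diagonal cost h√2; Dijkstra via
`scipy.sparse.csgraph`, one cached distance field per goal). The octile
metric overestimates free-space distance by up to ~8%, which without the
shortcut is enough to distort scores for near-efficient paths in corridor
worlds. Obstacle membership is boundary-inclusive: a point exactly on a
lake's edge is not passable, which prevents spurious passable slivers where
lakes meet the arena rim. Passable points whose nearest grid cell is
blocked (possible at polygon boundaries) snap to the nearest passable cell.

**Numerical floors.** Per-step log-probabilities are floored at −745
(≈ log of the smallest positive double); goals unreachable from every
candidate receive the floor rather than NaN.

## Bordered worlds

`make_bordered_world` buffers the trajectory polyline by `margin` (default
0.4 units — half a primitive's extent, close enough to flank the path while
leaving the dot visibly inside a corridor) and subtracts the corridor from
the padded arena; the remainder becomes impassable "lake" polygons (with
interior holes preserved when the corridor is fully enclosed). A geometry
error is raised if any frame point ends up closer than margin/2 to a lake.
Restricting goals and alternative actions to the corridor makes the same
trajectory consistent with efficient world-directed travel, so
score(bordered) ≤ score(unbordered) — the model analogue of the border
manipulation — which the tests verify on all 12 construction pairs.

## Synthetic judgments

`simulate_judgments` generates Likert (1–7) communicativeness ratings with

    rating = clamp(round(a + b·z(x) + u_p + ε), 1, 7),

where z standardizes the per-path predictor x (rarity or model score),
u_p ~ N(0, τ²) is a participant intercept and ε ~ N(0, σ²) trial noise.
Defaults: a = 4 (scale midpoint), b = 1.2, τ = 0.5, σ = 1.0, 30
participants — the sample size of the point-display experiments. The
rounded-clamped Gaussian is a pipeline-testing stand-in, not a model of
human raters: it produces monotone predictor–rating links with realistic
ordinal ties, but no participant-specific scale use, order effects, or
heavy-tailed responding. Passing tests therefore validate the *machinery*
(estimators, resampling, determinism), not claims about real data. Under
these defaults the rarity↔mean-rating correlation on the 23-path set lands
deep in the strong-positive regime (r ≈ 0.95–1.0), comfortably reproducing
the qualitative finding that rarer paths are rated more communicative.

## Statistics

* **Correlations** are Pearson r over per-path mean ratings with 95%
  percentile bootstrap CIs resampling paths (10,000 resamples by default);
  degenerate resamples are dropped, and the interval is clamped to bracket
  the point estimate (percentile intervals in n = 23 samples occasionally
  exclude it). Measured coverage at n = 23, ρ = 0.8 is ~93% (500
  replications), within the 90–99% band the tests enforce.
* **Calibration** of model scores to the rating scale is ordinary least
  squares; per-class discrepancy is the mean signed residual (fitted −
  mean rating), positive when the model rates the class as more
  communicative than raters do.
* **Exclusion permutation test.** The claim "excluding path subset S
  increases the correlation" is tested against a null of equally sized
  uniformly random exclusions: Δr_obs = r(without S) − r(all), p = (1 +
  #{Δr_null ≥ Δr_obs})/(n_perm + 1). Subsets are enumerated exhaustively
  when there are at most n_perm of them. What was permuted in the original
  analyses is not stated; permuting the identity of the excluded subset
  directly targets the claim being made.
* **Linking-slope recovery** uses a *crossed* (participants × paths)
  percentile bootstrap. Both factors of the design are sampled — raters
  from a population, paths from an 8200-path space — so both variance
  components belong in the interval; resampling either factor alone
  under-covers the true slope (~0.81/0.83 vs ~0.95 measured at the
  generator defaults), partly because the ordinal link attenuates the OLS
  slope (mean recovered ≈ 1.16 for b = 1.2).
* **Repetition trend** is the OLS slope of path-mean rating on repetition
  count (0/1/2) — the fixed-effect analogue of a mixed-effects repetition
  coefficient; mixed models are out of scope.

All resampling is seed-deterministic; results carry their seeds and
resample counts. The pipeline derives one sub-seed per stage from the
global seed via `numpy` seed sequences.

## Problem sizes

The default test and pipeline sizes are chosen to keep a full run on one
CPU in minutes: exhaustive symmetry oracles at 1–2 primitives, 200 sampled
orbits at 4 primitives, 500-replication coverage studies at 1000 bootstrap
resamples, 200-replication permutation calibration at 500 permutations, and
100-replication slope recovery at 1000 resamples. The full pipeline
(stimuli → scores → judgments → report) takes a few seconds at default
settings.

## Known limitations

* The observer scores rendered frames, so comparisons are meaningful at a
  fixed `frames_per_primitive`; scores grow with the number of scored steps.
* The candidate-action set ties the observer's angular resolution to K;
  very large β makes scores sensitive to whether the observed heading
  exactly matches a candidate.
* Obstacle rasterization is conservative (cell centers); extremely thin
  corridors relative to `grid_resolution` can disconnect the navigation
  grid even when the continuous corridor is connected.
* The raw marginal ℓ_t is reported rather than a normalized posterior
  against an explicit non-world-directed alternative; both carry the same
  ordering information over paths, and the two-hypothesis variant can be
  built from `world_directedness_curve` and the β = 0 closed form if
  needed.
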