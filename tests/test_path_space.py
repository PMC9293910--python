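"""Geometry, symmetry and taxonomy of the primitive path space."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effcomm import path_space as ps
from conftest import random_spec

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


class TestPrimitives:
    def test_sixteen_distinct(self):
        prims = ps.list_primitives()
        assert len(prims) == 16
        assert len({p.name for p in prims}) == 16
        kinds = {k: sum(p.kind == k for p in prims) for k in ("cardinal", "diagonal", "arc")}
        assert kinds == {"cardinal": 4, "diagonal": 4, "arc": 8}

    def test_lengths(self):
        for p in ps.list_primitives():
            expected = {"cardinal": 1.0, "diagonal": SQRT2, "arc": math.pi / 2}[p.kind]
            assert p.length == pytest.approx(expected)

    def test_cardinal_displacements_are_unit_vectors(self):
        got = {p.heading: p.displacement for p in ps.PRIMITIVES if p.kind == "cardinal"}
        assert got == {"N": (0, 1), "E": (1, 0), "S": (0, -1), "W": (-1, 0)}

    def test_arc_chord_magnitude(self):
        for p in ps.PRIMITIVES:
            if p.kind == "arc":
                assert math.hypot(*p.displacement) == pytest.approx(SQRT2)

    def test_arc_geometry_north_cw(self):
        # quarter circle of radius 1 about (1, 0): ends at (1, 1) heading east
        p = ps.primitive_by_name("arcN_cw")
        assert p.displacement == (1, 1)
        assert p.end_tangent() == (1, 0)

    def test_reversal_is_involution(self):
        for p in ps.PRIMITIVES:
            assert ps.reverse_primitive(ps.reverse_primitive(p.id)) == p.id
            q = ps.PRIMITIVES[ps.reverse_primitive(p.id)]
            assert q.displacement == (-p.displacement[0], -p.displacement[1])


# ---------------------------------------------------------------------------
# Composition and rendering
# ---------------------------------------------------------------------------


class TestCompose:
    def test_unit_segment_equal_subdivision(self):
        traj = ps.compose(ps.PathSpec(("N",)), 3)
        np.testing.assert_allclose(
            traj.points, [[0, 0], [0, 1 / 3], [0, 2 / 3], [0, 1]], atol=1e-12
        )

    def test_chaining_frame_count_and_endpoint(self):
        traj = ps.compose(ps.PathSpec(("N", "E")), 3)
        assert traj.n_frames == 7
        np.testing.assert_allclose(traj.points[-1], [1, 1], atol=1e-12)

    def test_arc_frames_lie_on_circle(self):
        traj = ps.compose(ps.PathSpec(("arcN_cw",)), 5)
        radii = np.linalg.norm(traj.points - np.array([1.0, 0.0]), axis=1)
        np.testing.assert_allclose(radii, 1.0, atol=1e-12)
        np.testing.assert_allclose(traj.points[-1], [1, 1], atol=1e-12)

    def test_equal_arc_length_steps(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = random_spec(rng)
            traj = ps.compose(spec, 4)
            steps = np.linalg.norm(traj.steps(), axis=1)
            per_prim = steps.reshape(len(spec.segments), 4)
            # within a primitive every sub-step spans equal arc length, hence
            # equal chord length
            assert np.allclose(per_prim, per_prim[:, :1], atol=1e-12)

    def test_unknown_primitive_rejected(self):
        with pytest.raises(ps.InvalidSpecError):
            ps.PathSpec((42,))
        with pytest.raises(ps.InvalidSpecError):
            ps.PathSpec(("NNE",))

    def test_empty_spec_rejected(self):
        with pytest.raises(ps.InvalidSpecError):
            ps.PathSpec(())


# ---------------------------------------------------------------------------
# Lengths, displacement, rarity
# ---------------------------------------------------------------------------


class TestRarity:
    @pytest.mark.parametrize(
        "names, length, dstar",
        [
            (("N", "N", "N", "N"), 4.0, 4.0),
            (("N", "E"), 2.0, SQRT2),
            (("N", "N", "S", "S"), 4.0, 0.0),
        ],
    )
    def test_length_and_net_displacement(self, names, length, dstar):
        spec = ps.PathSpec(names)
        assert ps.path_length(spec) == pytest.approx(length)
        assert ps.net_displacement(spec) == pytest.approx(dstar)

    def test_straight_path_rarity_zero(self):
        assert ps.rarity(ps.PathSpec(("N", "N", "N", "N"))) == 0.0
        assert ps.rarity(ps.PathSpec(("NE", "NE"))) == 0.0

    def test_corner_path(self):
        assert ps.rarity(ps.PathSpec(("N", "E"))) == pytest.approx(1 - SQRT2 / 2)

    def test_closed_path_rarity_one(self):
        assert ps.rarity(ps.PathSpec(("N", "E", "S", "W"))) == 1.0

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert 0.0 <= ps.rarity(random_spec(rng)) <= 1.0


# ---------------------------------------------------------------------------
# Symmetries
# ---------------------------------------------------------------------------

_INVERSE = {
    "identity": "identity",
    "rot90": "rot270",
    "rot270": "rot90",
    "rot180": "rot180",
    "reflect_x": "reflect_x",
    "reflect_y": "reflect_y",
    "reflect_diag": "reflect_diag",
    "reflect_antidiag": "reflect_antidiag",
}


class TestTransform:
    def test_rotation_of_straight_line(self):
        got = ps.transform(ps.PathSpec(("E",) * 4), "rot90")
        assert got.names() == ("N", "N", "N", "N")

    def test_unsupported_symmetry(self):
        with pytest.raises(ValueError):
            ps.transform(ps.PathSpec(("N",)), "rot45")

    @pytest.mark.parametrize("sym", ps.SYMMETRIES)
    def test_rendering_commutes(self, sym):
        rng = np.random.default_rng(3)
        m = ps._sym_matrix(sym)
        for _ in range(10):
            spec = random_spec(rng)
            direct = ps.compose(spec, 4).points @ m.T
            via_ids = ps.compose(ps.transform(spec, sym), 4).points
            np.testing.assert_allclose(via_ids, direct, atol=1e-12)

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=6), st.sampled_from(ps.SYMMETRIES))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rarity_invariant(self, segs, sym):
        spec = ps.PathSpec(tuple(segs))
        assert ps.rarity(ps.transform(spec, sym)) == pytest.approx(ps.rarity(spec), abs=1e-12)
        assert ps.path_length(ps.transform(spec, sym)) == pytest.approx(ps.path_length(spec))

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=6), st.sampled_from(ps.SYMMETRIES))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverse_restores(self, segs, sym):
        spec = ps.PathSpec(tuple(segs))
        assert ps.transform(ps.transform(spec, sym), _INVERSE[sym]).segments == spec.segments

    def test_masking_compositions_supported(self):
        # the repetition stimuli rotate 90 deg CCW then reflect over x
        spec = ps.PathSpec(("N", "E"))
        got = ps.transform(spec, "rot90ccw_reflect_x")
        expect = ps.transform(spec, "reflect_antidiag")
        assert got.segments == expect.segments


# ---------------------------------------------------------------------------
# Canonicalization vs a brute-force orbit oracle
# ---------------------------------------------------------------------------


def _oracle_orbit(segs: tuple[int, ...]) -> frozenset:
    """Independent orbit: apply each symmetry to the *rendered* trajectory and
    identify which primitive sequences reproduce the transformed points."""
    renderings = {}
    for sym in ps.SYMMETRIES:
        m = ps._sym_matrix(sym)
        pts = ps.compose(ps.PathSpec(segs), 4).points @ m.T
        renderings[sym] = (np.round(pts, 9) + 0.0).tobytes()  # normalize -0.0
    # match against all sequences of the same length
    n = len(segs)
    matches = set()
    import itertools

    for cand in itertools.product(range(16), repeat=n):
        key = (np.round(ps.compose(ps.PathSpec(cand), 4).points, 9) + 0.0).tobytes()
        if key in renderings.values():
            matches.add(cand)
    return frozenset(matches)


class TestCanonicalize:
    def test_rotated_lines_share_key(self):
        assert ps.canonical_key(ps.PathSpec(("N",) * 4)) == ps.canonical_key(
            ps.PathSpec(("E",) * 4)
        )

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            spec = random_spec(rng)
            c = ps.canonicalize(spec)
            assert ps.canonicalize(c).segments == c.segments

    def test_exhaustive_orbits_length_one(self):
        # brute-force oracle partition
        seen = set()
        oracle_orbits = []
        for i in range(16):
            if i in seen:
                continue
            orbit = {s[0] for s in _oracle_orbit((i,))}
            seen |= orbit
            oracle_orbits.append(frozenset(orbit))
        key_orbits = {}
        for i in range(16):
            key_orbits.setdefault(ps.canonical_key(ps.PathSpec((i,))), set()).add(i)
        assert {frozenset(v) for v in key_orbits.values()} == set(oracle_orbits)

    def test_exhaustive_orbits_length_two(self):
        import itertools

        key_orbits = {}
        for segs in itertools.product(range(16), repeat=2):
            key_orbits.setdefault(ps.canonical_key(ps.PathSpec(segs)), set()).add(segs)
        # oracle: grouping by brute-force rendering comparison
        seen = set()
        for segs in itertools.product(range(16), repeat=2):
            if segs in seen:
                continue
            orbit = _oracle_orbit(segs)
            seen |= orbit
            assert orbit in {frozenset(v) for v in key_orbits.values()}
        assert len(key_orbits) == 34


class TestEnumerate:
    def test_single_primitive_classes(self):
        # all cardinals equivalent, all diagonals equivalent, all arcs equivalent
        assert len(ps.enumerate_path_space(1)) == 3

    def test_length_two_count_matches_oracle(self):
        assert len(ps.enumerate_path_space(2)) == 34

    def test_representatives_are_canonical(self):
        for spec in ps.enumerate_path_space(2):
            assert ps.canonical_key(spec) == spec.segments

    def test_conventions_reported(self):
        counts = {
            c: len(ps.enumerate_path_space(2, chaining=c))
            for c in ("all", "no_retrace", "tangent")
        }
        assert counts["all"] > counts["no_retrace"] > counts["tangent"] > 0

    def test_resource_guard(self):
        with pytest.raises(ps.ResourceError):
            ps.enumerate_path_space(9)


# ---------------------------------------------------------------------------
# Movement classes
# ---------------------------------------------------------------------------


class TestClassify:
    @pytest.mark.parametrize(
        "names, label",
        [
            (("N", "N", "N", "N"), "A"),  # maximally efficient
            (("NE", "NE", "NE", "NE"), "A"),
            (("N", "N", "S", "S"), "B"),  # retraces to origin
            (("N", "E", "W", "S"), "B"),
            (("arcN_cw", "arcE_cw", "arcS_cw", "arcW_cw"), "H"),  # full circle
            (("N", "E", "S", "W"), "H"),  # square loop, no retrace
            (("N", "E", "N", "E"), "G"),  # repeated two-segment block
            (("N", "S", "E", "E"), "E"),  # out-and-back excursion, open
            (("N", "E", "S", "E"), "D"),  # stays in the first quadrant
            (("N", "NW", "E", "SE"), "C"),  # multiple quadrants, simple
        ],
    )
    def test_examples(self, names, label):
        assert ps.classify(ps.PathSpec(names)) == label

    def test_self_intersecting_open_path_is_F(self):
        # doubles back onto its own first leg without closing
        spec = ps.PathSpec(("E", "E", "NW", "S"))
        assert ps.net_displacement(spec) > 0
        assert ps.classify(spec) == "F"

    def test_non_four_segment_rejected(self):
        with pytest.raises(ps.InvalidSpecError):
            ps.classify(ps.PathSpec(("N", "E")))

    def test_total_partition(self):
        labels = [ps.classify(s) for s in ps.enumerate_path_space(4)[:500]]
        assert set(labels) <= set(ps.CLASS_LABELS)

    def test_invariant_under_symmetry(self):
        rng = np.random.default_rng(9)
        space = ps.enumerate_path_space(4)
        for idx in rng.choice(len(space), size=50, replace=False):
            spec = space[idx]
            for sym in ps.SYMMETRIES:
                assert ps.classify(ps.transform(spec, sym)) == ps.classify(spec)


# ---------------------------------------------------------------------------
# Stimulus builders
# ---------------------------------------------------------------------------


class TestStudy1Builder:
    def test_counts(self, study1):
        assert len(study1) == 23
        assert sum(1 for it in study1.items if it.movement_class == "A") == 2

    def test_class_a_paths_are_maximally_efficient(self, study1):
        for it in study1.items:
            if it.movement_class == "A":
                assert ps.rarity(it.spec) == 0.0

    def test_no_duplicate_canonical_forms(self, study1):
        keys = {ps.canonical_key(it.spec) for it in study1.items}
        assert len(keys) == 23

    def test_deterministic(self, study1):
        again = ps.build_study1_set(seed=11)
        assert [it.spec.segments for it in again.items] == [
            it.spec.segments for it in study1.items
        ]

    def test_three_per_remaining_class(self, study1):
        from collections import Counter

        counts = Counter(it.movement_class for it in study1.items)
        assert all(counts[c] == 3 for c in "BCDEFGH")


class TestStudy2Builder:
    def test_twenty_one_trajectories(self, study2):
        assert len(study2) == 21

    def test_equal_total_distance(self, study2):
        lengths = [ps.path_length(it.spec) for it in study2.items]
        assert max(lengths) - min(lengths) < 1e-9

    def test_two_repetition_paths_visit_origin_three_times(self, study2):
        for it in study2.items:
            if it.condition != "repetitions=2":
                continue
            traj = ps.compose(it.spec)
            d = np.linalg.norm(traj.points - np.asarray(it.spec.origin), axis=1)
            assert int(np.sum(d < 1e-9)) == 3

    def test_repetition_versions_share_base(self, study2):
        reps = {}
        for it in study2.items:
            base = it.path_id.split("_")[0]
            reps.setdefault(base, []).append(it.condition)
        assert len(reps) == 7
        assert all(sorted(v) == [f"repetitions={k}" for k in range(3)] for v in reps.values())


@pytest.fixture(scope="module")
def study3(study1):
    from effcomm import synthetic_data as sd

    rar = [ps.rarity(it.spec) for it in study1.items]
    ratings = sd.simulate_judgments(
        [it.path_id for it in study1.items], rar, sd.LinkingParams(seed=4)
    )
    return ps.build_study3_set(study1, ratings, seed=4)


class TestStudy3Builder:
    def test_twelve_base_paths_two_conditions(self, study3):
        assert len(study3) == 24
        assert len({it.path_id for it in study3.items}) == 12
        assert {it.condition for it in study3.items} == {"bordered", "unbordered"}

    def test_one_path_per_class_among_first_selections(self, study3):
        base = []
        seen = set()
        for it in study3.items:
            if it.path_id not in seen:
                seen.add(it.path_id)
                base.append(it)
        assert {it.movement_class for it in base[:8]} == set(ps.CLASS_LABELS)

    def test_deterministic(self, study1, study3):
        from effcomm import synthetic_data as sd

        rar = [ps.rarity(it.spec) for it in study1.items]
        ratings = sd.simulate_judgments(
            [it.path_id for it in study1.items], rar, sd.LinkingParams(seed=4)
        )
        again = ps.build_study3_set(study1, ratings, seed=4)
        assert [it.path_id for it in again.items] == [it.path_id for it in study3.items]

    def test_flat_ratings_raise(self, study1):
        import pandas as pd

        flat = pd.DataFrame(
            {
                "participant": 0,
                "path_id": [it.path_id for it in study1.items],
                "condition": "",
                "rating": 1,
            }
        )
        with pytest.raises(ps.ConstructionError):
            ps.build_study3_set(study1, flat, seed=0)
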