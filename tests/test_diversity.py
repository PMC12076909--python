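"""Diversity scoring: disconnection sets, C_M, Jaccard, CDS, baselines."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from retrodiverse.diversity import (
    build_cm,
    cds,
    cds_of_sets,
    extract_disconnections,
    formed_bonds,
    jaccard_distance,
    route_length_stats,
    unique_molecule_counts,
)
from retrodiverse.graph import GraphError, SynthesisRoute
from retrodiverse.synthetic import generate_route_set

f = frozenset

BOND_SETS = st.lists(
    st.frozensets(
        st.tuples(st.sampled_from("abcd"), st.sampled_from("efgh")), max_size=4
    ),
    max_size=6,
)


class TestFormedBonds:
    def test_set_difference(self):
        assert formed_bonds({("1", "2"), ("2", "3")}, {("2", "3")}) == f({("1", "2")})

    def test_identical_sets_form_nothing(self):
        assert formed_bonds({("1", "2")}, {("1", "2")}) == f()

    def test_no_reactant_bonds_keeps_all(self):
        assert formed_bonds({("1", "2"), ("3", "4")}, set()) == f(
            {("1", "2"), ("3", "4")}
        )

    def test_order_normalization(self):
        assert formed_bonds({("b", "a")}, set()) == f({("a", "b")})


class TestExtractDisconnections:
    def test_union_over_reactions_with_set_semantics(self):
        r = SynthesisRoute(
            root="m0",
            children={"m0": ["r0"], "r0": ["m1"], "m1": ["r1"], "r1": ["b"]},
            reaction_bonds={
                "r0": f({("a1", "a2"), ("a3", "a4")}),
                "r1": f({("a3", "a4"), ("a5", "a6")}),
            },
        )
        assert extract_disconnections(r) == f(
            {("a1", "a2"), ("a3", "a4"), ("a5", "a6")}
        )

    def test_missing_labels_error_names_reaction(self):
        r = SynthesisRoute(root="m0", children={"m0": ["r0"], "r0": ["b"]})
        with pytest.raises(GraphError, match="r0"):
            extract_disconnections(r)


class TestBuildCm:
    def test_superset_dropped(self):
        assert build_cm([f("a"), f("ab")]) == [f("a")]

    def test_incomparable_sets_kept(self):
        assert build_cm([f("a"), f("b")]) == [f("a"), f("b")]

    def test_duplicates_collapse(self):
        assert build_cm([f("a"), f("a")]) == [f("a")]

    def test_empty_sets_dropped(self):
        assert build_cm([f(), f("a")]) == [f("a")]

    def test_cover_mode_drops_unions(self):
        sets = [f("a"), f("b"), f("ab")]
        assert f("ab") not in build_cm(sets, minimality="cover")
        # subset mode already drops it (strict superset of {a})
        assert f("ab") not in build_cm(sets, minimality="subset")
        # a union of incomparable smaller sets that is NOT a superset of
        # any single one cannot exist for sets; cover differs on unions only
        assert build_cm([f("ab"), f("cd"), f("abcd")], "cover") == [f("ab"), f("cd")]


class TestJaccard:
    def test_identity_disjoint_and_partial(self):
        assert jaccard_distance(f("x"), f("x")) == 0.0
        assert jaccard_distance(f("x"), f("y")) == 1.0
        assert jaccard_distance(f("ab"), f("ac")) == pytest.approx(2 / 3)

    def test_both_empty_distance_zero(self):
        assert jaccard_distance(f(), f()) == 0.0

    @given(
        st.frozensets(st.integers(0, 6), max_size=5),
        st.frozensets(st.integers(0, 6), max_size=5),
        st.frozensets(st.integers(0, 6), max_size=5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_metric_properties(self, a, b, c):
        assert jaccard_distance(a, b) == jaccard_distance(b, a)
        assert jaccard_distance(a, a) == 0.0
        assert (
            jaccard_distance(a, c)
            <= jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12
        )


class TestCds:
    def test_single_route_scores_one(self):
        assert cds_of_sets([f({("a", "b")})]).score == 1.0

    @pytest.mark.parametrize("n", range(2, 7))
    def test_disjoint_ideas_score_their_count(self, n):
        sets = [f({(f"x{i}", f"y{i}")}) for i in range(n)]
        assert cds_of_sets(sets).score == pytest.approx(n)

    def test_partial_overlap_closed_form(self):
        result = cds_of_sets(
            [f({("a", "b"), ("c", "d")}), f({("a", "b"), ("e", "f")})]
        )
        assert result.score == pytest.approx(5 / 3)

    def test_empty_input_scores_zero_with_flag(self):
        result = cds_of_sets([])
        assert result.score == 0.0 and result.empty

    def test_matrix_symmetric_zero_diagonal(self):
        result = cds_of_sets([f("ab"), f("ac"), f("de")])
        mat = result.distance_matrix
        assert (mat == mat.T).all() and (mat.diagonal() == 0).all()

    @given(BOND_SETS)
    @settings(max_examples=150, derandomize=True)
    def test_score_bounds_and_disjointness(self, sets):
        result = cds_of_sets(sets)
        n = len(result.c_m)
        if n == 0:
            assert result.score == 0.0
            return
        assert 1.0 <= result.score <= n + 1e-9
        disjoint = all(
            not (a & b)
            for i, a in enumerate(result.c_m)
            for b in result.c_m[i + 1:]
        )
        assert (abs(result.score - n) < 1e-9) == disjoint

    @given(BOND_SETS, st.integers(0, 5))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_and_duplication_invariance(self, sets, seed):
        base = cds_of_sets(sets).score
        shuffled = list(sets)
        random.Random(seed).shuffle(shuffled)
        assert cds_of_sets(shuffled).score == pytest.approx(base)
        if sets:
            assert cds_of_sets(sets + [sets[0]]).score == pytest.approx(base)

    @given(BOND_SETS)
    @settings(max_examples=100, derandomize=True)
    def test_superset_routes_are_absorbed(self, sets):
        sets = [s for s in sets if s]
        if not sets:
            return
        base = cds_of_sets(sets).score
        extra = sets[0] | f({("z", "z2")})
        assert cds_of_sets(sets + [extra]).score == pytest.approx(base)

    def test_generated_route_groups_score_their_idea_count(self):
        for n_ideas in (1, 2, 4):
            routes = generate_route_set(8, n_ideas, overlap=0.0, seed=3)
            assert cds(routes).score == pytest.approx(n_ideas)


class TestBaselineMetrics:
    def _route(self, tag, inter=True):
        children = {"t": [f"r{tag}"], f"r{tag}": [f"i{tag}", f"b{tag}"]}
        if inter:
            children[f"i{tag}"] = [f"r{tag}b"]
            children[f"r{tag}b"] = [f"c{tag}"]
        return SynthesisRoute(root="t", children=children)

    def test_unique_counts_linear_route(self):
        r = self._route(0)
        counts = unique_molecule_counts([r])
        assert counts == {"unique_intermediates": 1, "unique_building_blocks": 2}

    def test_duplicate_route_counts_once(self):
        r = self._route(0)
        assert unique_molecule_counts([r, r]) == unique_molecule_counts([r])

    def test_empty_set_counts_zero(self):
        assert unique_molecule_counts([]) == {
            "unique_intermediates": 0,
            "unique_building_blocks": 0,
        }

    def test_route_length_stats_mean(self):
        routes = {"t": [self._route(0), self._route(1, inter=False)]}
        stats = route_length_stats(routes)
        assert stats["mean_reactions"] == pytest.approx(1.5)

    def test_equal_lengths_give_zero_iqr(self):
        stats = route_length_stats(
            {"a": [self._route(0)], "b": [self._route(1)]}
        )
        assert stats["iqr"] == 0.0

    def test_no_solved_targets_raises(self):
        with pytest.raises(GraphError):
            route_length_stats({"t": []})
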