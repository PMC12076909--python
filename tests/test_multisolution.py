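"""Multi-solution DFPN*: disproofs, penalties, costs, viability, route sets."""

import pytest

from retrodiverse.dfpn import (
    INF,
    DfpnSearch,
    DisproofRegistry,
    SearchBudget,
    SearchRecord,
)
from retrodiverse.graph import (
    MOLECULE,
    PathContext,
    GraphError,
    SynthesisRoute,
    route_is_valid,
)
from retrodiverse.io import write_routes
from retrodiverse.multisolution import (
    PenaltyConfig,
    apply_penalties,
    deepest_reaction,
    edge_cost,
    find_route_set,
    force_disprove,
    route_viability,
)
from retrodiverse.oracle import enumerate_routes
from retrodiverse.synthetic import NetworkSpec, counterexample_graph, generate_network

from conftest import make_diamond, make_two_route


def linear_route(n_steps: int) -> SynthesisRoute:
    children = {}
    for i in range(n_steps):
        children[f"m{i}"] = [f"r{i}"]
        children[f"r{i}"] = [f"m{i + 1}"]
    return SynthesisRoute(root="m0", children=children)


class TestDeepestReaction:
    def test_linear_route_last_reaction(self):
        assert deepest_reaction(linear_route(3)) == "r2"

    def test_branched_route_deepest_branch_wins(self):
        r = SynthesisRoute(
            root="m0",
            children={
                "m0": ["r0"],
                "r0": ["a", "b"],
                "a": ["ra"],  # depth-3 reaction
                "ra": ["a2"],
                "a2": ["ra2"],  # depth-5 reaction
                "ra2": ["leaf"],
            },
        )
        assert deepest_reaction(r) == "ra2"

    def test_tie_broken_by_traversal_order(self):
        r = SynthesisRoute(
            root="m0",
            children={
                "m0": ["r0"],
                "r0": ["a", "b"],
                "a": ["ra"], "ra": ["x"],
                "b": ["rb"], "rb": ["y"],
            },
        )
        assert deepest_reaction(r) == "ra"  # "a" branch visited first

    def test_empty_route_raises(self):
        with pytest.raises(GraphError):
            deepest_reaction(SynthesisRoute(root="bb"))


class TestPenalties:
    def test_reaction_pn_incremented(self):
        records = {"r": SearchRecord(pn=3, dn=1)}
        g = make_two_route()
        apply_penalties(["r0"], PenaltyConfig(p_reac=5), {"r0": records["r"]}, g=g)
        assert records["r"].pn == 8 and records["r"].pn_bonus == 5

    def test_default_molecule_penalty_is_zero(self):
        g = make_two_route()
        rec = SearchRecord(pn=3, dn=1)
        apply_penalties(["m0"], PenaltyConfig(p_reac=5, p_mol=0), {"m0": rec}, g=g)
        assert rec.pn == 3

    def test_infinity_saturates(self):
        g = make_two_route()
        rec = SearchRecord(pn=INF, dn=0)
        apply_penalties(["r0"], PenaltyConfig(p_reac=5), {"r0": rec}, g=g)
        assert rec.pn == INF

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(p_reac=-1)


class TestEdgeCost:
    def test_perfect_score_is_free(self):
        g = make_two_route()
        g.edge_scores[("m0", "r0")] = 1.0
        assert edge_cost(g, "m0", "r0") == 0

    def test_explicit_cost_passthrough(self):
        g = make_two_route()
        g.edge_costs[("m0", "r0")] = 3
        assert edge_cost(g, "m0", "r0") == 3

    def test_score_maps_to_neg_log(self):
        g = make_two_route()
        g.edge_scores[("m0", "r0")] = 0.1
        assert edge_cost(g, "m0", "r0") == 2  # round(-ln 0.1) = round(2.3)

    def test_absent_attributes_default_to_zero(self):
        assert edge_cost(make_two_route(), "m0", "r0") == 0

    def test_missing_edge_raises(self):
        with pytest.raises(GraphError):
            edge_cost(make_two_route(), "m0", "r9")


class TestRouteViability:
    def test_product_of_scores(self):
        r = linear_route(2)
        r.reaction_scores = {"r0": 0.9, "r1": 0.8}
        assert route_viability(r) == pytest.approx(0.72)

    def test_empty_route_scores_one(self):
        assert route_viability(SynthesisRoute(root="bb")) == 1.0

    def test_zero_score_annihilates(self):
        r = linear_route(2)
        r.reaction_scores = {"r0": 0.0, "r1": 0.8}
        assert route_viability(r) == 0.0

    def test_missing_score_names_reaction(self):
        r = linear_route(2)
        r.reaction_scores = {"r0": 0.9}
        with pytest.raises(GraphError, match="r1"):
            route_viability(r)

    def test_monotone_nonincreasing_in_length(self):
        scores = [0.95, 0.8, 0.99, 0.6]
        values = []
        for n in range(1, 5):
            r = linear_route(n)
            r.reaction_scores = {f"r{i}": scores[i] for i in range(n)}
            values.append(route_viability(r))
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestForceDisprove:
    def test_registry_idempotent(self):
        reg = DisproofRegistry()
        reg.add("r", frozenset({"a"}))
        reg.add("r", frozenset({"a"}))
        assert len(reg.entries) == 1

    def test_same_route_cannot_reappear(self):
        g = make_two_route()
        reg = DisproofRegistry()
        search = DfpnSearch(g, registry=reg)
        out = search.run(SearchBudget(100))
        first = out.strategy
        rxn = deepest_reaction(first)
        force_disprove(rxn, PathContext(frozenset({"m0"})), reg, search.records)
        out2 = search.run(SearchBudget(100))
        assert out2.status == "proved" and out2.strategy != first

    def test_node_usable_via_second_path(self):
        # rX is force-disproved under the mA branch only: the mB route
        # through the same deep reaction must still be found
        g = make_diamond()
        routes = find_route_set(
            g, PenaltyConfig(p_reac=2, max_solutions=5), SearchBudget(10_000)
        )
        assert len(routes) == 2
        used_branches = {r.children["m0"][0] for r in routes}
        assert used_branches == {"rA", "rB"}


class TestFindRouteSet:
    def test_two_disjoint_routes_found_exactly(self):
        routes = find_route_set(
            make_two_route(),
            PenaltyConfig(p_reac=5, max_solutions=5),
            SearchBudget(10_000),
        )
        assert len(routes) == 2

    def test_counterexample_single_route(self):
        routes = find_route_set(
            counterexample_graph(), PenaltyConfig(max_solutions=5), SearchBudget(10_000)
        )
        assert len(routes) == 1
        assert "v6" in routes[0].molecules()

    def test_unsolvable_graph_empty(self, dead_chain):
        assert find_route_set(
            dead_chain, PenaltyConfig(), SearchBudget(1_000)
        ) == []

    def test_soundness_distinctness_and_floor(self):
        for seed in range(20):
            g, _ = generate_network(
                NetworkSpec(seed=seed, planted_routes=2, cycle_fraction=0.15)
            )
            k = len(enumerate_routes(g, max_routes=10))
            routes = find_route_set(
                g, PenaltyConfig(p_reac=5, max_solutions=10), SearchBudget(50_000)
            )
            assert len(routes) >= 1  # solvable by construction
            assert len(set(routes)) == len(routes)
            assert len(routes) <= max(k, 10)
            for r in routes:
                assert route_is_valid(g, r)

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        g, _ = generate_network(NetworkSpec(seed=9, planted_routes=2))
        paths = []
        for run in (0, 1):
            routes = find_route_set(
                g, PenaltyConfig(p_reac=5, max_solutions=10),
                SearchBudget(50_000, rng_seed=4),
            )
            p = tmp_path / f"run{run}.json"
            write_routes(routes, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_edge_cost_mode_still_sound(self):
        for seed in (2, 4):
            g, _ = generate_network(NetworkSpec(seed=seed, planted_routes=2))
            routes = find_route_set(
                g, PenaltyConfig(p_reac=5, max_solutions=5),
                SearchBudget(50_000), edge_costs=True,
            )
            assert len(routes) >= 1
            for r in routes:
                assert route_is_valid(g, r)
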