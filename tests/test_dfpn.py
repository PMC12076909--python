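"""PNS/DFPN: update rules, thresholds, TCA, GHI caching, solver behaviour."""

import pytest

from retrodiverse.dfpn import (
    INF,
    DfpnSearch,
    SearchBudget,
    SearchRecord,
    child_thresholds,
    dfpn,
    extract_strategy,
    ghi_lookup,
    ghi_store,
    pns,
    tca_adjust,
    update_numbers,
)
from retrodiverse.graph import (
    BUILDING_BLOCK,
    DISPROVED,
    MOLECULE,
    PROVED,
    REACTION,
    UNPROVED,
    AndOrGraph,
    GraphError,
    PathContext,
    route_is_valid,
)
from retrodiverse.oracle import evaluate_dag, solve_brute_force
from retrodiverse.synthetic import counterexample_graph

from conftest import random_game_graph


class TestUpdateNumbers:
    @pytest.mark.parametrize(
        "role, pns_, dns_, expected",
        [
            (MOLECULE, [2, 3], [1, 4], (2, 5)),
            (REACTION, [2, 3], [1, 4], (5, 1)),
            (MOLECULE, [0, 7], [INF, 2], (0, INF)),
            (REACTION, [1, INF], [3, 0], (INF, 0)),
        ],
    )
    def test_aggregation(self, role, pns_, dns_, expected):
        assert update_numbers(role, pns_, dns_) == expected

    def test_empty_children_rejected(self):
        with pytest.raises(ValueError):
            update_numbers(MOLECULE, [], [])

    def test_edge_costs_shift_molecule_pn(self):
        pn, dn = update_numbers(MOLECULE, [2, 3], [1, 1], child_costs=[5, 0])
        assert (pn, dn) == (3, 2)


class TestChildThresholds:
    def test_molecule_capped_by_second_best(self):
        th = child_thresholds(
            MOLECULE, INF, INF, 1, 2, chosen=(1, 1), second_best=(4, INF),
            single_child=False,
        )
        assert th[0] == 5

    def test_single_child_passes_thresholds_on(self):
        assert child_thresholds(
            MOLECULE, 7, 9, 1, 1, (1, 1), (INF, INF), single_child=True
        ) == (7, 9)

    def test_reaction_surplus(self):
        th = child_thresholds(
            REACTION, 10, INF, 6, 1, chosen=(2, 1), second_best=(INF, 3),
            single_child=False,
        )
        assert th[0] == 6
        assert th[1] == 4  # min(INF, 3 + 1)


class TestGhiStore:
    def test_store_then_lookup_identity(self):
        records = {}
        ctx = PathContext(frozenset({"a", "b"}))
        ghi_store("v", ctx, PROVED, records)
        assert ghi_lookup("v", ctx, records) == PROVED

    def test_repetition_disproof_not_reused_on_other_path(self):
        # disproof hinged on molecule "b" being on the path
        records = {}
        ctx = PathContext(frozenset({"a", "b"}))
        ghi_store("v", ctx, DISPROVED, records, dependencies=frozenset({"b"}))
        assert ghi_lookup("v", PathContext(frozenset({"a"})), records) == "unknown"
        assert ghi_lookup("v", PathContext(frozenset({"a", "b", "c"})), records) == DISPROVED

    def test_proof_invalid_when_strategy_molecule_on_path(self):
        records = {}
        ghi_store(
            "v", PathContext(frozenset()), PROVED, records,
            dependencies=frozenset({"v", "x"}),
        )
        assert ghi_lookup("v", PathContext(frozenset({"x"})), records) == "unknown"
        assert ghi_lookup("v", PathContext(frozenset({"y"})), records) == PROVED

    def test_lookup_on_unknown_node(self):
        assert ghi_lookup("never", PathContext(frozenset()), {}) == "unknown"


class TestTcaAdjust:
    def _records(self):
        g = counterexample_graph()
        records = {
            "v3": SearchRecord(pn=1, dn=1, md=2, expanded=True),
            "v2": SearchRecord(pn=1, dn=1, md=1, expanded=True),
        }
        return g, records

    def test_old_unproved_child_raises_thresholds(self):
        g, records = self._records()
        # minimal raise: strictly above the current pn/dn, never lowered
        th_pn, th_dn, raised = tca_adjust(g, "v3", records, 1, 1)
        assert raised and (th_pn, th_dn) == (2, 2)
        th_pn, th_dn, raised = tca_adjust(g, "v3", records, 5, 5)
        assert raised and (th_pn, th_dn) == (5, 5)

    def test_strictly_deeper_children_leave_thresholds(self):
        g, records = self._records()
        records["v2"].md = 5
        assert tca_adjust(g, "v3", records, 3, 3) == (3, 3, False)

    def test_proved_old_child_does_not_raise(self):
        g, records = self._records()
        records["v2"].pn, records["v2"].dn = 0.0, INF
        assert tca_adjust(g, "v3", records, 3, 3) == (3, 3, False)


class TestSolvers:
    def test_buyable_root_proved_without_expansion(self):
        g = AndOrGraph(root="m0")
        g.add_node("m0", MOLECULE, BUILDING_BLOCK)
        out = dfpn(g, SearchBudget(5))
        assert out.status == PROVED and out.expansions_used == 0

    def test_unsolvable_chain_disproved(self, dead_chain):
        assert dfpn(dead_chain, SearchBudget(100)).status == DISPROVED
        assert pns(dead_chain, SearchBudget(100)).status == DISPROVED

    def test_budget_exhaustion_reports_unproved(self):
        g = random_game_graph(3, n_molecules=14)
        out = dfpn(g, SearchBudget(1))
        assert out.status in (UNPROVED, PROVED, DISPROVED)
        assert out.expansions_used <= 1

    @pytest.mark.parametrize("use_tca, ghi_safe", [(False, False), (True, True)])
    def test_dag_equivalence_with_oracle(self, use_tca, ghi_safe):
        for seed in range(60):
            g = random_game_graph(seed)
            expected = solve_brute_force(g).status
            out = dfpn(g, SearchBudget(5000), use_tca=use_tca, ghi_safe=ghi_safe)
            assert out.status == expected, seed
            if out.status == PROVED:
                assert route_is_valid(g, out.strategy)

    def test_pns_dag_equivalence_with_oracle(self):
        for seed in range(60):
            g = random_game_graph(seed)
            assert pns(g, SearchBudget(5000)).status == solve_brute_force(g).status

    def test_cyclic_equivalence_with_tca(self):
        for seed in range(60):
            g = random_game_graph(seed, cyclic=True)
            out = dfpn(g, SearchBudget(50 * len(g)), use_tca=True, ghi_safe=True)
            assert out.status == solve_brute_force(g).status, seed

    def test_resolved_records_sound_on_dags(self):
        # pn/dn duality: resolved record values agree with full evaluation
        for seed in range(20):
            g = random_game_graph(seed)
            search = DfpnSearch(g, use_tca=True, ghi_safe=True)
            search.run(SearchBudget(5000))
            for node, rec in search.records.items():
                if rec.pn == 0.0:
                    assert evaluate_dag(g, node) == PROVED, (seed, node)
                if rec.dn == 0.0:
                    assert evaluate_dag(g, node) == DISPROVED, (seed, node)

    def test_budget_accounting_matches_expand_events(self):
        for seed in (0, 7, 21):
            g = random_game_graph(seed)
            trace = []
            out = dfpn(g, SearchBudget(5000), trace=trace)
            expand_events = [e for e in trace if e[0] == "expand"]
            assert out.expansions_used == len(expand_events)
            assert len({e[1] for e in expand_events}) == len(expand_events)

    def test_md_never_increases(self):
        for seed in (1, 5, 9):
            g = random_game_graph(seed, cyclic=True)
            trace = []
            dfpn(g, SearchBudget(5000), trace=trace)
            last_md = {}
            for event in trace:
                node, md = event[1], event[6]
                if node in last_md:
                    assert md <= last_md[node]
                last_md[node] = md

    def test_deterministic_trace(self):
        g = random_game_graph(13, cyclic=True)
        t1, t2 = [], []
        dfpn(g, SearchBudget(5000), trace=t1)
        dfpn(g, SearchBudget(5000), trace=t2)
        assert t1 == t2


class TestExtractStrategy:
    def test_three_node_chain(self, chain):
        search = DfpnSearch(chain)
        out = search.run(SearchBudget(100))
        assert out.status == PROVED
        assert out.strategy.children == {"m0": ["r0"], "r0": ["m1"]}

    def test_tie_breaks_to_first_child_in_order(self, two_route):
        search = DfpnSearch(two_route)
        search.run(SearchBudget(100))
        # force both children proved, then re-extract
        search.run(SearchBudget(100))
        route = extract_strategy(two_route, search, "m0")
        assert route.children["m0"] == ["r0"]

    def test_unproved_root_raises(self, dead_chain):
        search = DfpnSearch(dead_chain)
        search.run(SearchBudget(100))
        with pytest.raises(GraphError):
            extract_strategy(dead_chain, search, "m0")
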