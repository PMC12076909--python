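"""Multi-solution DFPN (DFPN*): iterated search with diversity control.

A deterministic solver rerun on the same graph returns the same route.  To
produce a *set* of routes the driver, after each proof: (1) picks a deepest
reaction of the found route, (2) force-disproves it under the path that
reached it — keyed by path so the same reaction stays available along other
lines — and (3) adds a penalty ``p_reac`` to the proof number of every
reaction on that path (``p_mol`` for molecules, 0 by default), steering the
next iteration towards unexplored chemistry.  Penalties accumulate across
iterations; the expansion budget is global across the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dfpn import (
    INF,
    DfpnSearch,
    DisproofRegistry,
    SearchBudget,
    SearchRecord,
    sat_add,
)
from .graph import (
    DISPROVED,
    MOLECULE,
    PROVED,
    REACTION,
    AndOrGraph,
    GraphError,
    PathContext,
    SynthesisRoute,
)


@dataclass
class PenaltyConfig:
    """Diversity-control knobs of the multi-solution loop.

    ``p_reac`` is added to the proof number of every reaction on the path
    to the disproved node after each found route; larger values push the
    search away from already-used reactions at the cost of more work.
    ``p_mol`` is the analogous molecule penalty and defaults to 0 because
    disproving a molecule disproves a reaction anyway.
    """

    p_reac: int = 5
    p_mol: int = 0
    max_solutions: int = 10

    def __post_init__(self) -> None:
        if self.p_reac < 0 or self.p_mol < 0:
            raise ValueError("penalties must be non-negative")
        if self.max_solutions < 1:
            raise ValueError("max_solutions must be >= 1")


def deepest_reaction(route: SynthesisRoute) -> str:
    """A reaction at maximal depth; ties go to pre-order traversal order."""
    rxn, _path = deepest_reaction_with_path(route)
    return rxn


def deepest_reaction_with_path(route: SynthesisRoute) -> tuple[str, tuple[str, ...]]:
    """Deepest reaction plus the route branch from the target down to it."""
    if route.is_empty():
        raise GraphError("route has no reactions to disprove")
    best: tuple[str, tuple[str, ...]] | None = None
    best_depth = -1

    def walk(node: str, depth: int, path: tuple[str, ...]) -> None:
        nonlocal best, best_depth
        here = path + (node,)
        if depth % 2 == 1 and depth > best_depth:
            best, best_depth = (node, here), depth
        for child in route.children.get(node, []):
            walk(child, depth + 1, here)

    walk(route.root, 0, ())
    assert best is not None
    return best


def force_disprove(
    v: str,
    ctx: PathContext,
    registry: DisproofRegistry,
    records: dict[str, SearchRecord],
) -> dict[str, SearchRecord]:
    """Mark ``v`` disproved under the given path and stale the proof cache.

    The registry entry makes ``v`` behave as disproved whenever every
    molecule of ``ctx`` is on the current search path; other paths keep
    using ``v``.  Cached proofs that might rest on ``v`` are dropped so the
    next run re-derives them (idempotent: re-inserting changes nothing).
    """
    registry.add(v, frozenset(ctx.molecules_on_path))
    invalidate_proofs(records)
    return records


def invalidate_proofs(records: dict[str, SearchRecord]) -> None:
    """Drop cached proved entries; disproofs stay (removing options can
    never un-disprove a node, and penalties do not touch disproofs)."""
    for rec in records.values():
        if rec.terminal:
            continue
        if rec.proofs:
            rec.proofs = [e for e in rec.proofs if e[0] == DISPROVED]
        if rec.pn == 0.0:
            rec.pn, rec.dn = 1.0, 1.0


def apply_penalties(
    route_path_nodes,
    penalties: PenaltyConfig,
    records: dict[str, SearchRecord],
    g: AndOrGraph | None = None,
) -> dict[str, SearchRecord]:
    """Add ``p_reac``/``p_mol`` to the proof numbers along a route path.

    The increment is stored both in the live estimate and as a persistent
    per-node bonus so later re-aggregations keep the bias; infinity stays
    infinity and exact resolutions (pn of 0) are not destroyed.
    """
    for node in route_path_nodes:
        rec = records.get(node)
        if rec is None:
            continue
        if g is not None:
            amount = penalties.p_reac if g.role(node) == REACTION else penalties.p_mol
        else:
            amount = penalties.p_reac  # caller passed reaction nodes only
        if amount == 0:
            continue
        rec.pn_bonus += amount
        if rec.pn not in (0.0, INF):
            rec.pn = sat_add(rec.pn, amount)
    return records


def edge_cost(g: AndOrGraph, parent: str, child: str, max_cost: int = 10) -> int:
    """DFPN-E heuristic cost of a molecule->reaction edge.

    Explicit costs pass through; otherwise a reaction score ``s`` maps to
    ``round(-ln s)`` (confident one-step predictions are cheap), capped;
    with neither attribute the cost is 0 and the search is plain DFPN.
    """
    if child not in g.successors(parent):
        raise GraphError(f"no edge {parent!r} -> {child!r}")
    if (parent, child) in g.edge_costs:
        return g.edge_costs[(parent, child)]
    score = g.edge_scores.get((parent, child))
    if score is not None and score > 0.0:
        return min(max_cost, int(round(-math.log(score))))
    return 0


def route_viability(route: SynthesisRoute) -> float:
    """Product of per-reaction viability scores; the empty route scores 1.

    Interpretable as the probability that every step works in the lab,
    assuming independent steps.  Raises if any reaction lacks a score.
    """
    value = 1.0
    for rxn in route.reactions():
        if rxn not in route.reaction_scores:
            raise GraphError(f"reaction {rxn!r} carries no viability score")
        value *= route.reaction_scores[rxn]
    return value


def find_route_set(
    g: AndOrGraph,
    penalties: PenaltyConfig,
    budget: SearchBudget,
    use_tca: bool = True,
    edge_costs: bool = False,
) -> list[SynthesisRoute]:
    """Run the multi-solution loop and return the distinct routes found.

    Stops at ``max_solutions``, on budget exhaustion, or when the root is
    disproved (no further routes exist under the accumulated forced
    disproofs).  Deterministic: same graph, config and budget give the
    identical route sequence.
    """
    registry = DisproofRegistry()
    search = DfpnSearch(
        g,
        use_tca=use_tca,
        ghi_safe=True,
        use_edge_costs=edge_costs,
        registry=registry,
    )
    routes: list[SynthesisRoute] = []
    while len(routes) < penalties.max_solutions:
        outcome = search.run(budget)
        if outcome.status != PROVED:
            break
        route = outcome.strategy
        assert route is not None
        if route in routes:  # safety net; the registry should prevent this
            break
        routes.append(route)
        if route.is_empty():
            break  # target is itself a building block: single empty route
        rxn, path_nodes = deepest_reaction_with_path(route)
        key = frozenset(n for n in path_nodes if g.role(n) == MOLECULE)
        force_disprove(rxn, PathContext(key), registry, search.records)
        apply_penalties(path_nodes, penalties, search.records, g=g)
    return routes
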