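"""Exhaustive game solvers used as ground truth for the search algorithms.

These are deliberately simple exponential-time solvers, intended for test
graphs of a few dozen nodes.  ``solve_brute_force`` evaluates the exact
minimax value of the two-player retrosynthesis game (repetition of a
molecule on the current path loses for the molecule player), and
``enumerate_routes`` lists all winning strategies as synthesis routes.
"""

from __future__ import annotations

from typing import Optional

from .graph import (
    DISPROVED,
    MOLECULE,
    OPEN,
    PROVED,
    REACTION,
    UNPROVED,
    AndOrGraph,
    GameOutcome,
    GraphError,
    PathContext,
    SynthesisRoute,
    terminal_status,
)

#: soft guard: exhaustive search is only meant for small test graphs
BRUTE_FORCE_NODE_GUARD = 200


def solve_brute_force(
    g: AndOrGraph,
    v: Optional[str] = None,
    ctx: Optional[PathContext] = None,
    depth_cap: Optional[int] = None,
) -> GameOutcome:
    """Exact minimax value of the game rooted at ``v`` (default: graph root).

    The repetition rule bounds every play by the number of molecule nodes,
    so with the default ``depth_cap`` (the node count) the result is always
    ``proved`` or ``disproved``.  When proved, one valid strategy is
    attached, built with first-in-child-order tie-breaking.
    """
    if len(g) > BRUTE_FORCE_NODE_GUARD:
        raise GraphError(
            f"brute-force solver is limited to {BRUTE_FORCE_NODE_GUARD} nodes, "
            f"got {len(g)}"
        )
    if v is None:
        v = g.root
    if v not in g:
        raise GraphError(f"unknown node {v!r}")
    if ctx is None:
        ctx = PathContext(frozenset())
    if depth_cap is None:
        depth_cap = 2 * len(g) + 2

    capped = False

    def solve(node: str, path: frozenset[str], depth: int) -> Optional[bool]:
        nonlocal capped
        status = terminal_status(g, node, PathContext(path))
        if status == PROVED:
            return True
        if status == DISPROVED:
            return False
        if depth > depth_cap:
            capped = True
            return None
        role = g.role(node)
        kids = g.successors(node)
        if role == MOLECULE:
            new_path = path | {node}
            any_open = False
            for child in kids:
                res = solve(child, new_path, depth + 1)
                if res is True:
                    return True
                if res is None:
                    any_open = True
            return None if any_open else False
        # reaction node: all reactants must be provable
        all_true = True
        for child in kids:
            res = solve(child, path, depth + 1)
            if res is False:
                return False
            if res is None:
                all_true = False
        return True if all_true else None

    value = solve(v, ctx.molecules_on_path, 0)
    if value is True:
        strategy = _extract_route(g, v, ctx.molecules_on_path, depth_cap)
        assert strategy is not None
        return GameOutcome(status=PROVED, strategy=strategy)
    if value is False:
        return GameOutcome(status=DISPROVED)
    return GameOutcome(status=UNPROVED)  # depth cap hit (cannot happen at default cap)


def _winning_ranks(
    g: AndOrGraph, blocked: frozenset[str]
) -> dict[str, int]:
    """Attractor ranks of the molecule player's winning region.

    Building blocks have rank 0; a molecule joins one past the cheapest
    winning reaction, a reaction one past its slowest reactant.  Molecules
    in ``blocked`` (already on the path above the subgame) can never be
    used.  Following minimal-rank children gives a positional winning
    strategy with strictly decreasing ranks, hence an acyclic route even
    on cyclic graphs.
    """
    ranks: dict[str, int] = {}
    for n in g.nodes():
        if g.is_building_block(n) and n not in blocked:
            ranks[n] = 0
    changed = True
    while changed:
        changed = False
        for n in g.nodes():
            if n in ranks or (g.role(n) == MOLECULE and n in blocked):
                continue
            kids = g.successors(n)
            if not kids:
                continue
            if g.role(n) == MOLECULE:
                won = [ranks[c] for c in kids if c in ranks]
                if won:
                    ranks[n] = 1 + min(won)
                    changed = True
            else:
                if all(c in ranks for c in kids):
                    ranks[n] = 1 + max(ranks[c] for c in kids)
                    changed = True
    return ranks


def _extract_route(
    g: AndOrGraph, v: str, path: frozenset[str], depth_cap: int
) -> Optional[SynthesisRoute]:
    """Build one winning strategy from ``v`` via attractor ranks."""
    ranks = _winning_ranks(g, frozenset(path))
    if v not in ranks:
        return None
    route = SynthesisRoute(root=v)

    def build(node: str) -> None:
        if g.role(node) == MOLECULE:
            if g.is_building_block(node):
                return
            kids = [c for c in g.successors(node) if c in ranks]
            best = min(kids, key=lambda c: (ranks[c], g.successors(node).index(c)))
            route.children[node] = [best]
            build(best)
        else:
            kids = g.successors(node)
            route.children[node] = list(kids)
            for c in kids:
                build(c)

    build(v)
    return route


def evaluate_dag(g: AndOrGraph, v: Optional[str] = None) -> str:
    """Independent AND/OR evaluation for acyclic graphs (no path state).

    On a DAG the repetition rule never fires, so the game value is a plain
    recursive AND/OR evaluation.  Kept textually independent of
    :func:`solve_brute_force` as a cross-check oracle.
    """
    if v is None:
        v = g.root

    memo: dict[str, bool] = {}

    def ev(node: str) -> bool:
        if node in memo:
            return memo[node]
        term = g.terminal(node)
        if term == "building_block":
            memo[node] = True
            return True
        if term == "dead_end":
            memo[node] = False
            return False
        kids = g.successors(node)
        if not kids:
            memo[node] = g.role(node) == REACTION  # empty AND is true, empty OR false
            return memo[node]
        if g.role(node) == MOLECULE:
            memo[node] = any(ev(c) for c in kids)
        else:
            memo[node] = all(ev(c) for c in kids)
        return memo[node]

    return PROVED if ev(v) else DISPROVED


def enumerate_routes(
    g: AndOrGraph,
    max_routes: int = 100,
    max_depth: Optional[int] = None,
    root: Optional[str] = None,
) -> list[SynthesisRoute]:
    """All distinct winning strategies from the root, deterministic order.

    Routes are produced depth-first following child order, truncated at
    ``max_routes``.  Within one route a molecule that occurs on several
    branches is synthesised the same way on each (consistent strategies),
    matching the game notion of a positional strategy.
    """
    if root is None:
        root = g.root
    if max_depth is None:
        max_depth = 2 * len(g) + 2

    results: list[SynthesisRoute] = []
    seen: set = set()

    def mol_options(
        node: str, path: frozenset[str], depth: int
    ) -> list[dict[str, list[str]]]:
        """All ways to prove molecule ``node``: list of child-maps."""
        status = terminal_status(g, node, PathContext(path))
        if status == PROVED:
            return [{}]
        if status == DISPROVED or depth > max_depth:
            return []
        out: list[dict[str, list[str]]] = []
        new_path = path | {node}
        for rxn in g.successors(node):
            reactants = g.successors(rxn)
            # cartesian product of reactant solutions, consistent per molecule
            partial: list[dict[str, list[str]]] = [{node: [rxn], rxn: list(reactants)}]
            ok = True
            if any(reactant in new_path for reactant in reactants):
                continue  # repetition on this line of play: reaction unusable
            for reactant in reactants:
                next_partial: list[dict[str, list[str]]] = []
                for pmap in partial:
                    if reactant in pmap:  # already solved on this branch-set
                        next_partial.append(pmap)
                        continue
                    for sub in mol_options(reactant, new_path, depth + 2):
                        merged = dict(pmap)
                        conflict = False
                        for k, vv in sub.items():
                            if k in merged and merged[k] != vv:
                                conflict = True
                                break
                            merged[k] = vv
                        if not conflict:
                            next_partial.append(merged)
                partial = next_partial
                if not partial:
                    ok = False
                    break
            if ok:
                out.extend(partial)
        return out

    for cmap in mol_options(root, frozenset(), 0):
        route = SynthesisRoute(root=root, children={k: list(v) for k, v in cmap.items()})
        if not route.is_acyclic():
            # a shared sub-solution re-used beneath its own ancestor would
            # repeat a molecule on a line of play: not a winning strategy
            continue
        key = route.canonical()
        if key not in seen:
            seen.add(key)
            results.append(route)
        if len(results) >= max_routes:
            break
    return results
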