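"""Seeded generators for synthetic AND/OR reaction networks and route sets.

Real retrosynthesis stacks expand molecules with a learned one-step model
against a building-block catalog.  The generators here stand in for that
machinery: they emit branching AND/OR networks with *planted* synthesis
routes (so ground truth is known), optional directed cycles (the failure
mode DFPN variants must survive), per-reaction viability scores, and
formed-bond labels in the target's atom frame (so diversity scoring is
exercisable).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .graph import (
    BUILDING_BLOCK,
    DEAD_END,
    MOLECULE,
    NO_TERMINAL,
    REACTION,
    AndOrGraph,
    SynthesisRoute,
)


def counterexample_graph() -> AndOrGraph:
    """The 7-node cyclic counterexample on which history-free DFPN fails.

    Molecule nodes: v0 (target), v3, v4, v6 (the only building block);
    reaction nodes: v1, v2, v5.  The two reaction branches v1 and v2 lead
    into the two-node cycles v1<->v4 and v2<->v3, while v5 -> v6 is the only
    winning line.  Plain DFPN gets trapped revisiting the cyclic branches
    and never expands v5; with TCA the threshold raise at v3 (whose child
    v2 has md(v2) <= md(v3)) forces progress, v5 is expanded and the root
    is proved with the strategy through v6.  The graph is symmetric under
    swapping v1 with v2 and v3 with v4.
    """
    g = AndOrGraph(root="v0")
    g.add_node("v0", MOLECULE)
    g.add_node("v1", REACTION)
    g.add_node("v2", REACTION)
    g.add_node("v3", MOLECULE)
    g.add_node("v4", MOLECULE)
    g.add_node("v5", REACTION)
    g.add_node("v6", MOLECULE, BUILDING_BLOCK)
    g.add_edge("v0", "v1")
    g.add_edge("v0", "v2")
    g.add_edge("v0", "v5")
    g.add_edge("v1", "v4")
    g.add_edge("v2", "v3")
    g.add_edge("v3", "v2")
    g.add_edge("v4", "v1")
    g.add_edge("v5", "v6")
    return g


@dataclass
class NetworkSpec:
    """Parameters of one synthetic reaction network.

    ``n_molecules`` bounds the molecule count; ``depth`` is the number of
    retrosynthetic levels below the target; ``buyable_fraction`` the
    probability that a non-planted intermediate is purchasable;
    ``cycle_fraction`` the per-molecule probability of adding a back-edge
    that closes a directed cycle; ``planted_routes`` the number of known
    solutions wired in from the target.
    """

    n_molecules: int = 40
    max_reactions_per_molecule: int = 2
    max_reactants: int = 2
    buyable_fraction: float = 0.35
    dead_end_fraction: float = 0.0
    cycle_fraction: float = 0.0
    planted_routes: int = 1
    depth: int = 4
    seed: int = 0
    score_alpha: float = 6.0
    score_beta: float = 2.0
    n_atoms: int = 14

    def __post_init__(self) -> None:
        if not (0.0 < self.buyable_fraction <= 1.0):
            raise ValueError("buyable_fraction must be in (0, 1]")
        if not (0.0 <= self.dead_end_fraction < 1.0):
            raise ValueError("dead_end_fraction must be in [0, 1)")
        if self.buyable_fraction + self.dead_end_fraction > 1.0:
            raise ValueError("buyable_fraction + dead_end_fraction must be <= 1")
        if not (0.0 <= self.cycle_fraction < 1.0):
            raise ValueError("cycle_fraction must be in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.planted_routes < 0:
            raise ValueError("planted_routes must be >= 0")
        if self.max_reactants < 1 or self.max_reactions_per_molecule < 1:
            raise ValueError("fan-out parameters must be >= 1")
        # every planted route needs at least a root reaction and one leaf
        if self.planted_routes > 0 and self.n_molecules < 1 + 2 * self.planted_routes:
            raise ValueError(
                "n_molecules too small for the requested planted routes"
            )


def generate_network(spec: NetworkSpec) -> tuple[AndOrGraph, list[SynthesisRoute]]:
    """Build one network plus its planted routes (deterministic per seed)."""
    rng = random.Random(spec.seed)
    g = AndOrGraph(root="m0")
    g.add_node("m0", MOLECULE)
    depth_of = {"m0": 0}
    mol_counter = 1
    rxn_counter = 0

    def new_molecule(depth: int) -> str:
        nonlocal mol_counter
        if mol_counter >= spec.n_molecules:
            raise ValueError(
                f"molecule budget n_molecules={spec.n_molecules} exhausted; "
                "increase it or reduce planted_routes/depth"
            )
        m = f"m{mol_counter}"
        mol_counter += 1
        g.add_node(m, MOLECULE)
        depth_of[m] = depth
        return m

    # Each molecule owns a small pool of disconnection "ideas"; all its
    # reactions realise one of them.  This mirrors real chemistry, where
    # many named reactions form the same bond (e.g. the many variants of a
    # C-C coupling) and distinct routes often embody the same idea.
    idea_pool: dict[str, list[frozenset]] = {}

    def _ideas_for(mol: str) -> list[frozenset]:
        pool = idea_pool.get(mol)
        if pool is None:
            pool = []
            draw = rng.random()
            n_ideas = 1 if draw < 0.45 else (2 if draw < 0.8 else 3)
            for _ in range(n_ideas):
                bonds = set()
                for _ in range(rng.randint(1, 2)):
                    a, b = rng.sample(range(spec.n_atoms), 2)
                    bonds.add((f"a{min(a, b)}", f"a{max(a, b)}"))
                pool.append(frozenset(bonds))
            idea_pool[mol] = pool
        return pool

    def new_reaction(parent: str) -> str:
        nonlocal rxn_counter
        r = f"r{rxn_counter}"
        rxn_counter += 1
        g.add_node(r, REACTION)
        score = min(1.0, max(0.05, rng.betavariate(spec.score_alpha, spec.score_beta)))
        g.add_edge(parent, r, score=round(score, 3))
        pool = _ideas_for(parent)
        g.reaction_bonds[r] = pool[rng.randrange(len(pool))]
        return r

    def mark_buyable(m: str) -> None:
        g.terminals[m] = BUILDING_BLOCK
        g.children[m] = []

    # ---- plant the guaranteed routes ----------------------------------------
    planted: list[SynthesisRoute] = []

    def plant(mol: str, depth: int, route: SynthesisRoute) -> None:
        if depth >= spec.depth:
            mark_buyable(mol)
            return
        r = new_reaction(mol)
        route.children[mol] = [r]
        route.reaction_bonds[r] = g.reaction_bonds[r]
        route.reaction_scores[r] = g.edge_scores[(mol, r)]
        # planted backbones are mostly linear with occasional convergent
        # steps, like real synthesis plans; distractors use the full width
        n_react = 1 if rng.random() < 0.7 else min(2, spec.max_reactants)
        reactants = []
        for _ in range(n_react):
            child = new_molecule(depth + 1)
            reactants.append(child)
            g.add_edge(r, child)
        route.children[r] = reactants
        for child in reactants:
            # branches stop early with increasing probability
            if depth + 1 >= spec.depth or rng.random() < spec.buyable_fraction:
                mark_buyable(child)
            else:
                plant(child, depth + 1, route)

    for _ in range(spec.planted_routes):
        route = SynthesisRoute(root="m0")
        plant("m0", 0, route)
        planted.append(route)

    # ---- fill in distractor molecules and reactions -------------------------
    while mol_counter < spec.n_molecules:
        depth = rng.randint(1, spec.depth)
        m = new_molecule(depth)
        draw = rng.random()
        if depth >= spec.depth or draw < spec.buyable_fraction:
            mark_buyable(m)
        elif draw < spec.buyable_fraction + spec.dead_end_fraction:
            # unmakeable, unbuyable intermediate: a trap for naive search
            g.terminals[m] = DEAD_END
            g.children[m] = []

    by_depth: dict[int, list[str]] = {}
    for m, d in depth_of.items():
        by_depth.setdefault(d, []).append(m)

    for m in list(depth_of):
        if g.terminal(m) != NO_TERMINAL:
            continue
        d = depth_of[m]
        deeper = [
            x for x in depth_of if depth_of[x] > d and x != m and g.role(x) == MOLECULE
        ]
        if not deeper:
            continue
        n_extra = rng.randint(0, spec.max_reactions_per_molecule - 1)
        if m == "m0" and not g.successors(m):
            n_extra = max(n_extra, 1)
        for _ in range(n_extra):
            r = new_reaction(m)
            for child in rng.sample(deeper, min(len(deeper), rng.randint(1, spec.max_reactants))):
                g.add_edge(r, child)

    # ---- close directed cycles ----------------------------------------------
    if spec.cycle_fraction > 0.0:
        # an extra reaction child pointing back to an ancestor-side reaction
        # only adds an (unhelpful) option for the molecule player, so the
        # planted routes stay intact
        reactions = [n for n in g.nodes() if g.role(n) == REACTION]
        ancestors = _reaction_reach(g)
        for m in list(depth_of):
            if g.terminal(m) != NO_TERMINAL or m == "m0":
                continue
            if rng.random() >= spec.cycle_fraction:
                continue
            back = [r for r in reactions if m in ancestors.get(r, ())]
            if back:
                g.add_edge(m, rng.choice(back))

    return g, planted


def _reaction_reach(g: AndOrGraph) -> dict[str, set[str]]:
    """For each reaction, the set of molecules reachable below it."""
    reach: dict[str, set[str]] = {}

    def visit(n: str, seen: frozenset) -> set[str]:
        if n in reach:
            return reach[n]
        if n in seen:
            return set()
        out: set[str] = set()
        for c in g.successors(n):
            if g.role(c) == MOLECULE:
                out.add(c)
            out |= visit(c, seen | {n})
        reach[n] = out
        return out

    for n in list(g.nodes()):
        if g.role(n) == REACTION:
            visit(n, frozenset())
    return reach


def generate_route_set(
    n_routes: int, n_ideas: int, overlap: float = 0.0, seed: int = 0,
    bonds_per_idea: int = 3,
) -> list[SynthesisRoute]:
    """Synthetic routes whose disconnection sets form ``n_ideas`` groups.

    Each *idea* is a pool of bond labels; routes in the same group draw
    their formed bonds from the same pool, so with ``overlap=0`` the
    retained disconnection family has exactly ``n_ideas`` pairwise-disjoint
    members and the diversity score equals ``n_ideas``.  ``overlap`` is the
    fraction of labels each pool shares with a common core, pulling the
    pairwise Jaccard distances below 1.
    """
    if n_ideas > n_routes:
        raise ValueError("n_ideas must not exceed n_routes")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    rng = random.Random(seed)
    n_shared = round(overlap * bonds_per_idea)
    shared = [("s0", f"s{k + 1}") for k in range(n_shared)]
    pools: list[list[tuple[str, str]]] = []
    for i in range(n_ideas):
        own = [
            (f"i{i}a{2 * k}", f"i{i}a{2 * k + 1}")
            for k in range(bonds_per_idea - n_shared)
        ]
        pools.append(shared + own)

    routes = []
    for j in range(n_routes):
        pool = pools[j % n_ideas]
        route = SynthesisRoute(root="target")
        # linear two-step route; bond labels split over the two reactions
        r1, r2 = f"rt{j}_0", f"rt{j}_1"
        mid, leaf1, leaf2 = f"mid{j}", f"bb{j}a", f"bb{j}b"
        route.children = {
            "target": [r1],
            r1: [mid, leaf1],
            mid: [r2],
            r2: [leaf2],
        }
        cut = max(1, len(pool) // 2)
        # the union over the route must cover the full pool so grouped
        # routes share one disconnection set exactly
        route.reaction_bonds[r1] = frozenset(pool[:cut])
        route.reaction_bonds[r2] = frozenset(pool[cut:]) or frozenset(pool[:1])
        route.reaction_scores[r1] = round(rng.uniform(0.5, 1.0), 3)
        route.reaction_scores[r2] = round(rng.uniform(0.5, 1.0), 3)
        routes.append(route)
    return routes
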