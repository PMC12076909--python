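"""One-player Monte-Carlo tree search baseline for route finding.

The one-player view of retrosynthesis: a state is the set of still-open
(unsolved, non-purchasable) molecules, and a move applies one reaction to
the first open molecule, replacing it by the reaction's non-buyable
reactants.  A state with no open molecules is a win.  Each iteration runs
the four classic phases — selection by UCB1 (with a penalty on already
visited nodes, so that long runs keep producing *different* plans),
expansion of all children of the selected leaf, a uniformly random rollout,
and backpropagation of the binary reward.  Every distinct winning line of
the *tree* is recorded as a synthesis route; rollout wins only contribute
reward, as in standard practice.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .graph import (
    MOLECULE,
    AndOrGraph,
    GraphError,
    SynthesisRoute,
)


@dataclass
class MctsConfig:
    exploration_c: float = 1.4
    rollout_depth: int = 30
    visit_penalty: float = 0.02
    iterations: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.exploration_c <= 0:
            raise ValueError("exploration_c must be positive")


@dataclass
class MctsNode:
    """Search-tree node: a set of open molecules plus bandit statistics."""

    open_molecules: frozenset[str]
    applied_reaction: Optional[str] = None
    applied_to: Optional[str] = None
    visits: int = 0
    value_sum: float = 0.0
    children: list["MctsNode"] = field(default_factory=list)
    expanded: bool = False
    parent: Optional["MctsNode"] = None

    def is_win(self) -> bool:
        return not self.open_molecules


def uct_score(node: MctsNode, parent_visits: int, cfg: MctsConfig) -> float:
    """UCB1 with a visit penalty; unvisited nodes score infinity.

    mean value + c * sqrt(ln(parent_visits) / (1 + visits))
    - visit_penalty * visits.
    """
    if parent_visits < 1:
        raise ValueError("parent_visits must be >= 1")
    if node.visits == 0:
        return math.inf
    mean = node.value_sum / node.visits
    explore = cfg.exploration_c * math.sqrt(
        math.log(parent_visits) / (1 + node.visits)
    )
    return mean + explore - cfg.visit_penalty * node.visits


def _focus(state: frozenset[str]) -> str:
    """Deterministic choice of the next molecule to work on."""
    return min(state)


def _apply(
    g: AndOrGraph, state: frozenset[str], mol: str, rxn: str
) -> frozenset[str]:
    new_open = set(state)
    new_open.discard(mol)
    for reactant in g.successors(rxn):
        if not g.is_building_block(reactant):
            new_open.add(reactant)
    return frozenset(new_open)


def mcts_search(g: AndOrGraph, cfg: MctsConfig) -> list[SynthesisRoute]:
    """Run MCTS and return all distinct winning routes encountered."""
    rng = random.Random(cfg.rng_seed)
    root_mol = g.root
    if g.role(root_mol) != MOLECULE:
        raise GraphError("root must be a molecule node")
    if g.is_building_block(root_mol):
        return [SynthesisRoute(root=root_mol)]

    root = MctsNode(open_molecules=frozenset({root_mol}))
    routes: list[SynthesisRoute] = []
    seen: set = set()

    def record_win(assignment: dict[str, str]) -> None:
        route = _assignment_to_route(g, root_mol, assignment)
        if route is None:
            return
        key = route.canonical()
        if key not in seen:
            seen.add(key)
            routes.append(route)

    for _ in range(cfg.iterations):
        # -- selection ---------------------------------------------------------
        node = root
        assignment: dict[str, str] = {}
        while node.expanded and node.children:
            node = max(
                node.children,
                key=lambda c: uct_score(c, max(node.visits, 1), cfg),
            )
            assignment[node.applied_to] = node.applied_reaction  # type: ignore[index]
        reward = 0.0
        if node.is_win():
            record_win(assignment)
            reward = 1.0
        else:
            focus = _focus(node.open_molecules)
            moves = g.successors(focus)
            if not moves:
                reward = 0.0  # dead end
            elif not node.expanded:
                # -- expansion: add all children of the selected leaf at once --
                node.expanded = True
                for rxn in moves:
                    child = MctsNode(
                        open_molecules=_apply(g, node.open_molecules, focus, rxn),
                        applied_reaction=rxn,
                        applied_to=focus,
                        parent=node,
                    )
                    node.children.append(child)
                chosen = node.children[rng.randrange(len(node.children))]
                assignment[chosen.applied_to] = chosen.applied_reaction  # type: ignore[index]
                node = chosen
                if node.is_win():
                    record_win(assignment)
                    reward = 1.0
                else:
                    # rollouts only inform values; routes are read off the
                    # tree once a win line has actually been built
                    reward = _rollout(g, node.open_molecules, dict(assignment), cfg, rng)
            else:
                reward = 0.0
        # -- backpropagation ---------------------------------------------------
        while node is not None:
            node.visits += 1
            node.value_sum += reward
            node = node.parent

    return routes


def _rollout(
    g: AndOrGraph,
    state: frozenset[str],
    assignment: dict[str, str],
    cfg: MctsConfig,
    rng: random.Random,
) -> float:
    """Uniformly random playout; reward 1 iff everything becomes buyable."""
    for _ in range(cfg.rollout_depth):
        if not state:
            return 1.0
        focus = _focus(state)
        moves = g.successors(focus)
        if not moves:
            return 0.0
        rxn = moves[rng.randrange(len(moves))]
        assignment[focus] = rxn
        state = _apply(g, state, focus, rxn)
    return 1.0 if not state else 0.0


def _assignment_to_route(
    g: AndOrGraph, root_mol: str, assignment: dict[str, str]
) -> Optional[SynthesisRoute]:
    """Rebuild the route tree from the molecule->reaction choices of a win."""
    route = SynthesisRoute(root=root_mol)

    def build(mol: str, path: frozenset[str]) -> bool:
        if g.is_building_block(mol):
            return True
        if mol in path or mol not in assignment:
            return False
        rxn = assignment[mol]
        route.children[mol] = [rxn]
        if (mol, rxn) in g.edge_scores:
            route.reaction_scores[rxn] = g.edge_scores[(mol, rxn)]
        if rxn in g.reaction_bonds:
            route.reaction_bonds[rxn] = frozenset(g.reaction_bonds[rxn])
        kids = g.successors(rxn)
        route.children[rxn] = list(kids)
        return all(build(c, path | {mol}) for c in kids)

    return route if build(root_mol, frozenset()) else None
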