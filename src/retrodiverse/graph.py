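"""AND/OR game-graph data model for retrosynthetic search.

A retrosynthesis problem is modelled as a two-player game on a directed
bipartite graph.  Molecule nodes belong to the *molecule player* (OR
semantics: one provable reaction suffices), reaction nodes to the
*reaction player* (AND semantics: every reactant must be provable).  The
molecule player wins when a purchasable building block is reached; the
reaction player wins at a dead end (a molecule with no known reactions
that is not purchasable) or when a molecule repeats on the current path.
A winning strategy for the molecule player is a synthesis route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

MOLECULE = "molecule"
REACTION = "reaction"
BUILDING_BLOCK = "building_block"
DEAD_END = "dead_end"
NO_TERMINAL = "none"

PROVED = "proved"
DISPROVED = "disproved"
OPEN = "open"
UNPROVED = "unproved"


class GraphError(ValueError):
    """Raised for malformed graphs or queries against unknown nodes."""


@dataclass
class AndOrGraph:
    """Directed bipartite AND/OR game graph.

    Parameters
    ----------
    root:
        Identifier of the target molecule node.
    roles:
        Mapping node-id -> ``"molecule"`` | ``"reaction"``.
    terminals:
        Mapping node-id -> ``"building_block"`` | ``"dead_end"`` | ``"none"``.
        Nodes absent from the mapping are non-terminal.
    children:
        Mapping node-id -> ordered sequence of child ids.  Child order is
        the tie-breaking order used by every search algorithm, so it is
        part of the graph's identity.
    edge_costs / edge_scores:
        Optional per-edge attributes keyed by ``(parent, child)``.  Costs
        are non-negative integers used by the DFPN-E heuristic; scores in
        (0, 1] are one-step viability estimates.
    """

    root: str
    roles: dict[str, str] = field(default_factory=dict)
    terminals: dict[str, str] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)
    edge_costs: dict[tuple[str, str], int] = field(default_factory=dict)
    edge_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    #: optional per-reaction formed-bond labels in the target atom frame
    reaction_bonds: dict[str, frozenset] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def add_node(self, node: str, role: str, terminal: str = NO_TERMINAL) -> None:
        self.roles[node] = role
        if terminal != NO_TERMINAL:
            self.terminals[node] = terminal
        self.children.setdefault(node, [])

    def add_edge(self, parent: str, child: str,
                 cost: Optional[int] = None, score: Optional[float] = None) -> None:
        self.children.setdefault(parent, []).append(child)
        if cost is not None:
            self.edge_costs[(parent, child)] = cost
        if score is not None:
            self.edge_scores[(parent, child)] = score

    # -- queries --------------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self.roles

    def nodes(self) -> Iterator[str]:
        return iter(self.roles)

    def __len__(self) -> int:
        return len(self.roles)

    def role(self, node: str) -> str:
        try:
            return self.roles[node]
        except KeyError:
            raise GraphError(f"unknown node {node!r}") from None

    def terminal(self, node: str) -> str:
        if node not in self.roles:
            raise GraphError(f"unknown node {node!r}")
        return self.terminals.get(node, NO_TERMINAL)

    def successors(self, node: str) -> list[str]:
        if node not in self.roles:
            raise GraphError(f"unknown node {node!r}")
        return self.children.get(node, [])

    def is_building_block(self, node: str) -> bool:
        return self.terminals.get(node) == BUILDING_BLOCK

    def molecules(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == MOLECULE]

    def reactions(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == REACTION]


@dataclass(frozen=True)
class PathContext:
    """Set of molecule nodes on the root-to-current path (inclusive).

    Repetition of a molecule on the current line of play loses the game
    for the molecule player; only molecules need tracking because in a
    bipartite graph a reaction cannot repeat without a molecule repeating
    first.
    """

    molecules_on_path: frozenset[str] = frozenset()

    @staticmethod
    def root_context(root: str) -> "PathContext":
        return PathContext(frozenset({root}))

    def push(self, molecule: str) -> "PathContext":
        return PathContext(self.molecules_on_path | {molecule})

    def __contains__(self, node: str) -> bool:
        return node in self.molecules_on_path


@dataclass
class SynthesisRoute:
    """Rooted alternating molecule/reaction tree from target to building blocks.

    ``children[node]`` lists the route children of ``node``: for a molecule
    the single reaction producing it (absent for leaves), for a reaction all
    of its reactants.  ``reaction_bonds`` carries, per reaction, the set of
    bond keys formed in the forward direction, expressed in the target
    molecule's atom frame; ``reaction_scores`` optional per-reaction
    viability estimates in [0, 1].

    Node ids may repeat across disjoint branches (the same intermediate can
    be made twice); the tree is therefore stored with path-tuples as
    internal keys via :meth:`iter_edges`.
    """

    root: str
    children: dict[str, list[str]] = field(default_factory=dict)
    reaction_bonds: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    reaction_scores: dict[str, float] = field(default_factory=dict)

    def is_empty(self) -> bool:
        """True when the target itself is a building block (empty route)."""
        return not self.children.get(self.root)

    def iter_nodes(self) -> Iterator[tuple[str, int]]:
        """Yield (node, depth) pairs in deterministic pre-order."""
        stack = [(self.root, 0)]
        while stack:
            node, depth = stack.pop()
            yield node, depth
            for child in reversed(self.children.get(node, [])):
                stack.append((child, depth + 1))

    def reactions(self) -> list[str]:
        """Reaction nodes in pre-order (deduplicated, first occurrence)."""
        seen: list[str] = []
        for node, depth in self.iter_nodes():
            if depth % 2 == 1 and node not in seen:
                seen.append(node)
        return seen

    def n_reactions(self) -> int:
        return sum(1 for node, depth in self.iter_nodes() if depth % 2 == 1)

    def molecules(self) -> list[str]:
        out: list[str] = []
        for node, depth in self.iter_nodes():
            if depth % 2 == 0 and node not in out:
                out.append(node)
        return out

    def leaves(self) -> list[str]:
        return [n for n, _ in self.iter_nodes() if not self.children.get(n)]

    def canonical(self) -> tuple:
        """Order-independent canonical form used for route distinctness."""

        def canon(node: str, path: frozenset) -> tuple:
            if node in path:
                raise ValueError(f"route contains a cycle through {node!r}")
            sub = path | {node}
            kids = tuple(sorted(canon(c, sub) for c in self.children.get(node, [])))
            return (node, kids)

        return canon(self.root, frozenset())

    def is_acyclic(self) -> bool:
        try:
            self.canonical()
        except ValueError:
            return False
        return True

    def __eq__(self, other: object) -> bool:  # tree equality, not dict equality
        if not isinstance(other, SynthesisRoute):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


@dataclass
class GameOutcome:
    """Result of a solver run.

    ``status`` is ``proved`` (synthesis route exists and is attached as
    ``strategy``), ``disproved`` (no route exists under the game rules) or
    ``unproved`` (budget exhausted before a decision).
    """

    status: str
    strategy: Optional[SynthesisRoute] = None
    expansions_used: int = 0

    def __post_init__(self) -> None:
        if (self.status == PROVED) != (self.strategy is not None):
            raise ValueError("strategy must be present iff status is proved")


# -- validity ------------------------------------------------------------------


def validate_graph(g: AndOrGraph) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Never raises: diagnostics are collected so a caller can report all
    problems of an input file at once.
    """
    diags: list[str] = []
    if g.root not in g.roles:
        diags.append(f"root {g.root!r} is not a node")
    elif g.roles[g.root] != MOLECULE:
        diags.append(f"root {g.root!r} must be a molecule node, got {g.roles[g.root]!r}")

    for node, role in g.roles.items():
        if role not in (MOLECULE, REACTION):
            diags.append(f"node {node!r} has unknown role {role!r}")
    for node, term in g.terminals.items():
        if node not in g.roles:
            diags.append(f"terminal label on unknown node {node!r}")
            continue
        if term not in (BUILDING_BLOCK, DEAD_END):
            diags.append(f"node {node!r} has unknown terminal label {term!r}")
        elif g.roles[node] != MOLECULE:
            diags.append(f"terminal label {term!r} on non-molecule node {node!r}")
        elif g.children.get(node):
            diags.append(f"terminal node {node!r} must not have outgoing edges")

    for parent, kids in g.children.items():
        if parent not in g.roles:
            diags.append(f"edges from unknown node {parent!r}")
            continue
        for child in kids:
            if child not in g.roles:
                diags.append(f"edge {parent!r}->{child!r} targets unknown node")
            elif g.roles[parent] == g.roles[child]:
                diags.append(
                    f"edge {parent!r}->{child!r} violates bipartiteness "
                    f"(both {g.roles[parent]})"
                )
        if len(set(kids)) != len(kids):
            diags.append(f"node {parent!r} has duplicate child entries")

    for (parent, child), cost in g.edge_costs.items():
        if cost < 0:
            diags.append(f"edge {parent!r}->{child!r} has negative cost {cost}")
    for (parent, child), score in g.edge_scores.items():
        if not (0.0 <= score <= 1.0):
            diags.append(f"edge {parent!r}->{child!r} has score {score} outside [0,1]")
    return diags


def terminal_status(g: AndOrGraph, v: str, ctx: PathContext) -> str:
    """Game-terminal classification of ``v`` under the path context.

    Building block -> win for the molecule player (``proved``); dead end or
    a repeated molecule on the current path -> win for the reaction player
    (``disproved``); anything else is ``open``.  ``ctx`` holds the molecules
    strictly *above* ``v``, so membership of ``v`` itself means repetition.
    """
    term = g.terminal(v)  # raises GraphError on unknown node
    if term == BUILDING_BLOCK:
        return PROVED
    if term == DEAD_END:
        return DISPROVED
    if v in ctx and g.role(v) == MOLECULE:
        return DISPROVED
    if g.role(v) == MOLECULE and not g.successors(v):
        # childless, non-buyable molecule: implicit dead end
        return DISPROVED
    return OPEN


def route_is_valid(g: AndOrGraph, r: SynthesisRoute) -> bool:
    """True iff ``r`` is a synthesis route realisable in ``g``.

    Checks: the root matches a molecule node; every route edge exists in
    ``g``; every molecule has at most one reaction child; every non-leaf
    reaction includes *all* of its reactant children from the graph; every
    leaf is a building block.
    """
    if r.root not in g:
        return False
    if g.role(r.root) != MOLECULE:
        return False

    def check(node: str, depth: int) -> bool:
        kids = r.children.get(node, [])
        role = g.role(node) if node in g else None
        if role is None:
            return False
        expected_role = MOLECULE if depth % 2 == 0 else REACTION
        if role != expected_role:
            return False
        if not kids:
            # leaf: must be a buyable molecule
            return role == MOLECULE and g.is_building_block(node)
        graph_kids = g.successors(node)
        if role == MOLECULE:
            if len(kids) != 1 or kids[0] not in graph_kids:
                return False
        else:
            # reaction: all reactants, exactly, preserving multiset
            if sorted(kids) != sorted(graph_kids):
                return False
        return all(check(c, depth + 1) for c in kids)

    return check(r.root, 0)


def subroute(r: SynthesisRoute, node: str) -> SynthesisRoute:
    """Route subtree rooted at the first pre-order occurrence of ``node``."""
    sub = SynthesisRoute(root=node)

    def copy(n: str) -> None:
        kids = r.children.get(n, [])
        if kids:
            sub.children[n] = list(kids)
        if n in r.reaction_bonds:
            sub.reaction_bonds[n] = r.reaction_bonds[n]
        if n in r.reaction_scores:
            sub.reaction_scores[n] = r.reaction_scores[n]
        for c in kids:
            copy(c)

    copy(node)
    return sub
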