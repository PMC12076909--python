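"""Pluggable one-step expansion policies.

The search algorithms operate on an explicit :class:`~retrodiverse.graph.
AndOrGraph`.  In a production deployment the reaction options for a
molecule come from a learned one-step retrosynthesis model instead.  The
:class:`ExpansionPolicy` protocol is that seam: a provider maps a molecule
to scored candidate reactions, and :func:`materialize_graph` unrolls any
provider into the explicit game graph the solvers consume — so a model can
be plugged in later without touching search code.  The default provider
simply reads an existing graph back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from .graph import (
    BUILDING_BLOCK,
    MOLECULE,
    NO_TERMINAL,
    REACTION,
    AndOrGraph,
)


@dataclass(frozen=True)
class CandidateReaction:
    """One proposed retrosynthetic step for a molecule."""

    reaction_id: str
    reactants: tuple[str, ...]
    score: float = 1.0
    formed_bonds: frozenset = frozenset()


class ExpansionPolicy(Protocol):
    """Provider contract: molecule id -> candidate reactions."""

    def expand(self, molecule: str) -> Sequence[CandidateReaction]:
        ...

    def is_building_block(self, molecule: str) -> bool:
        ...


class GraphExpansionPolicy:
    """Default provider: read candidate reactions off an explicit graph."""

    def __init__(self, g: AndOrGraph) -> None:
        self._g = g

    def expand(self, molecule: str) -> list[CandidateReaction]:
        out = []
        for rxn in self._g.successors(molecule):
            out.append(
                CandidateReaction(
                    reaction_id=rxn,
                    reactants=tuple(self._g.successors(rxn)),
                    score=self._g.edge_scores.get((molecule, rxn), 1.0),
                    formed_bonds=self._g.reaction_bonds.get(rxn, frozenset()),
                )
            )
        return out

    def is_building_block(self, molecule: str) -> bool:
        return self._g.is_building_block(molecule)


def materialize_graph(
    policy: ExpansionPolicy, root: str, max_molecules: int = 10_000
) -> AndOrGraph:
    """Unroll a policy into the explicit AND/OR game graph from ``root``.

    Molecules the policy marks as building blocks become terminals; a
    molecule with no candidates becomes an implicit dead end.  Expansion is
    breadth-first and capped at ``max_molecules`` distinct molecules.
    """
    g = AndOrGraph(root=root)
    queue = [root]
    seen = {root}
    while queue:
        mol = queue.pop(0)
        buyable = policy.is_building_block(mol)
        g.add_node(mol, MOLECULE, BUILDING_BLOCK if buyable else NO_TERMINAL)
        if buyable:
            continue
        for cand in policy.expand(mol):
            known = cand.reaction_id in g.roles
            g.add_node(cand.reaction_id, REACTION)
            g.add_edge(mol, cand.reaction_id, score=cand.score)
            if cand.formed_bonds:
                g.reaction_bonds[cand.reaction_id] = frozenset(cand.formed_bonds)
            for reactant in cand.reactants:
                if not known:
                    g.add_edge(cand.reaction_id, reactant)
                if reactant not in seen and len(seen) < max_molecules:
                    seen.add(reactant)
                    queue.append(reactant)
    # reactants never expanded (cap) default to unexpandable molecules
    for node in list(g.children):
        for child in g.children[node]:
            if child not in g.roles:
                g.add_node(child, MOLECULE)
    return g
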