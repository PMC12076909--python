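"""Shared fixtures: hand-built game graphs and a seeded random-graph factory."""

from __future__ import annotations

import random

import pytest

from retrodiverse.graph import (
    BUILDING_BLOCK,
    MOLECULE,
    NO_TERMINAL,
    REACTION,
    AndOrGraph,
)


def make_chain(solvable: bool = True) -> AndOrGraph:
    """m0 -> r0 -> m1, with m1 buyable iff solvable."""
    g = AndOrGraph(root="m0")
    g.add_node("m0", MOLECULE)
    g.add_node("r0", REACTION)
    g.add_node("m1", MOLECULE, BUILDING_BLOCK if solvable else NO_TERMINAL)
    g.add_edge("m0", "r0")
    g.add_edge("r0", "m1")
    return g


def make_two_route() -> AndOrGraph:
    """Root with two independent one-step reactions (two routes)."""
    g = AndOrGraph(root="m0")
    g.add_node("m0", MOLECULE)
    for i in (0, 1):
        g.add_node(f"r{i}", REACTION)
        g.add_node(f"b{i}", MOLECULE, BUILDING_BLOCK)
        g.add_edge("m0", f"r{i}")
        g.add_edge(f"r{i}", f"b{i}")
    return g


def make_diamond() -> AndOrGraph:
    """Two routes sharing one deep reaction, reachable via two paths.

    m0 -> rA -> mA -> r1 -> mX -> rX -> bb
    m0 -> rB -> mB -> r2 -> mX -> rX -> bb
    """
    g = AndOrGraph(root="m0")
    g.add_node("m0", MOLECULE)
    for name in ("mA", "mB", "mX"):
        g.add_node(name, MOLECULE)
    g.add_node("bb", MOLECULE, BUILDING_BLOCK)
    for name in ("rA", "rB", "r1", "r2", "rX"):
        g.add_node(name, REACTION)
    g.add_edge("m0", "rA")
    g.add_edge("m0", "rB")
    g.add_edge("rA", "mA")
    g.add_edge("rB", "mB")
    g.add_edge("mA", "r1")
    g.add_edge("mB", "r2")
    g.add_edge("r1", "mX")
    g.add_edge("r2", "mX")
    g.add_edge("mX", "rX")
    g.add_edge("rX", "bb")
    return g


def random_game_graph(
    seed: int, n_molecules: int = 12, cyclic: bool = False
) -> AndOrGraph:
    """Small seeded game graph for oracle-equivalence fuzzing.

    Molecules are ordered; reactions point at strictly later molecules so
    the base graph is acyclic, and ``cyclic=True`` adds back-edges to
    earlier molecules, creating directed cycles.
    """
    rng = random.Random(seed)
    g = AndOrGraph(root="m0")
    mols = [f"m{i}" for i in range(n_molecules)]
    for i, m in enumerate(mols):
        buyable = i > 0 and rng.random() < 0.3
        g.add_node(m, MOLECULE, BUILDING_BLOCK if buyable else NO_TERMINAL)
    rid = 0
    for i, m in enumerate(mols):
        if g.is_building_block(m):
            continue
        for _ in range(rng.randint(0, 2)):
            later = mols[i + 1:]
            if not later:
                continue
            r = f"r{rid}"
            rid += 1
            g.add_node(r, REACTION)
            g.add_edge(m, r)
            for tgt in rng.sample(later, min(len(later), rng.randint(1, 2))):
                g.add_edge(r, tgt)
            if cyclic and rng.random() < 0.4 and i > 0:
                g.add_edge(r, mols[rng.randint(0, i)])
    return g


@pytest.fixture
def chain():
    return make_chain()


@pytest.fixture
def dead_chain():
    return make_chain(solvable=False)


@pytest.fixture
def two_route():
    return make_two_route()


@pytest.fixture
def diamond():
    return make_diamond()
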