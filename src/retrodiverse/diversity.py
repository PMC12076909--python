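"""Chemical Diversity Score (CDS) and baseline route-set metrics.

The CDS quantifies how many distinct *chemical ideas* a set of synthesis
routes contains.  Each route is reduced to its disconnection set — the
bonds of the target that are formed in the forward direction anywhere
along the route, keyed by target-frame atom labels.  After deduplication,
dropping empty sets and keeping only inclusion-minimal sets (a route whose
disconnections merely extend another's adds no new idea), the retained
family C_M is scored

    CDS = 1 + (1 / |C_M|) * sum over all ordered pairs (T, T') in C_M
                                 of the Jaccard distance d_J(T, T'),

so a single idea scores 1 and n pairwise-disjoint ideas score exactly n.
Bond keys deliberately ignore bond order/type: a disconnection is a change
of connectivity, and different named reactions forming the same bond are
one idea.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph import GraphError, SynthesisRoute

BondKey = tuple[str, str]
DisconnectionSet = frozenset  # of BondKey


def bond_key(a: str, b: str) -> BondKey:
    """Order-normalized key of one formed bond."""
    return (a, b) if a <= b else (b, a)


def formed_bonds(
    product_bonds: Iterable[tuple[str, str]],
    reactant_bonds: Iterable[tuple[str, str]],
) -> DisconnectionSet:
    """Bonds present in the product but not in the reactants.

    These are the bonds formed in the forward direction, i.e. the
    disconnections when read retrosynthetically.  Atom labels must be in a
    consistent (atom-mapped) frame.
    """
    prod = {bond_key(a, b) for a, b in product_bonds}
    reac = {bond_key(a, b) for a, b in reactant_bonds}
    return frozenset(prod - reac)


def extract_disconnections(route: SynthesisRoute) -> DisconnectionSet:
    """Union of formed-bond keys over every reaction of the route."""
    bonds: set[BondKey] = set()
    for rxn in route.reactions():
        if rxn not in route.reaction_bonds:
            raise GraphError(f"reaction {rxn!r} carries no formed-bond labels")
        bonds.update(bond_key(a, b) for a, b in route.reaction_bonds[rxn])
    return frozenset(bonds)


def build_cm(
    sets: Sequence[DisconnectionSet], minimality: str = "subset"
) -> list[DisconnectionSet]:
    """The retained family C_M: deduplicated, non-empty, minimal sets.

    ``minimality="subset"`` keeps a set unless some other (smaller) input
    set is a strict subset of it; ``"cover"`` additionally drops sets that
    are unions of strictly smaller retained sets.  Output order is by size,
    then lexicographic, for determinism.
    """
    family = {frozenset(s) for s in sets if s}
    if minimality not in ("subset", "cover"):
        raise ValueError("minimality must be 'subset' or 'cover'")
    kept = []
    for t in family:
        if any(o < t for o in family):
            continue
        kept.append(t)
    if minimality == "cover":
        survivors = []
        for t in kept:
            smaller = [o for o in family if o < t]
            union: set = set()
            for o in smaller:
                union |= o
            if smaller and union == set(t):
                continue
            survivors.append(t)
        kept = survivors
    return sorted(kept, key=lambda s: (len(s), sorted(s)))


def jaccard_distance(a: DisconnectionSet, b: DisconnectionSet) -> float:
    """1 - |a n b| / |a u b|; two empty sets are at distance 0."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


@dataclass
class CdsResult:
    """Retained family, all-to-all distance matrix and the final score."""

    c_m: list[DisconnectionSet]
    distance_matrix: np.ndarray
    score: float
    empty: bool = False


def cds(
    routes: Sequence[SynthesisRoute], minimality: str = "subset"
) -> CdsResult:
    """Chemical diversity score of a route set.

    Scores lie in [1, |C_M|]; the upper bound is attained exactly when the
    retained disconnection sets are pairwise disjoint.  An empty input (or
    routes with no disconnections at all) scores 0 with ``empty=True``.
    """
    sets = [extract_disconnections(r) for r in routes]
    return cds_of_sets(sets, minimality=minimality)


def cds_of_sets(
    sets: Sequence[DisconnectionSet], minimality: str = "subset"
) -> CdsResult:
    c_m = build_cm(sets, minimality=minimality)
    n = len(c_m)
    if n == 0:
        return CdsResult(c_m=[], distance_matrix=np.zeros((0, 0)), score=0.0, empty=True)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jaccard_distance(c_m[i], c_m[j])
            mat[i, j] = mat[j, i] = d
    score = 1.0 + float(mat.sum()) / n
    return CdsResult(c_m=c_m, distance_matrix=mat, score=score)


def unique_molecule_counts(routes: Sequence[SynthesisRoute]) -> dict[str, int]:
    """Counts of unique intermediates and building blocks across routes.

    Intermediates are non-root, non-leaf molecules; building blocks the
    route leaves.  Both are unions over the whole set, so duplicating a
    route changes nothing.
    """
    intermediates: set[str] = set()
    leaves: set[str] = set()
    for r in routes:
        r_leaves = set(r.leaves())
        leaves |= r_leaves
        for m in r.molecules():
            if m != r.root and m not in r_leaves:
                intermediates.add(m)
    return {
        "unique_intermediates": len(intermediates),
        "unique_building_blocks": len(leaves),
    }


def route_length_stats(
    route_sets: Mapping[str, Sequence[SynthesisRoute]]
) -> dict[str, float]:
    """Distribution of per-target mean reaction counts.

    For each solved target the mean number of reactions over its routes is
    taken; the summary reports mean, median and interquartile range of
    those per-target means.  Raises when no target has any route.
    """
    per_target = [
        statistics.fmean(r.n_reactions() for r in routes)
        for routes in route_sets.values()
        if routes
    ]
    if not per_target:
        raise GraphError("no solved targets: route_length_stats needs >= 1 route")
    q1, _q2, q3 = np.percentile(per_target, [25, 50, 75])
    return {
        "mean_reactions": statistics.fmean(per_target),
        "median": float(_q2),
        "iqr": float(q3 - q1),
    }
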