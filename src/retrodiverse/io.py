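"""JSON readers and writers for graphs and route sets.

Graph dialect (``format_version`` 1)::

    {"format_version": 1,
     "root": "m0",
     "nodes": [{"id": "m0", "role": "molecule", "terminal": "building_block"}, ...],
     "edges": [{"from": "m0", "to": "r0", "cost": 2, "score": 0.91}, ...],
     "reaction_bonds": {"r0": [["a1", "a4"]]}}

Routes are stored as nested alternating trees::

    {"format_version": 1,
     "routes": [{"mol": "m0",
                 "via": {"rxn": "r0", "bonds": [["a1", "a4"]], "score": 0.91,
                         "reactants": [{"mol": "m3"}, ...]}}]}

Readers validate the schema and name the offending field on error.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence, Union

from .graph import (
    BUILDING_BLOCK,
    DEAD_END,
    MOLECULE,
    NO_TERMINAL,
    REACTION,
    AndOrGraph,
    SynthesisRoute,
)

FORMAT_VERSION = 1

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed or schema-violating input file."""


def _check_version(data: dict, where: str) -> None:
    version = data.get("format_version")
    if version != FORMAT_VERSION:
        raise FormatError(
            f"{where}: unsupported format_version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )


# -- graphs --------------------------------------------------------------------


def graph_to_dict(g: AndOrGraph) -> dict:
    nodes = []
    for node in g.nodes():
        entry: dict[str, Any] = {"id": node, "role": g.role(node)}
        term = g.terminal(node)
        if term != NO_TERMINAL:
            entry["terminal"] = term
        nodes.append(entry)
    edges = []
    for parent in g.nodes():
        for child in g.successors(parent):
            e: dict[str, Any] = {"from": parent, "to": child}
            if (parent, child) in g.edge_costs:
                e["cost"] = g.edge_costs[(parent, child)]
            if (parent, child) in g.edge_scores:
                e["score"] = g.edge_scores[(parent, child)]
            edges.append(e)
    out: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "root": g.root,
        "nodes": nodes,
        "edges": edges,
    }
    if g.reaction_bonds:
        out["reaction_bonds"] = {
            r: sorted(list(b) for b in bonds) for r, bonds in g.reaction_bonds.items()
        }
    return out


def graph_from_dict(data: dict) -> AndOrGraph:
    _check_version(data, "graph")
    if "root" not in data:
        raise FormatError("graph: missing field 'root'")
    g = AndOrGraph(root=data["root"])
    for i, entry in enumerate(data.get("nodes", [])):
        if "id" not in entry:
            raise FormatError(f"graph.nodes[{i}]: missing field 'id'")
        role = entry.get("role")
        if role not in (MOLECULE, REACTION):
            raise FormatError(
                f"graph.nodes[{i}] ({entry['id']!r}): invalid role {role!r}"
            )
        term = entry.get("terminal", NO_TERMINAL)
        if term not in (BUILDING_BLOCK, DEAD_END, NO_TERMINAL):
            raise FormatError(
                f"graph.nodes[{i}] ({entry['id']!r}): invalid terminal {term!r}"
            )
        g.add_node(entry["id"], role, term)
    for i, e in enumerate(data.get("edges", [])):
        if "from" not in e or "to" not in e:
            raise FormatError(f"graph.edges[{i}]: missing 'from'/'to'")
        cost = e.get("cost")
        score = e.get("score")
        if cost is not None and (not isinstance(cost, (int, float)) or cost < 0):
            raise FormatError(f"graph.edges[{i}]: invalid cost {cost!r}")
        if score is not None and not (0.0 <= score <= 1.0):
            raise FormatError(f"graph.edges[{i}]: score {score!r} outside [0,1]")
        g.add_edge(e["from"], e["to"], cost=cost, score=score)
    for rxn, bonds in data.get("reaction_bonds", {}).items():
        g.reaction_bonds[rxn] = frozenset(tuple(b) for b in bonds)
    return g


def write_graph(g: AndOrGraph, path: PathLike) -> None:
    Path(path).write_text(json.dumps(graph_to_dict(g), indent=1, sort_keys=True))


def read_graph(path: PathLike) -> AndOrGraph:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    return graph_from_dict(data)


# -- routes --------------------------------------------------------------------


def _route_to_tree(route: SynthesisRoute, mol: str) -> dict:
    node: dict[str, Any] = {"mol": mol}
    kids = route.children.get(mol, [])
    if kids:
        rxn = kids[0]
        via: dict[str, Any] = {"rxn": rxn}
        if rxn in route.reaction_bonds:
            via["bonds"] = sorted(list(b) for b in route.reaction_bonds[rxn])
        if rxn in route.reaction_scores:
            via["score"] = route.reaction_scores[rxn]
        via["reactants"] = [
            _route_to_tree(route, m) for m in route.children.get(rxn, [])
        ]
        node["via"] = via
    return node


def route_to_dict(route: SynthesisRoute) -> dict:
    return _route_to_tree(route, route.root)


def route_from_dict(tree: dict, where: str = "route") -> SynthesisRoute:
    if "mol" not in tree:
        raise FormatError(f"{where}: missing field 'mol'")
    route = SynthesisRoute(root=tree["mol"])

    def walk(node: dict, where: str) -> None:
        mol = node.get("mol")
        if not isinstance(mol, str):
            raise FormatError(f"{where}: invalid 'mol' {mol!r}")
        via = node.get("via")
        if via is None:
            return
        rxn = via.get("rxn")
        if not isinstance(rxn, str):
            raise FormatError(f"{where}.via: invalid 'rxn' {rxn!r}")
        route.children[mol] = [rxn]
        if "bonds" in via:
            try:
                route.reaction_bonds[rxn] = frozenset(
                    (a, b) for a, b in via["bonds"]
                )
            except (TypeError, ValueError):
                raise FormatError(f"{where}.via.bonds: not a list of pairs") from None
        if "score" in via:
            score = via["score"]
            if not (0.0 <= score <= 1.0):
                raise FormatError(f"{where}.via.score: {score!r} outside [0,1]")
            route.reaction_scores[rxn] = score
        reactants = via.get("reactants", [])
        route.children[rxn] = [r.get("mol") for r in reactants]
        for i, sub in enumerate(reactants):
            walk(sub, f"{where}.via.reactants[{i}]")

    walk(tree, where)
    return route


def write_routes(routes: Sequence[SynthesisRoute], path: PathLike) -> None:
    data = {
        "format_version": FORMAT_VERSION,
        "routes": [route_to_dict(r) for r in routes],
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def read_routes(path: PathLike) -> list[SynthesisRoute]:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    _check_version(data, str(path))
    return [
        route_from_dict(tree, where=f"routes[{i}]")
        for i, tree in enumerate(data.get("routes", []))
    ]
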