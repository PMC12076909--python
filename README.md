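# retrodiverse

Diversity-oriented retrosynthetic route search on AND/OR reaction
networks.

Computer-assisted synthesis planning reduces to a two-player game on a
bipartite graph: molecule nodes (OR) need one provable reaction, reaction
nodes (AND) need all their reactants provable; the molecule player wins on
reaching a purchasable building block, the reaction player at a dead end
or when a molecule repeats on the line of play. A winning strategy is a
synthesis route. A single "best" route is rarely what a chemist wants —
objectives differ by lab and context — so this package searches for a
*diverse set* of routes and quantifies that diversity.

It provides:

* **Game core and oracles** — the AND/OR graph model, route validity,
  exhaustive minimax solving and route enumeration as ground truth.
* **PNS / DFPN** — proof-number search and its depth-first variant with
  threshold propagation (pn = min/sum, dn = sum/min over OR/AND nodes,
  backtracking once `pn ≥ th_pn` or `dn ≥ th_dn`), the threshold
  controlling algorithm (TCA) that raises thresholds at nodes with an old
  child `md(child) ≤ md(node)` so cyclic graphs cannot trap the search,
  and path-keyed proof caching that avoids the graph-history-interaction
  pitfall. A 7-node cyclic fixture on which plain history-free DFPN is
  demonstrably incomplete ships with the package.
* **Multi-solution DFPN*** — iterated DFPN that, after each found route,
  force-disproves a deepest reaction *under the path that reached it* and
  adds a penalty `p_reac` to the proof numbers of the used reactions
  (`pn(v) := pn(v) + p_reac`), so successive searches are steered toward
  different chemistry. Optional DFPN-E edge costs (`round(-ln s)` of a
  one-step score `s`).
* **MCTS baseline** — a one-player UCB1 tree search with a visited-node
  penalty, for comparison.
* **Chemical Diversity Score (CDS)** — each route is reduced to its set of
  formed bonds (disconnections) in the target's atom frame; after
  deduplication and inclusion-minimal filtering into the family C_M,

      CDS = 1 + (1/|C_M|) · Σ_{T,T'∈C_M} d_J(T, T'),

  the all-to-all Jaccard-distance mean, interpretable as the number of
  distinct chemical ideas in the set (n disjoint ideas score exactly n).
* **Synthetic networks** — seeded generators of branching reaction
  networks with planted routes, dead ends, directed cycles, per-reaction
  viability scores and idea-redundant bond labels, plus route-set
  generators with exact planted diversity.

## Worked example

Generate a synthetic target network, search it for a diverse route set,
and score the result:

```
$ cat spec.json
{"n_molecules": 80, "depth": 5, "planted_routes": 3,
 "max_reactions_per_molecule": 3, "buyable_fraction": 0.3,
 "dead_end_fraction": 0.3, "cycle_fraction": 0.1, "seed": 7}

$ retrodiverse simulate --spec spec.json --out net.json --routes planted.json
wrote 118-node network (3 planted route(s)) -> net.json

$ retrodiverse diversify --graph net.json -k 8 --p-reac 5 --budget 20000 --out routes.json
found 6 route(s) -> routes.json

$ retrodiverse score-cds --routes routes.json
CDS: 3.5460 over |C_M| = 4 idea(s)
unique intermediates: 5, unique building blocks: 8
mean reactions/route: 3.67 (median 3.67, iqr 0.00)
```

The six routes embody four distinct disconnection ideas; a CDS of 3.55
(between 1 = one idea and |C_M| = 4 = all ideas mutually disjoint) says
the ideas partially overlap in the bonds they form. The same library calls
are available programmatically:

```python
from retrodiverse import (NetworkSpec, generate_network, find_route_set,
                          PenaltyConfig, SearchBudget, cds)

graph, planted = generate_network(NetworkSpec(seed=7, planted_routes=3))
routes = find_route_set(graph, PenaltyConfig(p_reac=5, max_solutions=8),
                        SearchBudget(max_expansions=20_000))
print(len(routes), cds(routes).score)
```

Other subcommands: `search` (single-solution PNS/DFPN/MCTS), `bench`
(DFPN* vs MCTS table across budgets, tidy TSV), `simulate --counterexample` (emit
the 7-node counterexample graph).

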