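# Methods

## The game model

Retrosynthesis is played as a two-player game on a directed bipartite
AND/OR graph. Molecule nodes belong to the molecule player (OR: one
provable reaction suffices), reaction nodes to the reaction player (AND:
every reactant must be provable). The molecule player wins on reaching a
purchasable building block; the reaction player wins at a dead end or when
a molecule repeats on the current line of play. A winning strategy for the
molecule player is exactly a synthesis route: a rooted alternating tree
whose leaves are building blocks.

Because the repetition rule caps play length by the molecule count, the
game value is decidable by exhaustive minimax (`solve_brute_force`), and a
winning region with attractor ranks gives positional strategies that are
acyclic even on cyclic graphs. These two independent evaluations are the
ground truth for every search algorithm in the package.

## Proof-number search and DFPN

Each explored node carries a proof number `pn` and disproof number `dn` —
optimistic estimates of how many frontier nodes must be (dis)proved to
settle it. Molecule nodes aggregate `pn = min`, `dn = sum` over children;
reaction nodes the transpose. PNS repeatedly descends to the most
promising frontier node (minimum `pn` at molecule nodes, minimum `dn` at
reaction nodes) and expands it. DFPN makes this depth-first: a child is
searched while `pn < th_pn` and `dn < th_dn`, with thresholds derived from
the point at which best-first search would have switched children (capped
one above the second-best sibling, or carrying the surplus over the
parent's threshold). Sums and thresholds saturate at infinity.

Two reinforcements handle cyclic graphs:

* **Threshold controlling (TCA).** Every record keeps `md`, the minimum
  root distance seen so far (monotonically non-increasing). When a node
  has an unproved *old* child (`md(child) <= md(node)`) — the signature of
  a cycle being re-derived — the thresholds are raised to one above the
  current `pn`/`dn`, so the search cannot backtrack without making
  progress; the raise propagates to recursive calls until a node is
  expanded or a cycle is closed. The raise amount is the minimal one
  satisfying the strict threshold inequalities.

* **Path-aware caching (GHI safety).** A (dis)proof found along one root
  path need not hold along another (graph-history interaction). In safe
  mode every resolution is stored with its dependency set: proofs carry
  the molecules of the proving strategy and are reused only in contexts
  disjoint from it; repetition-based disproofs carry the on-path molecules
  they blamed and are reused only while those are still on the path.
  Resolutions with empty dependencies are context-free and cached in the
  record itself. Estimates (unresolved `pn`/`dn`) remain ordinary DFPN
  heuristics and may be stale; only validated resolutions decide outcomes.

With `ghi_safe=False` the solver is the textbook history-free DFPN: it
ignores path state entirely, and when a selection would close a cycle it
backtracks with whatever stale values it has. On the bundled 7-node
counterexample this search revisits the two cyclic branches indefinitely
and never expands the reaction leading to the only building block; with
TCA and path-aware caching the same graph is proved in a handful of
expansions. Since the history-free search can loop without expanding,
budgets combine an expansion count with a derived visit cap and a stall
guard (visits since the last expansion or resolution); an undecided search
reports `unproved`.

### The counterexample fixture

The fixture is the smallest graph the package ships on which history-free
DFPN is incomplete: root `v0` with reaction children `v1`, `v2`, `v5`; the
branches `v1 <-> v4` and `v2 <-> v3` are two-node cycles; `v5 -> v6` is the
only winning line (`v6` the only building block, no explicit dead ends).
The graph is symmetric under swapping the two cyclic branches. Its edge
set was fixed by enumerating all bipartite-legal completions of the
structurally required edges and keeping the unique fully symmetric one on
which (a) plain DFPN exhausts any budget without expanding `v5`, (b)
DFPN+TCA proves the root through `v6`, and (c) the TCA trigger condition
`md(v2) <= md(v3)` is observed.

## Multi-solution search (DFPN*)

A deterministic solver rerun returns the same route, so the multi-solution
driver perturbs the problem after each proof:

1. pick a deepest reaction of the found route (longest path from the
   target; ties to pre-order), which invalidates the route while
   destroying as few other routes as possible;
2. force-disprove it *under the path that reached it* — keyed by the
   branch molecules, so the same reaction remains usable along other
   paths; the registry only grows within a run;
3. add `p_reac` to the proof number of every reaction on that path
   (`p_mol` for molecules, default 0 since disproving a molecule disproves
   a reaction anyway), steering the next iteration away from used
   chemistry.

Penalties persist across iterations as per-node bonuses folded into the
estimates at recomputation time; they bias selection but never veto an
exact resolution, so penalized-but-provable subtrees remain reachable.
After each forced disproof the cached proofs are invalidated (disproofs
survive: removing options cannot un-disprove a node). The expansion budget
is global across the whole run. Optional DFPN-E edge costs map a one-step
reaction score `s` to `round(-ln s)` (capped) and enter the molecule-node
selection keys and pn thresholds symmetrically; whether the original
edge-cost variant also reshapes threshold propagation differently is not
specified in the available description, and the symmetric treatment is the
package's choice.

The scheme trades enumeration completeness for diversity: a forced
disproof can prune siblings that only recombine already-seen chemistry, so
on graphs with k enumerable routes the driver may legitimately stop with
fewer than k (it always returns at least one on solvable inputs, and the
returned set is valid, duplicate-free and byte-reproducible).

## MCTS baseline

The one-player formulation: a state is the set of open (unsolved,
non-purchasable) molecules; a move applies one candidate reaction to the
first open molecule, replacing it by its non-buyable reactants; a state
with no open molecules is a win. Iterations run selection (UCB1 with an
additive penalty `visit_penalty * visits`, so long runs keep drifting to
new lines; unvisited children score infinity), expansion of all children
of the selected leaf at once, a uniformly random rollout to
`rollout_depth` with binary reward, and backpropagation. Every distinct
winning line of the tree is recorded as a route; rollout wins contribute
reward only. The baseline is deliberately simple — no learned priors, no
progressive widening — and is used as a comparison scaffold, not a
re-implementation of any production tool.

## Chemical diversity score

A route's *disconnection set* is the union, over its reactions, of the
bonds formed in the forward direction, keyed by order-normalized pairs of
target-frame atom labels; bond order/type is ignored (a disconnection is a
connectivity change). Across a route set the family is deduplicated,
empty sets are dropped, and only inclusion-minimal sets are retained
(strict-subset reading; a union-cover reading is switchable with
`minimality="cover"`): a route whose disconnections merely extend
another's contributes no new idea. The score is

    CDS = 1 + (1/|C_M|) * sum_{T,T' in C_M} d_J(T, T'),

an ordered double sum including the zero diagonal. One idea scores 1, n
pairwise-disjoint ideas score exactly n, and the score is invariant under
route order, duplication, and superset routes. Empty input scores 0 with
an explicit flag. Baseline metrics (unique intermediates/building blocks,
per-target route-length distributions) are provided for comparison.

## Synthetic networks

`generate_network` emulates the search landscape a model-backed
retrosynthesis stack faces, with known ground truth:

* **planted routes** — mostly linear backbones (convergent steps with
  probability 0.3) wired from the target to forced building blocks, so
  solvability and a reference route are guaranteed;
* **distractor chemistry** — additional molecules per depth layer that are
  buyable (`buyable_fraction`), explicit dead ends (`dead_end_fraction` —
  the unmakeable intermediates that dominate real searches), or expandable
  through further random reactions;
* **idea redundancy** — every molecule owns a pool of one to three
  disconnection ideas (bond-label sets over `n_atoms` target atoms) and
  each of its reactions realises one of them, mirroring the many named
  reactions that form the same bond; without this, every route would be a
  new idea and diversity scores would just count routes;
* **cycles** — with probability `cycle_fraction` a molecule gains an extra
  edge back to an ancestor-side reaction, creating directed cycles while
  only ever adding options for the molecule player (planted routes stay
  intact);
* **viability scores** — per-edge Beta(6, 2) samples (mean ≈ 0.75,
  left-skewed, as confident one-step predictions tend to be).

What the generator does not emulate: real molecular structure, reaction
feasibility chemistry, catalog composition, or score calibration of any
actual model. Passing tests therefore demonstrate algorithmic properties
(soundness, completeness, determinism, directional diversity behaviour),
not chemical performance.

`generate_route_set` builds route sets with an exact planted idea
structure (pools of bond labels with controllable overlap) and is the
closed-form harness for the diversity score.

## The diversity-trend experiment

The directional comparison runs on networks where a route search has real
choices: 600 molecule slots, depth 9, up to 4 reactions per molecule and 3
reactants per reaction, buyable fraction 0.12, dead-end fraction 0.55,
cycle fraction 0.1. Both algorithms get the same numeric work budget
(4000 DFPN* expansions / 4000 MCTS iterations) — a deterministic analogue
of the wall-clock budgets a deployment would use — with no cap pressure on
route counts (max 50). Over the fixed seed panel 0–49 the package asserts,
with a 0.05 tolerance on means, that raising `p_reac` from 0 to 20 does
not reduce mean CDS and that DFPN* attains at least the MCTS baseline's
mean CDS. These are trend statements over the panel, not per-instance
guarantees; the margins were confirmed on five disjoint seed windows
before the panel was frozen.

## Numerical and degenerate-input choices

* `pn`/`dn` are extended non-negative numbers; sums and threshold
  arithmetic saturate at infinity, subtraction floors at zero.
* Ties everywhere break to the first child in the graph's stored child
  order; node ids are opaque strings; all algorithms are deterministic
  given the seed.
* A target that is itself a building block is solved by the empty route
  with viability 1 (empty-product convention); a childless non-buyable
  molecule is an implicit dead end; a childless reaction is vacuously
  proved.
* Initial root thresholds are (∞, ∞); unexpanded nodes start at
  `pn = dn = 1`; `md(root) = 0` and `md(child)` is minimized over visits.
* The brute-force solver is guarded to 200 nodes; route enumeration caps
  at `max_routes` and is intended for fixture-scale graphs only.

## Known limitations

* History-free mode reports `unproved` via stall/visit guards rather than
  looping forever; the guard thresholds are generous but finite.
* The multi-solution driver's forced disproofs can prune reachable routes
  (by design); it is not an enumerator.
* The MCTS baseline's route output depends on the visit penalty; with a
  zero penalty it can fixate on one line indefinitely.
* Proof-cache invalidation between multi-solution iterations is
  conservative (all proofs dropped), trading recomputation for simplicity.
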