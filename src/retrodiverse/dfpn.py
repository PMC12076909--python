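"""Proof-number search and depth-first proof-number search (DFPN).

Both solvers maintain, for every explored node, a *proof number* ``pn``
(estimated number of frontier nodes that must be proved for the node to be
proved) and a *disproof number* ``dn``.  Molecule (OR) nodes take the
minimum child ``pn`` and the sum of child ``dn``; reaction (AND) nodes the
other way round.  DFPN avoids restarting from the root by carrying
thresholds ``th_pn``/``th_dn`` down the recursion and backtracking once
``pn >= th_pn`` or ``dn >= th_dn``.

Two optional reinforcements deal with cyclic reaction networks:

* **TCA** (threshold controlling algorithm): every node records ``md``,
  its minimum distance from the root in the explored graph.  When a node
  has an unproved *old* child (``md(child) <= md(node)``) the thresholds
  are raised just above the current ``pn``/``dn`` so the search cannot
  oscillate without making progress; the raise is propagated to recursive
  calls until a node is expanded or a cycle is closed.

* **GHI-safe caching**: a (dis)proof found along one root path need not
  hold along another (graph-history interaction).  In safe mode the
  repetition rule is evaluated against the actual path, and every
  resolution is stored together with the set of molecules it depended on:
  a proof is reused only when no molecule of its strategy lies on the new
  path, a repetition-based disproof only when the molecules it blamed are
  still on the path.  With ``ghi_safe=False`` the solver is the textbook
  history-free DFPN, which is incomplete on cyclic graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .graph import (
    BUILDING_BLOCK,
    DEAD_END,
    DISPROVED,
    MOLECULE,
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

INF = float("inf")
UNKNOWN = "unknown"


def sat_add(a: float, b: float) -> float:
    """Saturating addition on extended non-negative integers."""
    if a == INF or b == INF:
        return INF
    return a + b


def sat_sum(values) -> float:
    total = 0.0
    for v in values:
        if v == INF:
            return INF
        total += v
    return total


def sat_sub(a: float, b: float) -> float:
    """``a - b`` with ``INF`` absorbing; never below 0."""
    if a == INF:
        return INF
    if b == INF:
        return 0.0
    return max(a - b, 0.0)


@dataclass
class SearchBudget:
    """Work limits for one solver run.

    ``max_expansions`` bounds the number of distinct node-expansion events.
    ``max_visits`` (optional) bounds total node visits; by default it is
    derived generously from ``max_expansions`` so that a search that stops
    expanding but keeps revisiting nodes — the failure mode of history-free
    DFPN on cyclic graphs — still terminates and reports ``unproved``.
    ``rng_seed`` is carried for stochastic consumers (MCTS, generators);
    the DFPN family itself is deterministic.
    """

    max_expansions: int = 10_000
    rng_seed: int = 0
    max_visits: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_expansions < 1:
            raise ValueError("max_expansions must be >= 1")

    def visit_cap(self, n_nodes: int) -> int:
        if self.max_visits is not None:
            return self.max_visits
        return max(5_000, 40 * self.max_expansions, 400 * n_nodes)


@dataclass
class SearchRecord:
    """Per-node search state.

    ``pn``/``dn`` are the latest estimates (terminal nodes hold their exact
    values).  ``md`` is the minimum root distance seen so far, ``pn_bonus``
    the cumulative diversity penalty added by the multi-solution driver,
    and ``proofs`` the path-keyed resolution store used in GHI-safe mode:
    tuples ``(status, key, dep_known)`` where ``key`` is the dependency set
    of molecules (``dep_known=True``) or the full storing path as a
    conservative fallback.
    """

    pn: float = 1.0
    dn: float = 1.0
    md: int = 0
    expanded: bool = False
    terminal: bool = False
    pn_bonus: float = 0.0
    proofs: list[tuple[str, frozenset, bool]] = field(default_factory=list)


# -- pure update rules ---------------------------------------------------------


def update_numbers(
    role: str,
    child_pns: Sequence[float],
    child_dns: Sequence[float],
    child_costs: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Aggregate child (dis)proof numbers at a node of the given role.

    Molecule (OR): ``pn = min(pn_i + cost_i)``, ``dn = sum(dn_i)``;
    reaction (AND): ``pn = sum(pn_i)``, ``dn = min(dn_i)``.  Costs are the
    optional DFPN-E edge heuristic, only meaningful on molecule->reaction
    edges.  Sums saturate at infinity.
    """
    if not child_pns or len(child_pns) != len(child_dns):
        raise ValueError("child number sequences must be non-empty and aligned")
    if child_costs is None:
        child_costs = [0.0] * len(child_pns)
    if role == MOLECULE:
        pn = min(sat_add(p, c) for p, c in zip(child_pns, child_costs))
        dn = sat_sum(child_dns)
    elif role == REACTION:
        pn = sat_sum(child_pns)
        dn = min(child_dns)
    else:
        raise ValueError(f"unknown role {role!r}")
    return pn, dn


def child_thresholds(
    role: str,
    th_pn_v: float,
    th_dn_v: float,
    pn_v: float,
    dn_v: float,
    chosen: tuple[float, float],
    second_best: tuple[float, float],
    single_child: bool,
    chosen_cost: float = 0.0,
    second_cost: float = 0.0,
) -> tuple[float, float]:
    """Thresholds handed to the chosen child.

    A single child inherits the thresholds unchanged.  At a molecule node
    the child's ``th_pn`` is capped one above the second-best child's proof
    number (the point at which PNS would switch children) while ``th_dn``
    passes on the surplus over the sum; at a reaction node the roles of pn
    and dn swap.  Edge costs, when enabled, shift the pn bounds into and
    out of the child's own frame.
    """
    if single_child:
        return th_pn_v, th_dn_v
    if role == MOLECULE:
        bound = sat_add(sat_add(second_best[0], second_cost), 1)
        th_pn = sat_sub(min(th_pn_v, bound), chosen_cost)
        th_dn = sat_add(sat_sub(th_dn_v, dn_v), chosen[1])
        if th_dn_v == INF:
            th_dn = INF
    else:
        th_pn = sat_add(sat_sub(th_pn_v, pn_v), chosen[0])
        if th_pn_v == INF:
            th_pn = INF
        th_dn = min(th_dn_v, sat_add(second_best[1], 1))
    return th_pn, th_dn


# -- GHI store -----------------------------------------------------------------


def ghi_store(
    v: str,
    ctx: PathContext,
    status: str,
    records: dict[str, SearchRecord],
    dependencies: Optional[frozenset] = None,
) -> None:
    """Record a (dis)proof of ``v`` found under path ``ctx``.

    With an explicit dependency set the entry is reusable in every context
    the set permits; without one the storing path itself is kept and reuse
    is restricted to contexts where validity is certain (subset for proofs,
    superset for disproofs).
    """
    rec = records.setdefault(v, SearchRecord())
    if dependencies is not None:
        entry = (status, frozenset(dependencies), True)
    else:
        entry = (status, frozenset(ctx.molecules_on_path), False)
    if entry not in rec.proofs:
        rec.proofs.append(entry)


def ghi_lookup(
    v: str, ctx: PathContext, records: dict[str, SearchRecord]
) -> str:
    """Return a stored resolution of ``v`` valid under ``ctx``, else unknown."""
    status, _dep = ghi_lookup_entry(v, ctx, records)
    return status


def ghi_lookup_entry(
    v: str, ctx: PathContext, records: dict[str, SearchRecord]
) -> tuple[str, frozenset]:
    """Like :func:`ghi_lookup` but also return the validated dependency set."""
    rec = records.get(v)
    if rec is None:
        return UNKNOWN, frozenset()
    path = ctx.molecules_on_path
    for status, key, dep_known in rec.proofs:
        if status == PROVED:
            if dep_known:
                if not (key & path):
                    return PROVED, key
            elif path <= key:
                return PROVED, key
        else:
            if key <= path:
                return DISPROVED, key
    return UNKNOWN, frozenset()


# -- forced-disproof registry (used by the multi-solution driver) --------------


@dataclass
class DisproofRegistry:
    """Path-keyed forced disproofs; entries only ever grow within one run."""

    entries: set[tuple[str, frozenset]] = field(default_factory=set)

    def add(self, node: str, path_molecules: frozenset) -> None:
        self.entries.add((node, frozenset(path_molecules)))

    def matches(self, node: str, path_molecules: frozenset) -> Optional[frozenset]:
        """Dependency key of a matching forced disproof, or None.

        A forced disproof applies whenever every molecule of the stored
        branch lies on the current path — i.e. the search is about to
        rebuild the very route the disproof was meant to invalidate.
        """
        for n, key in self.entries:
            if n == node and key <= path_molecules:
                return key
        return None


class _Exhausted(Exception):
    """Internal: budget or stall limit hit; surfaced as an unproved outcome."""


class DfpnSearch:
    """Resumable DFPN engine over one graph.

    Counters and records persist across :meth:`run` calls so the
    multi-solution driver can continue a search after forcing disproofs and
    applying penalties, under one global budget.
    """

    def __init__(
        self,
        g: AndOrGraph,
        use_tca: bool = True,
        ghi_safe: bool = True,
        use_edge_costs: bool = False,
        registry: Optional[DisproofRegistry] = None,
        trace: Optional[list] = None,
    ) -> None:
        self.g = g
        self.use_tca = use_tca
        self.ghi_safe = ghi_safe
        self.use_edge_costs = use_edge_costs
        self.registry = registry
        self.trace = trace
        self.records: dict[str, SearchRecord] = {}
        self.expansions = 0
        self.visits = 0
        self._last_expand_visit = 0
        self._max_expansions = 0
        self._visit_cap = 0
        self._stall_limit = max(4_000, 600 * len(g))

    # -- helpers ---------------------------------------------------------------

    def _ensure_record(self, v: str, depth: int) -> SearchRecord:
        rec = self.records.get(v)
        if rec is None:
            rec = SearchRecord(md=depth)
            term = self.g.terminal(v)
            if term == BUILDING_BLOCK:
                rec.pn, rec.dn, rec.terminal = 0.0, INF, True
            elif term == DEAD_END or (
                self.g.role(v) == MOLECULE and not self.g.successors(v)
            ):
                rec.pn, rec.dn, rec.terminal = INF, 0.0, True
            self.records[v] = rec
        else:
            rec.md = min(rec.md, depth)
        return rec

    def child_value(
        self, c: str, path_mols: frozenset
    ) -> tuple[float, float, frozenset]:
        """(pn, dn, dependency set) of child ``c`` seen from a path.

        Resolution sources, in order: exact terminal values; the repetition
        rule (GHI-safe mode only — history-free DFPN ignores path state,
        which is precisely what makes it incomplete); forced disproofs from
        the multi-solution registry; the path-keyed proof store; finally
        the cached estimates, with the diversity penalty folded into pn.
        """
        rec = self.records[c]
        if rec.terminal:
            dep = frozenset({c}) if rec.pn == 0 else frozenset()
            return rec.pn, rec.dn, dep
        if self.ghi_safe and self.g.role(c) == MOLECULE and c in path_mols:
            return INF, 0.0, frozenset({c})
        if self.registry is not None and self.g.role(c) == REACTION:
            key = self.registry.matches(c, path_mols)
            if key is not None:
                return INF, 0.0, key
        if self.ghi_safe:
            status, dep = ghi_lookup_entry(c, PathContext(path_mols), self.records)
            if status == PROVED:
                return 0.0, INF, dep
            if status == DISPROVED:
                return INF, 0.0, dep
        pn = rec.pn if rec.pn in (0.0, INF) else sat_add(rec.pn, rec.pn_bonus)
        return pn, rec.dn, frozenset()

    def _edge_cost(self, parent: str, child: str) -> float:
        if not self.use_edge_costs:
            return 0.0
        from .multisolution import edge_cost  # late import: sibling module

        return float(edge_cost(self.g, parent, child))

    def _tick(self) -> None:
        self.visits += 1
        if self.visits > self._visit_cap:
            raise _Exhausted
        if self.visits - self._last_expand_visit > self._stall_limit:
            raise _Exhausted

    # -- main recursion --------------------------------------------------------

    def _mid(
        self,
        v: str,
        th_pn: float,
        th_dn: float,
        path_mols: frozenset,
        path_nodes: frozenset,
        depth: int,
        raised: bool,
    ) -> None:
        self._tick()
        rec = self._ensure_record(v, depth)
        role = self.g.role(v)
        kids = self.g.successors(v)
        here_mols = path_mols | {v} if role == MOLECULE else path_mols
        here_nodes = path_nodes | {v}

        if not rec.expanded:
            if self.expansions + 1 > self._max_expansions:
                raise _Exhausted
            self.expansions += 1
            self._last_expand_visit = self.visits
            rec.expanded = True
            raised = False  # progress: a node was expanded
            for c in kids:
                self._ensure_record(c, depth + 1)
            if self.trace is not None:
                self.trace.append(("expand", v, rec.pn, rec.dn, th_pn, th_dn, rec.md))

        if not kids:
            # childless reaction: vacuously proved (empty reactant set)
            rec.pn, rec.dn, rec.terminal = 0.0, INF, True
            return

        costs = None
        if self.use_edge_costs and role == MOLECULE:
            costs = [self._edge_cost(v, c) for c in kids]

        while True:
            vals = [self.child_value(c, here_mols) for c in kids]
            pn_raw, dn = update_numbers(
                role, [x[0] for x in vals], [x[1] for x in vals], costs
            )
            pn = pn_raw if pn_raw in (0.0, INF) else sat_add(pn_raw, rec.pn_bonus)

            if pn_raw == 0.0 or dn == 0.0:
                self._resolve(v, role, kids, vals, pn_raw, dn, here_mols)
                return

            if self.use_tca:
                old_child = any(
                    self.records[c].md <= rec.md
                    and val[0] != 0.0
                    and val[1] != 0.0
                    for c, val in zip(kids, vals)
                )
                if raised or old_child:
                    th_pn = max(th_pn, sat_add(pn, 1))
                    th_dn = max(th_dn, sat_add(dn, 1))
                    raised = True
                    if self.trace is not None:
                        self.trace.append(
                            ("tca_raise", v, pn, dn, th_pn, th_dn, rec.md)
                        )

            if pn >= th_pn or dn >= th_dn:
                rec.pn, rec.dn = pn_raw, dn
                if self.trace is not None:
                    self.trace.append(("backtrack", v, pn, dn, th_pn, th_dn, rec.md))
                return

            # select the most promising child; ties go to graph child order.
            # Selection keys are cost-inclusive pn at molecule nodes, dn at
            # reaction nodes; the second-best key bounds the child threshold.
            if role == MOLECULE:
                keys = [
                    sat_add(vals[i][0], costs[i] if costs else 0.0)
                    for i in range(len(kids))
                ]
            else:
                keys = [vals[i][1] for i in range(len(kids))]
            best = min(range(len(kids)), key=lambda i: (keys[i], i))
            second_key = min(
                (keys[i] for i in range(len(kids)) if i != best), default=INF
            )
            if role == MOLECULE:
                second = (second_key, INF)
            else:
                second = (INF, second_key)
            child = kids[best]

            if child in here_nodes and not self.ghi_safe:
                # closing a cycle: progress for TCA purposes, but the
                # history-free search cannot descend further here.  In
                # GHI-safe mode descent is allowed: the repetition rule
                # resolves the on-path molecules below and bounds the path.
                rec.pn, rec.dn = pn_raw, dn
                if self.trace is not None:
                    self.trace.append(("cycle", v, pn, dn, th_pn, th_dn, rec.md))
                return

            th_pn_c, th_dn_c = child_thresholds(
                role,
                th_pn,
                th_dn,
                pn,
                dn,
                (vals[best][0], vals[best][1]),
                second,
                single_child=len(kids) == 1,
                chosen_cost=costs[best] if costs else 0.0,
                second_cost=0.0,  # second_key is already cost-inclusive
            )
            self._mid(child, th_pn_c, th_dn_c, here_mols, here_nodes, depth + 1, raised)
            rec.pn, rec.dn = pn_raw, dn  # keep estimates current for outer loops

    def _resolve(
        self,
        v: str,
        role: str,
        kids: list[str],
        vals: list[tuple[float, float, frozenset]],
        pn: float,
        dn: float,
        here_mols: frozenset,
    ) -> None:
        """Store a context resolution of ``v`` with its dependency set."""
        rec = self.records[v]
        if pn == 0.0:
            status = PROVED
            if role == MOLECULE:
                i = next(i for i, val in enumerate(vals) if val[0] == 0.0)
                dep = frozenset({v}) | vals[i][2]
            else:
                dep = frozenset().union(*(val[2] for val in vals))
        else:
            status = DISPROVED
            if role == MOLECULE:
                dep = frozenset().union(*(val[2] for val in vals)) - {v}
            else:
                i = next(i for i, val in enumerate(vals) if val[1] == 0.0)
                dep = vals[i][2]
        self._last_expand_visit = self.visits  # a resolution is progress too
        if self.ghi_safe:
            ghi_store(v, PathContext(here_mols - {v}), status, self.records, dep)
            universal = not dep or (status == PROVED and dep == frozenset({v}))
            if universal:
                rec.pn, rec.dn = (0.0, INF) if status == PROVED else (INF, 0.0)
        else:
            rec.pn, rec.dn = (0.0, INF) if status == PROVED else (INF, 0.0)
        if self.trace is not None:
            self.trace.append((status, v, rec.pn, rec.dn, None, None, rec.md))

    # -- public API ------------------------------------------------------------

    def root_status(self) -> str:
        root = self.g.root
        rec = self.records.get(root)
        if rec is None:
            return UNPROVED
        if rec.terminal or not self.ghi_safe:
            if rec.pn == 0.0:
                return PROVED
            if rec.dn == 0.0:
                return DISPROVED
            return UNPROVED
        status = ghi_lookup(root, PathContext(frozenset()), self.records)
        return status if status != UNKNOWN else UNPROVED

    def run(self, budget: SearchBudget) -> GameOutcome:
        """Search until the root resolves or the budget runs out."""
        self._max_expansions = budget.max_expansions
        self._visit_cap = budget.visit_cap(len(self.g))
        # the stall guard measures lack of progress within this run: resumed
        # multi-solution iterations mostly re-derive values without expanding
        self._last_expand_visit = self.visits
        root = self.g.root
        if self.g.role(root) != MOLECULE:
            raise GraphError("root must be a molecule node")
        # recursion depth is bounded by the path length, itself bounded by
        # the node count (a repeated node on the path closes a cycle)
        import sys

        limit = max(sys.getrecursionlimit(), 4 * len(self.g) + 200)
        sys.setrecursionlimit(limit)
        self._ensure_record(root, 0)
        try:
            while self.root_status() == UNPROVED:
                self._mid(root, INF, INF, frozenset(), frozenset(), 0, False)
        except _Exhausted:
            return GameOutcome(status=UNPROVED, expansions_used=self.expansions)
        status = self.root_status()
        if status == PROVED:
            try:
                strategy = extract_strategy(self.g, self, root)
            except GraphError:
                # a history-free "proof" on a cyclic graph may not yield a
                # repetition-free strategy; report the search as undecided
                return GameOutcome(status=UNPROVED, expansions_used=self.expansions)
            return GameOutcome(
                status=PROVED, strategy=strategy, expansions_used=self.expansions
            )
        return GameOutcome(status=status, expansions_used=self.expansions)

    def was_expanded(self, v: str) -> bool:
        rec = self.records.get(v)
        return bool(rec and rec.expanded)


def tca_adjust(
    g: AndOrGraph,
    v: str,
    records: dict[str, SearchRecord],
    th_pn: float,
    th_dn: float,
) -> tuple[float, float, bool]:
    """Standalone TCA threshold adjustment at an expanded node.

    If ``v`` has an unproved old child (``md(child) <= md(v)``) the
    thresholds are raised to the minimal values strictly above the current
    ``pn(v)``/``dn(v)``; otherwise they are returned unchanged.
    """
    rec = records[v]
    raised = False
    for c in g.successors(v):
        crec = records.get(c)
        if crec is None or not crec.expanded:
            continue
        if crec.pn != 0.0 and crec.dn != 0.0 and crec.md <= rec.md:
            raised = True
            break
    if raised:
        return max(th_pn, sat_add(rec.pn, 1)), max(th_dn, sat_add(rec.dn, 1)), True
    return th_pn, th_dn, False


def extract_strategy(
    g: AndOrGraph, search: DfpnSearch, root: str
) -> SynthesisRoute:
    """Read the winning strategy off a finished search.

    At each molecule the first proved reaction child (graph child order) is
    chosen; reactions contribute all their reactants.  Raises if the root
    is not proved.
    """
    if search.root_status() != PROVED and root == g.root:
        raise GraphError("extract_strategy called on an unproved root")
    route = SynthesisRoute(root=root)

    def build(v: str, path_mols: frozenset) -> bool:
        role = g.role(v)
        if role == MOLECULE:
            if g.is_building_block(v):
                return True
            if v in path_mols:
                return False  # repetition: this branch of proofs is unusable
            here = path_mols | {v}
            for c in g.successors(v):
                pn, _dn, _dep = search.child_value(c, here)
                if pn == 0.0 and build(c, here):
                    route.children[v] = [c]
                    if (v, c) in g.edge_scores:
                        route.reaction_scores[c] = g.edge_scores[(v, c)]
                    bonds = getattr(g, "reaction_bonds", None)
                    if bonds and c in bonds:
                        route.reaction_bonds[c] = frozenset(bonds[c])
                    return True
            return False
        kids = g.successors(v)
        if not all(build(c, path_mols) for c in kids):
            return False
        route.children[v] = list(kids)
        return True

    if not build(root, frozenset()):
        raise GraphError(
            "stored proofs do not compose into a repetition-free strategy"
        )
    return route


# -- solvers -------------------------------------------------------------------


def dfpn(
    g: AndOrGraph,
    budget: SearchBudget,
    use_tca: bool = True,
    ghi_safe: bool = True,
    trace: Optional[list] = None,
) -> GameOutcome:
    """One-shot DFPN run; see :class:`DfpnSearch` for the engine."""
    search = DfpnSearch(g, use_tca=use_tca, ghi_safe=ghi_safe, trace=trace)
    return search.run(budget)


def pns(g: AndOrGraph, budget: SearchBudget) -> GameOutcome:
    """Best-first proof-number search, restarting from the root each step.

    Correct on acyclic graphs; on cyclic inputs the visit cap bounds the
    run and an undecided search reports ``unproved``.
    """
    records: dict[str, SearchRecord] = {}
    expansions = 0
    visits = 0
    visit_cap = budget.visit_cap(len(g))
    root = g.root

    def ensure(v: str, depth: int) -> SearchRecord:
        rec = records.get(v)
        if rec is None:
            rec = SearchRecord(md=depth)
            term = g.terminal(v)
            if term == BUILDING_BLOCK:
                rec.pn, rec.dn, rec.terminal = 0.0, INF, True
            elif term == DEAD_END or (g.role(v) == MOLECULE and not g.successors(v)):
                rec.pn, rec.dn, rec.terminal = INF, 0.0, True
            records[v] = rec
        return rec

    def recompute(v: str, path_mols: frozenset) -> None:
        rec = records[v]
        if rec.terminal or not rec.expanded:
            return
        kids = g.successors(v)
        if not kids:
            rec.pn, rec.dn, rec.terminal = 0.0, INF, True
            return
        pns_, dns_ = [], []
        for c in kids:
            crec = records[c]
            if g.role(c) == MOLECULE and c in path_mols and not crec.terminal:
                pns_.append(INF)
                dns_.append(0.0)
            else:
                pns_.append(crec.pn)
                dns_.append(crec.dn)
        rec.pn, rec.dn = update_numbers(g.role(v), pns_, dns_)

    ensure(root, 0)
    while True:
        rec = records[root]
        if rec.pn == 0.0:
            strategy = _pns_extract(g, records, root)
            return GameOutcome(PROVED, strategy=strategy, expansions_used=expansions)
        if rec.dn == 0.0:
            return GameOutcome(DISPROVED, expansions_used=expansions)
        if expansions >= budget.max_expansions or visits >= visit_cap:
            return GameOutcome(UNPROVED, expansions_used=expansions)

        # descend to the most promising unexpanded node
        v = root
        path: list[str] = []
        path_mols: frozenset = frozenset()
        stuck = False
        while records[v].expanded and not records[v].terminal:
            visits += 1
            if visits >= visit_cap:
                stuck = True
                break
            role = g.role(v)
            if role == MOLECULE:
                path_mols = path_mols | {v}
            kids = g.successors(v)
            best, best_key = None, None
            for i, c in enumerate(kids):
                crec = records[c]
                if g.role(c) == MOLECULE and c in path_mols and not crec.terminal:
                    pn_c, dn_c = INF, 0.0
                else:
                    pn_c, dn_c = crec.pn, crec.dn
                key = (pn_c, i) if role == MOLECULE else (dn_c, i)
                if best_key is None or key < best_key:
                    best_key, best = key, c
            path.append(v)
            v = best  # type: ignore[assignment]
            if g.role(v) == MOLECULE and v in path_mols:
                stuck = True
                break
        if stuck:
            for node in reversed(path):
                recompute(node, frozenset())
            continue

        rec_v = records[v]
        if not rec_v.terminal:
            rec_v.expanded = True
            expansions += 1
            for c in g.successors(v):
                ensure(c, rec_v.md + 1)
        recompute(v, path_mols)
        for node in reversed(path):
            recompute(node, frozenset())


def _pns_extract(
    g: AndOrGraph, records: dict[str, SearchRecord], root: str
) -> SynthesisRoute:
    route = SynthesisRoute(root=root)

    def build(v: str) -> None:
        if g.role(v) == MOLECULE:
            if g.is_building_block(v):
                return
            for c in g.successors(v):
                if records.get(c) and records[c].pn == 0.0:
                    route.children[v] = [c]
                    build(c)
                    return
            raise GraphError(f"no proved child at {v!r}")
        kids = g.successors(v)
        route.children[v] = list(kids)
        for c in kids:
            build(c)

    build(root)
    return route
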