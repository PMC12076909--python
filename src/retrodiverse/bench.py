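"""Scaled-down benchmark harness comparing DFPN* with the MCTS baseline.

For each target graph, each algorithm and each work budget the harness
records whether the target was solved, how many routes were found, the
diversity score of the set, the mean route length and the mean route
viability.  Budgets are expansion counts for DFPN* and iteration counts
for MCTS — deterministic analogues of the wall-clock budgets a production
deployment would use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .dfpn import SearchBudget
from .diversity import cds
from .graph import AndOrGraph, GraphError, SynthesisRoute
from .mcts import MctsConfig, mcts_search
from .multisolution import PenaltyConfig, find_route_set, route_viability


@dataclass
class BenchResult:
    """Tidy per-target table plus per-algorithm/budget aggregates."""

    per_target: pd.DataFrame
    aggregates: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.per_target.to_csv(path, sep="\t", index=False)


ALGORITHMS = ("dfpn_star", "mcts")

#: Study conditions for the diversity-trend experiment: deep reaction
#: networks with sparse buyables, abundant dead ends, idea-redundant
#: sibling reactions and a few directed cycles — the regime in which a
#: route search has real choices to spend diversity pressure on.
TREND_NETWORK = dict(
    n_molecules=600,
    depth=9,
    planted_routes=2,
    max_reactions_per_molecule=4,
    max_reactants=3,
    buyable_fraction=0.12,
    dead_end_fraction=0.55,
    cycle_fraction=0.1,
)

#: Matched work budget (DFPN* expansions / MCTS iterations) and penalty
#: levels of the trend experiment.
TREND_BUDGET = 4_000
TREND_P_HIGH = 20


def diversity_trend(
    seeds: Sequence[int],
    budget: int = TREND_BUDGET,
    p_high: int = TREND_P_HIGH,
    rollout_depth: int = 80,
    max_solutions: int = 50,
) -> dict[str, float]:
    """Mean route-set diversity of DFPN* (low/high penalty) and MCTS.

    Runs the three configurations on one synthetic network per seed and
    returns the mean diversity score of each; unsolved targets contribute
    0 (they cannot contribute diversity).
    """
    from .synthetic import NetworkSpec, generate_network

    sums = {"dfpn_p0": 0.0, "dfpn_phigh": 0.0, "mcts": 0.0}
    for seed in seeds:
        g, _ = generate_network(NetworkSpec(seed=seed, **TREND_NETWORK))
        budget_obj = SearchBudget(max_expansions=budget, rng_seed=seed)
        low = find_route_set(
            g, PenaltyConfig(p_reac=0, max_solutions=max_solutions), budget_obj
        )
        high = find_route_set(
            g, PenaltyConfig(p_reac=p_high, max_solutions=max_solutions), budget_obj
        )
        sampled = mcts_search(
            g,
            MctsConfig(iterations=budget, rollout_depth=rollout_depth, rng_seed=seed),
        )
        for key, routes in (("dfpn_p0", low), ("dfpn_phigh", high), ("mcts", sampled)):
            sums[key] += cds(routes).score if routes else 0.0
    n = len(seeds)
    return {key: total / n for key, total in sums.items()}


def run_bench(
    graphs: Sequence[AndOrGraph],
    budgets: Sequence[int],
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    penalties: Optional[PenaltyConfig] = None,
    mcts_base: Optional[MctsConfig] = None,
) -> BenchResult:
    """Run every (graph, algorithm, budget) cell and aggregate medians/IQR."""
    if not graphs or not budgets:
        raise ValueError("run_bench needs at least one graph and one budget")
    for algo in algorithms:
        if algo not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algo!r}")
    if penalties is None:
        penalties = PenaltyConfig()
    rows = []
    for t_idx, g in enumerate(graphs):
        for algo in algorithms:
            for budget in budgets:
                routes = _run_one(g, algo, budget, seed, penalties, mcts_base)
                rows.append(_measure(t_idx, algo, budget, routes))
    per_target = pd.DataFrame(rows)
    aggregates = (
        per_target.groupby(["algorithm", "budget"])
        .agg(
            solved_fraction=("solved", "mean"),
            median_cds=("cds", "median"),
            iqr_cds=("cds", lambda s: s.quantile(0.75) - s.quantile(0.25)),
            median_n_routes=("n_routes", "median"),
            median_mean_reactions=("mean_reactions", "median"),
            median_mean_viability=("mean_viability", "median"),
        )
        .reset_index()
    )
    return BenchResult(per_target=per_target, aggregates=aggregates)


def _run_one(
    g: AndOrGraph,
    algo: str,
    budget: int,
    seed: int,
    penalties: PenaltyConfig,
    mcts_base: Optional[MctsConfig],
) -> list[SynthesisRoute]:
    if algo == "dfpn_star":
        return find_route_set(
            g, penalties, SearchBudget(max_expansions=budget, rng_seed=seed)
        )
    base = mcts_base or MctsConfig()
    cfg = MctsConfig(
        exploration_c=base.exploration_c,
        rollout_depth=base.rollout_depth,
        visit_penalty=base.visit_penalty,
        iterations=budget,
        rng_seed=seed,
    )
    return mcts_search(g, cfg)


def _measure(t_idx: int, algo: str, budget: int, routes: list[SynthesisRoute]) -> dict:
    n = len(routes)
    lengths = [r.n_reactions() for r in routes]
    viabilities = []
    for r in routes:
        try:
            viabilities.append(route_viability(r))
        except GraphError:
            pass  # unscored route (e.g. hand-written fixture)
    try:
        score = cds(routes).score if n else 0.0
    except GraphError:
        score = float("nan")  # routes without bond labels cannot be scored
    return {
        "target": t_idx,
        "algorithm": algo,
        "budget": budget,
        "solved": n > 0,
        "n_routes": n,
        "cds": score,
        "mean_reactions": sum(lengths) / n if n else float("nan"),
        "mean_viability": (
            sum(viabilities) / len(viabilities) if viabilities else float("nan")
        ),
    }
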