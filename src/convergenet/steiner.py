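"""Node-weighted Steiner subnetwork construction for a seed gene set.

Given an unweighted PPI network and a set of seed ("terminal") genes, the
goal is a connected subgraph spanning as many seeds as possible while
recruiting as few non-seed ("linker") genes as possible. This is the
node-weighted Steiner tree problem with weight 0 on seeds and 1 on
non-seeds; we solve it with Klein–Ravi-style spider merging, which carries
a 2·ln(k) approximation guarantee on the number of recruited nodes (k =
number of seeds) and is exact on trees.

The heuristic maintains a set of connected components, initially one
singleton per seed. Each round it picks a center node v and r >= 2
components minimizing

    ratio = (# new non-seed nodes on shortest paths from v to one node of
             each chosen component, plus v itself if new and non-seed) / r

and merges them along those paths. Shortest paths are unweighted BFS paths;
among equal-length paths the one recruiting fewest new nodes is taken, and
all remaining ties are broken lexicographically by node symbol (then by
smaller component name), so the construction is fully deterministic.

A merge whose ratio exceeds ``max_merge_cost_per_terminal`` is refused;
since the chosen merge is always the cheapest available, the first refusal
ends the growth phase, and seeds left outside the winning component are
reported as dropped with a reason (``not-in-network``, ``unreachable``, or
``too-costly``). The returned subnetwork is the subgraph induced by the
winning component's nodes.

``exact_steiner_oracle`` provides an exhaustive-search reference for graphs
of at most 15 nodes, used to validate the heuristic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .model import GeneSet, Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "SteinerParams",
    "Subnetwork",
    "steiner_subnetwork",
    "steiner_forest",
    "exact_steiner_oracle",
    "classify_nodes",
]

DROP_REASONS = ("not-in-network", "unreachable", "too-costly")


@dataclass(frozen=True)
class SteinerParams:
    """Tunable knobs of the spider-merge construction.

    ``max_merge_cost_per_terminal`` caps the number of new linker nodes a
    merge may recruit per component it joins (default 2.0); seeds whose
    components can no longer be merged under the cap are dropped as
    too-costly. ``tie_break`` is fixed to lexicographic ordering.
    """

    max_merge_cost_per_terminal: float = 2.0
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if self.max_merge_cost_per_terminal < 0:
            raise ValueError("max_merge_cost_per_terminal must be >= 0")
        if self.tie_break != "lexicographic":
            raise ValueError("only lexicographic tie-breaking is supported")


@dataclass
class Subnetwork:
    """A connected seed subnetwork with node roles.

    ``terminals_included`` are seeds present in the subnetwork;
    ``linkers`` are recruited non-seed nodes; ``terminals_dropped`` maps
    each excluded seed to its reason.
    """

    graph: nx.Graph
    terminals_included: set[str]
    linkers: set[str]
    terminals_dropped: dict[str, str] = field(default_factory=dict)
    name: str = "subnetwork"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0

    def roles(self) -> dict[str, str]:
        roles = {n: "terminal" for n in self.terminals_included}
        roles.update({n: "linker" for n in self.linkers})
        return roles

    def validate(self) -> None:
        nodes = self.nodes
        if nodes and not nx.is_connected(self.graph):
            raise ValueError("subnetwork is not connected")
        if self.terminals_included & self.linkers:
            raise ValueError("terminal and linker sets overlap")
        if self.terminals_included | self.linkers != nodes:
            raise ValueError("terminals + linkers do not cover the subnetwork nodes")
        bad = {r for r in self.terminals_dropped.values()} - set(DROP_REASONS)
        if bad:
            raise ValueError(f"unknown drop reason(s): {sorted(bad)}")


def _component_bfs(adj: dict[str, list[str]], sources: set[str], free: set[str]):
    """Multi-source BFS returning, per node, the cheapest shortest path.

    ``free`` nodes (seeds or already-recruited nodes) cost nothing to
    traverse; every other interior node costs 1. Among hop-shortest paths
    the minimum-cost one is kept; remaining ties prefer the
    lexicographically smallest predecessor. Returns (cost, parent) maps,
    where cost[v] counts chargeable interior nodes on the path from the
    source set to v, excluding v itself.
    """
    cost: dict[str, int] = {s: 0 for s in sources}
    parent: dict[str, str | None] = {s: None for s in sources}
    visited = set(sources)
    frontier = sorted(sources)
    while frontier:
        candidates: dict[str, tuple[int, str]] = {}
        for u in frontier:
            step = cost[u] + (0 if (u in sources or u in free) else 1)
            for w in adj[u]:
                if w in visited:
                    continue
                key = (step, u)
                if w not in candidates or key < candidates[w]:
                    candidates[w] = key
        for w, (c, u) in candidates.items():
            cost[w] = c
            parent[w] = u
            visited.add(w)
        frontier = sorted(candidates)
    return cost, parent


def _trace_path(parent: dict[str, str | None], v: str) -> list[str]:
    """Path from v back to the BFS source set, inclusive of both endpoints."""
    path = [v]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])  # type: ignore[arg-type]
    return path


def _merge_in_component(
    g: nx.Graph, seeds_here: list[str], all_seeds: set[str], cap: float
) -> tuple[list[set[str]], set[str]]:
    """Spider-merge the seeds of one connected graph component.

    Returns the final list of merged components (each a node set) and the
    set of recruited linker nodes across all accepted merges.
    """
    adj = {n: sorted(g.adj[n]) for n in g.nodes}
    comps: dict[str, set[str]] = {s: {s} for s in sorted(seeds_here)}
    included: set[str] = set(seeds_here)
    linkers: set[str] = set()
    free = all_seeds | included  # zero-cost nodes for path purposes

    while len(comps) > 1:
        names = sorted(comps)
        bfs = {name: _component_bfs(adj, comps[name], free) for name in names}

        best: tuple[float, str, int] | None = None  # (ratio, center, r)
        best_order: list[str] = []
        for v in sorted(g.nodes):
            # cost of reaching v from each component, cheapest first
            reach = sorted(
                (bfs[name][0][v], name) for name in names if v in bfs[name][0]
            )
            if len(reach) < 2:
                continue
            v_weight = 0 if (v in free) else 1
            total = v_weight
            for r in range(2, len(reach) + 1):
                total_r = total + sum(c for c, _ in reach[:r])
                ratio = total_r / r
                cand = (ratio, v, r)
                if best is None or cand < best:
                    best = cand
                    best_order = [name for _, name in reach[:r]]
        if best is None:
            break  # components mutually unreachable (cannot happen within one cc)
        ratio, center, _r = best
        if ratio > cap:
            break  # cheapest merge already violates the cap

        # execute: union the chosen components with the connecting paths
        new_nodes: set[str] = {center}
        for name in best_order:
            new_nodes.update(_trace_path(bfs[name][1], center))
        merged = set().union(*(comps[name] for name in best_order)) | new_nodes
        for name in best_order:
            del comps[name]
        # absorb any other component the paths happened to touch
        for name in sorted(comps):
            if comps[name] & merged:
                merged |= comps.pop(name)
        recruited = {n for n in new_nodes if n not in all_seeds and n not in included}
        linkers |= recruited
        included |= merged
        free |= merged
        comps[min(merged)] = merged

    return list(comps.values()), linkers


def steiner_forest(
    net: Interactome, seeds: GeneSet, params: SteinerParams | None = None
) -> list[Subnetwork]:
    """Run spider merging in every graph component holding seeds.

    Returns one subnetwork per final merged component (largest seed count
    first), letting callers keep either the single best tree or the union.
    """
    params = params or SteinerParams()
    if not seeds.genes:
        raise ValueError("empty seed set")
    g = net.graph
    present = {s for s in seeds.genes if s in g}
    absent = {s: "not-in-network" for s in sorted(seeds.genes - present)}
    if not present:
        empty = Subnetwork(graph=nx.Graph(), terminals_included=set(), linkers=set(),
                           terminals_dropped=dict(absent), name=seeds.name)
        return [empty]

    all_seeds = set(seeds.genes)
    cap = params.max_merge_cost_per_terminal
    pieces: list[tuple[set[str], set[str]]] = []  # (component nodes, linkers therein)
    for cc in nx.connected_components(g):
        seeds_here = sorted(present & cc)
        if not seeds_here:
            continue
        sub = g.subgraph(cc)
        comps, linkers = _merge_in_component(sub, seeds_here, all_seeds, cap)
        for comp in comps:
            pieces.append((comp, linkers & comp))

    # order: most seeds, then lexicographically smallest node set
    pieces.sort(key=lambda p: (-len(p[0] & all_seeds), sorted(p[0])))
    results: list[Subnetwork] = []
    winner_nodes = pieces[0][0]
    for comp, comp_linkers in pieces:
        dropped = dict(absent)
        for s in sorted(present - comp):
            if nx.has_path(g, s, next(iter(comp))):
                dropped[s] = "too-costly"
            else:
                dropped[s] = "unreachable"
        sub = Subnetwork(
            graph=nx.Graph(g.subgraph(comp)),
            terminals_included=comp & all_seeds,
            linkers=set(comp_linkers),
            terminals_dropped=dropped,
            name=seeds.name,
        )
        results.append(sub)
    logger.info(
        "steiner(%s): winning component has %d seeds + %d linkers; %d seeds dropped",
        seeds.name, len(winner_nodes & all_seeds), len(pieces[0][1]),
        len(results[0].terminals_dropped),
    )
    return results


def steiner_subnetwork(
    net: Interactome, seeds: GeneSet, params: SteinerParams | None = None
) -> Subnetwork:
    """Return the best single-component Steiner subnetwork for the seeds.

    The winning component is the one containing the most seeds (ties:
    lexicographically smallest node set). If no seed is present in the
    network an empty subnetwork is returned with every seed dropped.
    """
    return steiner_forest(net, seeds, params)[0]


def exact_steiner_oracle(net: Interactome, seeds: GeneSet) -> Subnetwork:
    """Exhaustive minimum-linker Steiner subnetwork for tiny graphs (<= 15 nodes).

    Searches subsets of non-seed nodes in order of size, then
    lexicographically, returning the first whose union with the seeds
    induces a connected subgraph; this is the optimum with deterministic
    tie-breaking. Raises if the seeds are not mutually reachable.
    """
    g = net.graph
    if g.number_of_nodes() > 15:
        raise ValueError("exact oracle is limited to 15 nodes")
    seed_nodes = set(seeds.genes)
    missing = seed_nodes - set(g.nodes)
    if missing:
        raise ValueError(f"unreachable terminals: {sorted(missing)} not in network")
    comp = nx.node_connected_component(g, min(seed_nodes))
    if not seed_nodes <= comp:
        raise ValueError("unreachable terminals: seeds span multiple components")
    non_seeds = sorted(set(g.nodes) - seed_nodes)
    for size in range(len(non_seeds) + 1):
        for subset in itertools.combinations(non_seeds, size):
            cand = seed_nodes | set(subset)
            sub = g.subgraph(cand)
            if nx.is_connected(sub):
                return Subnetwork(
                    graph=nx.Graph(sub),
                    terminals_included=set(seed_nodes),
                    linkers=set(subset),
                    terminals_dropped={},
                    name=f"{seeds.name}-exact",
                )
    raise AssertionError("unreachable: full node set must connect the seeds")


def classify_nodes(subnet: Subnetwork, seeds: GeneSet):
    """Tabulate node roles and summary counts for a constructed subnetwork."""
    import pandas as pd

    roles = subnet.roles()
    table = pd.DataFrame(
        {"node": sorted(roles), "role": [roles[n] for n in sorted(roles)]}
    )
    by_reason = {r: 0 for r in DROP_REASONS}
    for reason in subnet.terminals_dropped.values():
        by_reason[reason] += 1
    summary = {
        "n_terminals": len(subnet.terminals_included),
        "n_linkers": len(subnet.linkers),
        "n_dropped": len(subnet.terminals_dropped),
        "n_dropped_by_reason": by_reason,
    }
    return table, summary


def klein_ravi_bound(k: int, opt_linkers: int) -> float:
    """Approximation guarantee 2·ln(k)·OPT on the recruited-node count."""
    if k < 2 or opt_linkers == 0:
        return float(opt_linkers)
    return 2.0 * math.log(k) * opt_linkers
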