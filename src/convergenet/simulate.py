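"""Synthetic study generator with planted, recoverable structure.

Real inputs to the convergent analysis — a curated PPI interactome, two
disease seed-gene lists, a normalized case/control expression matrix, and
a canonical-pathway collection — cannot be redistributed or re-downloaded
reproducibly, so this module generates stand-ins that carry the exact
statistical structure the pipeline is meant to exploit, together with a
:class:`SyntheticTruth` record of what was planted:

* a connected scale-free interactome (~5 edges per node, mirroring the
  shape of curated human PPI exports) at desk scale (1000 nodes);
* two seed lists drawn from two network neighborhoods, sharing a small
  overlap core (5 genes, mirroring the real seed lists' intersection) and
  joined through planted *bridge* genes: non-seed nodes that are the sole
  cheap connector between designated seed pairs of both modules, so a
  correct Steiner construction must recruit them into both subnetworks;
* an expression matrix on a log-like intensity scale (baseline Normal(8,1))
  for 7 cases vs 8 controls with a fraction of genes shifted in cases, and
  a second, dimmer probe for 10% of genes to exercise probe collapse;
* a pathway collection with planted overlap clusters (pathways within a
  cluster share a gene core; different clusters share nothing).

All generators are deterministic given ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GeneSet, Interactome, PathwayCollection

__all__ = [
    "SyntheticTruth",
    "SimulatedStudy",
    "gen_interactome",
    "gen_seed_sets",
    "gen_expression",
    "gen_pathways",
    "default_study",
    "validate_truth",
]


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery checks."""

    planted_bridges: set[str] = field(default_factory=set)
    planted_overlap: set[str] = field(default_factory=set)
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_pathway_clusters: dict[str, str] = field(default_factory=dict)
    rng_seed: int = 0

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            planted_bridges=self.planted_bridges | other.planted_bridges,
            planted_overlap=self.planted_overlap | other.planted_overlap,
            planted_de={**self.planted_de, **other.planted_de},
            planted_pathway_clusters={**self.planted_pathway_clusters,
                                      **other.planted_pathway_clusters},
            rng_seed=self.rng_seed,
        )

    def to_json(self, path) -> None:
        payload = {
            "planted_bridges": sorted(self.planted_bridges),
            "planted_overlap": sorted(self.planted_overlap),
            "planted_de": {k: self.planted_de[k] for k in sorted(self.planted_de)},
            "planted_pathway_clusters": {
                k: self.planted_pathway_clusters[k]
                for k in sorted(self.planted_pathway_clusters)
            },
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_bridges=set(d["planted_bridges"]),
            planted_overlap=set(d["planted_overlap"]),
            planted_de=dict(d["planted_de"]),
            planted_pathway_clusters=dict(d["planted_pathway_clusters"]),
            rng_seed=int(d["rng_seed"]),
        )


def _symbol(i: int) -> str:
    return f"G{i:04d}"


def gen_interactome(
    n_nodes: int,
    model: str = "scale-free",
    mean_degree: float = 10.0,
    rng_seed: int = 0,
) -> Interactome:
    """Generate a connected simple interactome of gene symbols.

    ``scale-free`` uses preferential attachment (heavy-tailed degrees);
    ``erdos-renyi`` a G(n, p) with matching expected degree. Only the
    largest connected component is kept, relabeled G0000, G0001, ...
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    if model == "scale-free":
        if not 0 < mean_degree < n_nodes:
            raise ValueError(f"infeasible mean_degree {mean_degree} for n={n_nodes}")
        # Chung-Lu graph with Pareto expected degrees (power-law exponent
        # ~2.05, structural cutoff at sqrt(n*mean)): reproduces the shape of
        # curated PPI exports — many degree-1..3 proteins, a few large hubs.
        rng = np.random.default_rng(rng_seed)
        w = rng.pareto(1.05, size=n_nodes) + 1.0
        w = np.minimum(w, np.sqrt(n_nodes * mean_degree))
        # the 1.06 factor offsets edges lost to the cutoff, collapsed
        # duplicates and pruning to the giant component
        w = w * (1.06 * mean_degree / w.mean())
        g = nx.expected_degree_graph(w.tolist(), seed=int(rng_seed), selfloops=False)
    elif model == "erdos-renyi":
        p = mean_degree / max(n_nodes - 1, 1)
        if not 0 < p <= 1:
            raise ValueError(f"infeasible mean_degree {mean_degree} for n={n_nodes}")
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng_seed))
    else:
        raise ValueError(f"unknown model: {model!r}")
    largest = max(nx.connected_components(g), key=len)
    if len(largest) < 2:
        raise ValueError("generated graph has no non-trivial connected component")
    g = g.subgraph(largest)
    mapping = {old: _symbol(i) for i, old in enumerate(sorted(g.nodes))}
    relabeled = nx.relabel_nodes(nx.Graph(g), mapping)
    return Interactome(graph=relabeled, name=f"synthetic-{model}")


def _bfs_ball(g: nx.Graph, anchor: str, size: int) -> list[str]:
    """The `size` nodes closest to `anchor` (BFS layers, symbols sorted)."""
    order = [anchor]
    seen = {anchor}
    frontier = [anchor]
    while frontier and len(order) < size:
        nxt = sorted({w for u in frontier for w in g.adj[u]} - seen)
        seen.update(nxt)
        order.extend(nxt)
        frontier = nxt
    return order[:size]


def _hanging_sides(g: nx.Graph) -> dict[str, list[str]]:
    """Articulation points that cut >= 2 nodes off the main component.

    For each such point b the returned list holds the nodes separated from
    the bulk of the graph when b is removed: every path from those nodes to
    anywhere else runs through b.
    """
    out: dict[str, list[str]] = {}
    for b in nx.articulation_points(g):
        h = g.copy()
        h.remove_node(b)
        comps = sorted(nx.connected_components(h), key=len)
        if len(comps) < 2:
            continue
        hang = set().union(*comps[:-1])
        if len(hang) >= 2:
            out[b] = sorted(hang)
    return out


def gen_seed_sets(
    net: Interactome,
    n_seeds_a: int = 40,
    n_seeds_b: int = 20,
    n_bridges: int = 5,
    n_overlap: int = 5,
    rng_seed: int = 0,
) -> tuple[GeneSet, GeneSet, SyntheticTruth]:
    """Plant two seed modules with a shared core and forced bridge linkers.

    Seeds A and B are sampled from two network neighborhoods; ``n_overlap``
    genes go into both lists. Bridges are cut vertices of the interactome
    made unavoidable by seed placement, in one of two ways: (a) a cut
    vertex with at least two nodes hanging off it — one hanging node
    becomes an A-seed and another a B-seed; or, where such structures run
    out, (b) the host of a degree-1 pendant node, with the pendant made
    one of the ``n_overlap`` shared seeds. In both cases every path from
    the planted seed(s) to the rest of either module runs through the
    bridge, so both Steiner constructions are forced to recruit it.
    """
    g = net.graph
    if n_overlap + n_bridges > min(n_seeds_a, n_seeds_b):
        raise ValueError("overlap and bridge anchors exceed the seed budget")
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(g.nodes)

    bridges: list[str] = []
    anchors_a: list[str] = []
    anchors_b: list[str] = []
    pendant_overlap: list[str] = []  # shared seeds that force their host
    reserved: set[str] = set()  # bridges, anchors and whole hanging sides
    attempts = 0

    # (a) cut vertices with >= 2 hanging nodes: one anchor per seed list
    hosts = _hanging_sides(g) if n_bridges else {}
    for idx in rng.permutation(len(hosts)) if hosts else []:
        if len(bridges) == n_bridges:
            break
        attempts += 1
        b = sorted(hosts)[idx]
        if b in reserved:
            continue
        hang = [v for v in hosts[b] if v not in reserved]
        if len(hang) < 2:
            continue
        # hanging nodes adjacent to the bridge give the cheapest forced path
        hang.sort(key=lambda v: (0 if g.has_edge(b, v) else 1, v))
        anchors_a.append(hang[0])
        anchors_b.append(hang[1])
        bridges.append(b)
        reserved.update(hosts[b])
        reserved.add(b)

    # (b) pendant hosts: the pendant joins both seed lists (an overlap slot)
    if len(bridges) < n_bridges:
        pend = {}
        for v in nodes:
            if g.degree(v) == 1:
                pend.setdefault(next(iter(g.adj[v])), []).append(v)
        cand = sorted(pend)
        for idx in rng.permutation(len(cand)) if cand else []:
            if len(bridges) == n_bridges or len(pendant_overlap) == n_overlap:
                break
            attempts += 1
            if attempts > 100 * max(n_bridges, 1):
                break
            b = cand[idx]
            if b in reserved:
                continue
            leaves = [v for v in sorted(pend[b]) if v not in reserved]
            if not leaves:
                continue
            bridges.append(b)
            pendant_overlap.append(leaves[0])
            reserved.add(leaves[0])
            reserved.add(b)
    if len(bridges) < n_bridges:
        raise ValueError(
            f"could not place {n_bridges} bridges after {attempts} attempts "
            f"(placed {len(bridges)}); try a larger network or fewer bridges"
        )

    # two module neighborhoods
    anchor_a = nodes[int(rng.integers(len(nodes)))]
    dist = nx.single_source_shortest_path_length(g, anchor_a)
    anchor_b = max(nodes, key=lambda n: (dist.get(n, -1), n))
    region_a = _bfs_ball(g, anchor_a, max(6 * n_seeds_a, 120))
    region_b = _bfs_ball(g, anchor_b, max(6 * n_seeds_b, 120))

    blocked = set(reserved)
    n_extra = n_overlap - len(pendant_overlap)
    overlap_pool = sorted((set(region_a) | set(region_b)) - blocked)
    if len(overlap_pool) < n_extra:
        overlap_pool = sorted(set(nodes) - blocked)
    overlap = pendant_overlap + [
        overlap_pool[i]
        for i in rng.choice(len(overlap_pool), size=n_extra, replace=False)
    ]
    blocked |= set(overlap)

    def fill(region: list[str], need: int, taken: set[str]) -> list[str]:
        pool = [n for n in region if n not in blocked and n not in taken]
        if len(pool) < need:
            pool += [n for n in nodes if n not in blocked and n not in taken
                     and n not in pool]
        picks = rng.choice(len(pool), size=need, replace=False)
        return [pool[i] for i in sorted(picks)]

    seeds_a = set(anchors_a) | set(overlap)
    seeds_a |= set(fill(region_a, n_seeds_a - len(seeds_a), seeds_a))
    seeds_b = set(anchors_b) | set(overlap)
    seeds_b |= set(fill(region_b, n_seeds_b - len(seeds_b), seeds_b | seeds_a))

    truth = SyntheticTruth(planted_bridges=set(bridges),
                           planted_overlap=set(overlap), rng_seed=rng_seed)
    return (
        GeneSet.from_iterable("seeds_a", seeds_a),
        GeneSet.from_iterable("seeds_b", seeds_b),
        truth,
    )


def gen_expression(
    genes: list[str],
    n_case: int = 7,
    n_control: int = 8,
    de_fraction: float = 0.05,
    effect_sd: float = 2.0,
    rng_seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Normalized-intensity matrix with planted differential expression.

    Baseline intensities are Normal(8, 1) per cell; planted DE genes are
    shifted by ``effect_sd`` standard deviations in cases. Ten percent of
    genes get a second probe with a dimmer baseline (mean 6), so max-mean
    probe collapse has real work to do.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    genes = sorted(dict.fromkeys(genes))
    rng = np.random.default_rng(rng_seed)
    n_genes = len(genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = set(rng.choice(n_genes, size=n_de, replace=False).tolist())
    dup_idx = set(rng.choice(n_genes, size=n_genes // 10, replace=False).tolist())

    samples = [f"CASE{i + 1:02d}" for i in range(n_case)] + \
              [f"CTRL{i + 1:02d}" for i in range(n_control)]
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    case_mask = np.array([groups[s] == "case" for s in samples], dtype=float)

    probes, probe_to_gene, rows = [], {}, []
    for i, gene in enumerate(genes):
        shift = effect_sd * case_mask if i in de_idx else 0.0
        main = 8.0 + shift + rng.normal(0.0, 1.0, size=len(samples))
        probes.append(f"{gene}_PA")
        probe_to_gene[f"{gene}_PA"] = gene
        rows.append(main)
        if i in dup_idx:
            dim = 6.0 + shift + rng.normal(0.0, 1.0, size=len(samples))
            probes.append(f"{gene}_PB")
            probe_to_gene[f"{gene}_PB"] = gene
            rows.append(dim)
    values = pd.DataFrame(np.asarray(rows), index=probes, columns=samples)
    truth = SyntheticTruth(
        planted_de={genes[i]: effect_sd for i in sorted(de_idx)}, rng_seed=rng_seed
    )
    return ExpressionMatrix(values, groups, probe_to_gene), truth


def gen_pathways(
    genes: list[str],
    n_pathways: int = 20,
    cluster_spec: tuple[tuple[int, int], ...] = ((3, 4), (3, 4)),
    pathway_size: int = 20,
    rng_seed: int = 0,
    focus_sets: list[GeneSet] | None = None,
) -> tuple[PathwayCollection, SyntheticTruth]:
    """Pathway collection with planted overlap clusters.

    Each ``(cluster_size, shared_core_size)`` entry makes ``cluster_size``
    pathways sharing a common gene core; gene pools are disjoint otherwise,
    so cross-cluster sharing is zero by construction. When ``focus_sets``
    aligns a gene set with each cluster, that cluster's pathways draw their
    cores and members preferentially from it — this is how the preset makes
    the planted clusters enrichable by the seed subnetworks.
    """
    genes = sorted(dict.fromkeys(genes))
    n_cluster_pw = sum(c for c, _ in cluster_spec)
    if n_cluster_pw > n_pathways:
        raise ValueError("cluster_spec lists more pathways than n_pathways")
    for c, core in cluster_spec:
        if core > pathway_size:
            raise ValueError("shared core larger than pathway_size")
    needed = sum(core + c * (pathway_size - core) for c, core in cluster_spec)
    needed += (n_pathways - n_cluster_pw) * pathway_size
    if needed > len(genes):
        raise ValueError(f"need {needed} genes for disjoint pools, have {len(genes)}")
    if focus_sets is not None and len(focus_sets) != len(cluster_spec):
        raise ValueError("focus_sets must align with cluster_spec")

    rng = np.random.default_rng(rng_seed)
    available = [genes[i] for i in rng.permutation(len(genes))]

    def take(n: int, prefer: list[str] | None = None) -> list[str]:
        out: list[str] = []
        if prefer:
            for gsym in prefer:
                if len(out) == n:
                    break
                if gsym in avail_set:
                    out.append(gsym)
                    avail_set.discard(gsym)
        while len(out) < n:
            gsym = available.pop()
            if gsym in avail_set:
                out.append(gsym)
                avail_set.discard(gsym)
        return out

    avail_set = set(available)
    pathways: list[GeneSet] = []
    clusters: dict[str, str] = {}
    pw_i = 0
    for ci, (csize, core_size) in enumerate(cluster_spec, start=1):
        prefer = None
        if focus_sets is not None:
            focus = sorted(focus_sets[ci - 1].genes)
            prefer = [focus[i] for i in rng.permutation(len(focus))]
        core = take(core_size, prefer)
        # spread remaining preferred genes evenly across the cluster's pathways
        leftover = [g for g in (prefer or []) if g in avail_set]
        chunks = [leftover[j::csize] for j in range(csize)]
        for j in range(csize):
            pw_i += 1
            name = f"PW{pw_i:02d}_C{ci}"
            members = core + take(pathway_size - core_size, chunks[j])
            pathways.append(GeneSet.from_iterable(name, members))
            clusters[name] = f"cluster{ci}"
    for _ in range(n_pathways - n_cluster_pw):
        pw_i += 1
        name = f"PW{pw_i:02d}_BG"
        pathways.append(GeneSet.from_iterable(name, take(pathway_size)))
        clusters[name] = "background"

    collection = PathwayCollection(
        pathways=pathways, source="synthetic",
        descriptions={p.name: clusters[p.name] for p in pathways},
    )
    truth = SyntheticTruth(planted_pathway_clusters=clusters, rng_seed=rng_seed)
    return collection, truth


@dataclass
class SimulatedStudy:
    """One complete synthetic study: every input the pipeline consumes."""

    net: Interactome
    seeds_a: GeneSet
    seeds_b: GeneSet
    expression: ExpressionMatrix
    pathways: PathwayCollection
    truth: SyntheticTruth

    def write_dir(self, outdir) -> dict[str, Path]:
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ppi": outdir / "ppi.tsv",
            "seeds_a": outdir / "seeds_a.txt",
            "seeds_b": outdir / "seeds_b.txt",
            "expr": outdir / "expr.tsv",
            "groups": outdir / "groups.tsv",
            "probe_map": outdir / "probe_map.tsv",
            "gmt": outdir / "pathways.gmt",
            "truth": outdir / "truth.json",
        }
        cio.write_interactome(self.net, paths["ppi"])
        cio.write_gene_set(self.seeds_a, paths["seeds_a"])
        cio.write_gene_set(self.seeds_b, paths["seeds_b"])
        cio.write_expression(self.expression, paths["expr"], paths["groups"],
                             paths["probe_map"])
        cio.write_gmt(self.pathways, paths["gmt"])
        self.truth.to_json(paths["truth"])
        return paths


def derive_seeds(seed: int, n: int) -> list[int]:
    """n independent sub-seeds (< 2**31) derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def default_study(
    rng_seed: int = 42,
    n_nodes: int = 1000,
    mean_degree: float = 10.0,
    n_seeds_a: int = 40,
    n_seeds_b: int = 20,
    n_bridges: int = 5,
    n_overlap: int = 5,
    de_fraction: float = 0.05,
    effect_sd: float = 2.0,
    n_pathways: int = 20,
    cluster_spec: tuple[tuple[int, int], ...] = ((3, 4), (3, 4)),
    pathway_size: int = 20,
) -> SimulatedStudy:
    """The default study conditions: a desk-scale analogue of the real inputs.

    1000-node scale-free interactome with ~5 edges per node; 40- and 20-gene
    seed lists (roughly one tenth of the real 373/165) sharing a 5-gene
    overlap; 5 planted bridges; a 7-vs-8 expression design with 5% of genes
    shifted by 2 SD; 20 pathways of 20 genes with two planted 3-pathway
    clusters sharing 4-gene cores.
    """
    s_net, s_seeds, s_expr, s_pw = derive_seeds(rng_seed, 4)
    net = gen_interactome(n_nodes, "scale-free", mean_degree, s_net)
    seeds_a, seeds_b, t_seeds = gen_seed_sets(
        net, n_seeds_a, n_seeds_b, n_bridges, n_overlap, s_seeds
    )
    expr, t_expr = gen_expression(sorted(net.nodes), 7, 8, de_fraction,
                                  effect_sd, s_expr)
    pathways, t_pw = gen_pathways(sorted(net.nodes), n_pathways, cluster_spec,
                                  pathway_size, s_pw, focus_sets=[seeds_a, seeds_b])
    truth = t_seeds.merge(t_expr).merge(t_pw)
    truth.rng_seed = rng_seed
    return SimulatedStudy(net=net, seeds_a=seeds_a, seeds_b=seeds_b,
                          expression=expr, pathways=pathways, truth=truth)


def validate_truth(study: SimulatedStudy) -> None:
    """Check that every planted symbol exists in its generated artifact."""
    t = study.truth
    nodes = study.net.nodes
    problems = []
    if not t.planted_bridges <= nodes:
        problems.append("bridges missing from interactome")
    if not t.planted_overlap <= (study.seeds_a.genes & study.seeds_b.genes):
        problems.append("overlap genes missing from a seed list")
    expr_genes = {study.expression.probe_to_gene[p]
                  for p in study.expression.probe_to_gene or {}}
    if not set(t.planted_de) <= expr_genes:
        problems.append("planted DE genes missing from expression matrix")
    if not set(t.planted_pathway_clusters) <= set(study.pathways.names):
        problems.append("planted cluster labels name unknown pathways")
    if problems:
        raise AssertionError("; ".join(problems))
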