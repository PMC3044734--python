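"""Pathway over-representation and the pathway-crosstalk functional map.

Enrichment of a query gene set (typically the genes of one Steiner
subnetwork) against a pathway collection uses the one-sided hypergeometric
(Fisher's exact) upper tail, with significance defined by two thresholds:
p < p_cutoff (default 0.01) and at least min_hits (default 5) query genes
in the pathway.

Crosstalk between two pathways A and B is scored by the mean of the
Jaccard coefficient JC = |A∩B| / |A∪B| and the overlap coefficient
OC = |A∩B| / min(|A|, |B|). Pairs of significant pathways sharing at
least ``min_shared`` genes (default 3) become candidate edges; within
each enrichment result only the top-scoring fraction of edges is kept
(ties at the threshold retained), the two filtered graphs are unioned,
and the connected components of the union are the "functional groups".

By default overlaps are computed on each pathway's *hit genes* (the query
genes it contains); ``use_full_sets=True`` scores full pathway memberships
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model import GeneSet, PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_enrich",
    "crosstalk_score",
    "build_crosstalk_graph",
    "functional_groups",
    "EnrichmentResult",
    "CrosstalkGraph",
]


@dataclass
class EnrichmentResult:
    """Per-pathway over-representation results for one query gene set.

    ``table`` columns: pathway, n_hits, pathway_size, p, significant.
    ``hit_genes`` maps pathway name -> the query genes it contains.
    """

    table: pd.DataFrame
    hit_genes: dict[str, frozenset[str]]
    query_name: str
    background_size: int
    query_size: int
    min_hits: int
    p_cutoff: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "pathway"])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["hit_genes"] = [
            ",".join(sorted(self.hit_genes[p])) for p in out["pathway"]
        ]
        out["significant"] = out["significant"].map({True: "Y", False: "N"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def fisher_enrich(
    query: GeneSet,
    collection: PathwayCollection,
    background: GeneSet,
    min_hits: int = 5,
    p_cutoff: float = 0.01,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test per pathway.

    With N = |background|, K = |pathway ∩ background|, n = |query| and
    k = |query ∩ pathway|, the p-value is the upper tail P(X >= k) of the
    hypergeometric distribution. Query genes outside the background are
    dropped with a warning; pathway memberships are likewise intersected
    with the background.
    """
    if len(collection) == 0:
        raise ValueError("empty pathway collection")
    if len(query) > len(background):
        raise ValueError("background is smaller than the query gene set")
    bg = set(background.genes)
    q = set(query.genes) & bg
    n_outside = len(query) - len(q)
    if n_outside:
        logger.warning("fisher_enrich: %d query genes outside the background dropped",
                       n_outside)
    if not q:
        raise ValueError("no query gene lies in the background")

    N, n = len(bg), len(q)
    rows, hits = [], {}
    for pw in collection:
        members = pw.genes & bg
        hit = frozenset(q & members)
        K, k = len(members), len(hit)
        # upper tail P(X >= k); k = 0 gives p = 1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        hits[pw.name] = hit
        rows.append({
            "pathway": pw.name,
            "n_hits": k,
            "pathway_size": K,
            "p": p,
            "significant": bool(p < p_cutoff and k >= min_hits),
        })
    table = pd.DataFrame(rows).sort_values(["p", "pathway"], kind="mergesort")
    table = table.reset_index(drop=True)
    logger.info("fisher_enrich(%s): %d/%d pathways significant (p<%g, hits>=%d)",
                query.name, int(table["significant"].sum()), len(table), p_cutoff, min_hits)
    return EnrichmentResult(
        table=table, hit_genes=hits, query_name=query.name,
        background_size=N, query_size=n, min_hits=min_hits, p_cutoff=p_cutoff,
    )


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int):
    """Exact upper-tail hypergeometric probability by direct rational summation.

    Independent reference for :func:`fisher_enrich` (exact arithmetic via
    integer binomials); returns a :class:`fractions.Fraction`.
    """
    from fractions import Fraction
    from math import comb

    total = comb(N, n)
    s = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, 0), min(K, n) + 1))
    return Fraction(s, total)


def crosstalk_score(a: GeneSet | frozenset, b: GeneSet | frozenset):
    """Jaccard coefficient, overlap coefficient and their mean for two gene sets."""
    sa = set(a.genes) if isinstance(a, GeneSet) else set(a)
    sb = set(b.genes) if isinstance(b, GeneSet) else set(b)
    if not sa or not sb:
        raise ValueError("crosstalk_score requires non-empty gene sets")
    inter = len(sa & sb)
    jc = inter / len(sa | sb)
    oc = inter / min(len(sa), len(sb))
    return jc, oc, (jc + oc) / 2.0


@dataclass
class CrosstalkGraph:
    """Filtered union of the two per-result crosstalk graphs.

    Nodes are significant pathways (attributes: membership in
    {setA, setB, both}; n_interesting = hit-gene count); edges carry
    n_shared, jc, oc and score; ``groups`` are the connected components
    with >= 2 nodes, largest first.
    """

    graph: nx.Graph
    groups: list[list[str]] = field(default_factory=list)

    @property
    def isolated(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.degree(n) == 0)

    def groups_table(self) -> pd.DataFrame:
        rows = []
        for i, grp in enumerate(self.groups, start=1):
            for pw in grp:
                rows.append({
                    "group": i,
                    "pathway": pw,
                    "membership": self.graph.nodes[pw]["membership"],
                })
        for pw in self.isolated:
            rows.append({"group": 0, "pathway": pw,
                         "membership": self.graph.nodes[pw]["membership"]})
        return pd.DataFrame(rows, columns=["group", "pathway", "membership"])

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for n in sorted(self.graph.nodes):
            g.add_node(n, **self.graph.nodes[n])
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            g.add_edge(u, v, **self.graph.edges[u, v])
        nx.write_graphml(g, path, named_key_ids=True)


def _edges_for_result(
    enrich: EnrichmentResult,
    collection: PathwayCollection | None,
    min_shared: int,
    top_fraction: float,
    use_full_sets: bool,
) -> list[tuple[str, str, dict]]:
    """Score all qualifying pathway pairs of one result, keep the top fraction."""
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if use_full_sets and collection is None:
        raise ValueError("use_full_sets requires the pathway collection")
    sig = enrich.significant
    gene_sets: dict[str, frozenset[str]] = {}
    for pw in sig:
        gene_sets[pw] = (collection[pw].genes if use_full_sets
                         else enrich.hit_genes[pw])
    edges = []
    for i, a in enumerate(sorted(sig)):
        for b in sorted(sig)[i + 1:]:
            shared = gene_sets[a] & gene_sets[b]
            if len(shared) < min_shared:
                continue
            jc, oc, score = crosstalk_score(gene_sets[a], gene_sets[b])
            edges.append((a, b, {"n_shared": len(shared), "jc": jc, "oc": oc,
                                 "score": score}))
    if not edges:
        return []
    scores = np.array([e[2]["score"] for e in edges])
    threshold = float(np.quantile(scores, 1.0 - top_fraction))
    kept = [e for e in edges if e[2]["score"] >= threshold]  # ties kept
    return kept


def build_crosstalk_graph(
    enrich_a: EnrichmentResult,
    enrich_b: EnrichmentResult,
    min_shared: int = 3,
    top_fraction_a: float = 0.01,
    top_fraction_b: float = 0.05,
    collection: PathwayCollection | None = None,
    use_full_sets: bool = False,
) -> CrosstalkGraph:
    """Union of the two top-filtered crosstalk graphs, with functional groups.

    Each enrichment result contributes its significant pathways as nodes
    and its top-scoring qualifying pairs as edges; the per-result top
    fractions mirror the asymmetric 1% / 5% filtering used when one
    pathway set is much larger than the other. A pathway significant in
    both results gets membership "both"; an edge present in both keeps the
    attributes of the higher-scoring copy.
    """
    sig_a, sig_b = set(enrich_a.significant), set(enrich_b.significant)
    g = nx.Graph()
    for pw in sorted(sig_a | sig_b):
        membership = "both" if pw in sig_a & sig_b else ("setA" if pw in sig_a else "setB")
        n_int = len(enrich_a.hit_genes.get(pw, frozenset()) |
                    enrich_b.hit_genes.get(pw, frozenset()))
        g.add_node(pw, membership=membership, n_interesting=n_int)
    for enrich, frac, tag in ((enrich_a, top_fraction_a, "setA"),
                              (enrich_b, top_fraction_b, "setB")):
        for u, v, attrs in _edges_for_result(enrich, collection, min_shared,
                                             frac, use_full_sets):
            if g.has_edge(u, v):
                if attrs["score"] > g.edges[u, v]["score"]:
                    g.edges[u, v].update(attrs)
                g.edges[u, v]["source"] = "both"
            else:
                g.add_edge(u, v, **attrs, source=tag)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c))
    logger.info("crosstalk: %d pathways, %d edges, %d functional groups",
                g.number_of_nodes(), g.number_of_edges(), len(comps))
    return CrosstalkGraph(graph=g, groups=comps)


def functional_groups(graph: CrosstalkGraph) -> pd.DataFrame:
    """Connected components with >= 2 pathways; isolated nodes get group 0."""
    return graph.groups_table()
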