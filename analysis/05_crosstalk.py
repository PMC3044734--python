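#!/usr/bin/env python
"""Pathway enrichment of both subnetworks and the crosstalk functional map.

Tests each subnetwork's genes for pathway over-representation
(hypergeometric, p < 0.01 and >= 5 genes), scores gene-set overlap between
significant pathways (mean of Jaccard and overlap coefficients, >= 3
shared genes), keeps each side's top-scoring connections, and reports the
connected components of the union — the functional groups.
"""

import argparse
from pathlib import Path

from convergenet import build_crosstalk_graph, fisher_enrich, functional_groups
from convergenet import io as cio
from convergenet.model import GeneSet


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--top-a", type=float, default=0.01)
    parser.add_argument("--top-b", type=float, default=0.05)
    args = parser.parse_args()

    net = cio.read_interactome(args.simdir / "ppi.tsv")
    collection = cio.read_gmt(args.simdir / "pathways.gmt")
    background = GeneSet.from_iterable("interactome", net.nodes)

    enrich = {}
    for tag in ("a", "b"):
        sub = cio.read_subnetwork_graphml(args.outdir / f"subnet_{tag}.graphml")
        query = GeneSet.from_iterable(f"subnet_{tag}", sub.nodes)
        res = fisher_enrich(query, collection, background)
        res.write_tsv(args.outdir / f"enrich_{tag}.tsv")
        enrich[tag] = res
        print(f"subnetwork {tag.upper()}: {len(res.significant)} of "
              f"{len(res.table)} pathways significant "
              f"(p < {res.p_cutoff:g}, >= {res.min_hits} genes)")

    graph = build_crosstalk_graph(enrich["a"], enrich["b"],
                                  top_fraction_a=args.top_a,
                                  top_fraction_b=args.top_b,
                                  collection=collection)
    graph.write_graphml(args.outdir / "crosstalk.graphml")
    table = functional_groups(graph)
    table.to_csv(args.outdir / "groups.tsv", sep="\t", index=False)

    print(f"crosstalk map: {graph.graph.number_of_nodes()} pathways, "
          f"{graph.graph.number_of_edges()} connections")
    for i, grp in enumerate(graph.groups, start=1):
        members = {graph.graph.nodes[p]["membership"] for p in grp}
        print(f"  functional group {i}: {len(grp)} pathways "
              f"({'/'.join(sorted(members))}): {', '.join(grp)}")
    if graph.isolated:
        print(f"  isolated pathways: {', '.join(graph.isolated)}")


if __name__ == "__main__":
    main()
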