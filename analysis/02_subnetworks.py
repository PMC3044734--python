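#!/usr/bin/env python
"""Build the Steiner subnetwork for each seed list.

Reads the simulated inputs from results/sim/, runs the node-weighted
spider-merge construction for both seed lists, and writes each subnetwork
(GraphML + node-role table + dropped-seed report) under results/.
"""

import argparse
from pathlib import Path

from convergenet import SteinerParams, classify_nodes, steiner_subnetwork
from convergenet import io as cio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--max-cost", type=float, default=2.0,
                        help="max new linkers per merged component")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    net = cio.read_interactome(args.simdir / "ppi.tsv")
    params = SteinerParams(max_merge_cost_per_terminal=args.max_cost)
    for tag in ("a", "b"):
        seeds = cio.read_gene_set(args.simdir / f"seeds_{tag}.txt", f"seeds_{tag}")
        sub = steiner_subnetwork(net, seeds, params)
        cio.write_subnetwork(sub, args.outdir / f"subnet_{tag}.graphml", "graphml")
        roles, summary = classify_nodes(sub, seeds)
        roles.to_csv(args.outdir / f"subnet_{tag}_roles.tsv", sep="\t", index=False)
        with open(args.outdir / f"subnet_{tag}_dropped.tsv", "w") as fh:
            fh.write("seed\treason\n")
            for s in sorted(sub.terminals_dropped):
                fh.write(f"{s}\t{sub.terminals_dropped[s]}\n")
        print(f"subnetwork {tag.upper()}: {summary['n_terminals']} of {len(seeds)} "
              f"seeds connected + {summary['n_linkers']} recruited linkers "
              f"({summary['n_dropped']} seeds dropped: "
              f"{summary['n_dropped_by_reason']})")


if __name__ == "__main__":
    main()
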