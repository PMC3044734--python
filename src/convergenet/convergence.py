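"""Convergence of two seed subnetworks into a high-priority gene table.

A gene is "high-priority" when it appears in both subnetworks — whether it
got there as a seed (terminal) or was recruited as a linker. Each
convergent gene is annotated against the two original seed lists, giving
four origin classes: both-seeds, cnv-only-seed, huge-only-seed, and
linker-only (present in neither seed list, recruited by both
constructions). Genes that sit in both seed lists but fell out of either
subnetwork are deliberately NOT high-priority: the seed-list intersection
is a separate, weaker line of evidence than the subnetwork intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import GeneSet
from .steiner import Subnetwork

__all__ = ["converge", "annotate_origin", "ConvergentTable", "ORIGIN_CLASSES"]

ORIGIN_CLASSES = ("both-seeds", "cnv-only-seed", "huge-only-seed", "linker-only")


@dataclass
class ConvergentTable:
    """Per-gene evidence table for the convergent (high-priority) genes.

    ``table`` columns: gene, in_cnv_subnet, in_huge_subnet, is_cnv_seed,
    is_huge_seed, origin_class and, when a differential-expression result
    was attached, de_p.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])

    def by_class(self, origin_class: str) -> pd.DataFrame:
        if origin_class not in ORIGIN_CLASSES:
            raise ValueError(f"unknown origin class: {origin_class!r}")
        return self.table[self.table["origin_class"] == origin_class]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        for col in ("is_cnv_seed", "is_huge_seed"):
            out[col] = out[col].map({True: "Y", False: "N"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def converge(subnet_a: Subnetwork, subnet_b: Subnetwork) -> set[str]:
    """Genes common to both subnetworks (terminals and linkers alike)."""
    return subnet_a.nodes & subnet_b.nodes


def annotate_origin(
    genes: set[str],
    cnv_seeds: GeneSet,
    huge_seeds: GeneSet,
    de=None,
) -> ConvergentTable:
    """Annotate convergent genes against the original seed lists.

    ``de`` may be a DEResult (from :mod:`convergenet.diffexpr`) or a
    mapping gene -> p-value; matching genes get a ``de_p`` column.
    """
    de_p: dict[str, float] = {}
    if de is not None:
        if hasattr(de, "p_values"):
            de_p = de.p_values()
        else:
            de_p = dict(de)

    rows = []
    for gene in sorted(genes):
        is_cnv = gene in cnv_seeds
        is_huge = gene in huge_seeds
        if is_cnv and is_huge:
            cls = "both-seeds"
        elif is_cnv:
            cls = "cnv-only-seed"
        elif is_huge:
            cls = "huge-only-seed"
        else:
            cls = "linker-only"
        row = {
            "gene": gene,
            "in_cnv_subnet": True,
            "in_huge_subnet": True,
            "is_cnv_seed": is_cnv,
            "is_huge_seed": is_huge,
            "origin_class": cls,
        }
        if de is not None:
            row["de_p"] = de_p.get(gene, float("nan"))
        rows.append(row)
    columns = ["gene", "in_cnv_subnet", "in_huge_subnet", "is_cnv_seed",
               "is_huge_seed", "origin_class"] + (["de_p"] if de is not None else [])
    return ConvergentTable(table=pd.DataFrame(rows, columns=columns))
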