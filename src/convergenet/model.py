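"""Core in-memory containers for the convergent-analysis pipeline.

Everything downstream operates on four objects: an :class:`Interactome`
(the unweighted, undirected protein-protein interaction network), named
:class:`GeneSet` objects (seed lists and pathways), a
:class:`PathwayCollection`, and an :class:`ExpressionMatrix` (a normalized
probe- or gene-level intensity table with a two-group case/control design).

Gene symbols are normalized to uppercase, whitespace-stripped strings; no
alias resolution is attempted — mapping synonyms onto a single symbol space
is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "normalize_symbol",
    "Interactome",
    "GeneSet",
    "PathwayCollection",
    "ExpressionMatrix",
]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; reject empty / internal whitespace."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise ValueError(f"gene symbol contains whitespace: {symbol!r}")
    return s


@dataclass
class Interactome:
    """Simple undirected graph of gene symbols (no self-loops, no multi-edges)."""

    graph: nx.Graph
    name: str = "interactome"

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], name: str = "interactome") -> "Interactome":
        g = nx.Graph()
        for u, v in edges:
            u, v = normalize_symbol(u), normalize_symbol(v)
            if u == v:
                continue
            g.add_edge(u, v)
        return cls(graph=g, name=name)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("interactome contains a self-loop")
        for n in self.graph.nodes:
            normalize_symbol(n)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.graph


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols (a seed list or a pathway)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        if not str(name):
            raise ValueError("gene set requires a non-empty name")
        return cls(name=str(name), genes=frozenset(normalize_symbol(g) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def intersection(self, other: "GeneSet | set[str] | frozenset[str]") -> frozenset[str]:
        other_genes = other.genes if isinstance(other, GeneSet) else frozenset(other)
        return self.genes & other_genes


@dataclass
class PathwayCollection:
    """Ordered list of uniquely named pathways (gene sets)."""

    pathways: list[GeneSet]
    source: str = "pathways"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate pathway name(s): {dup}")
        for p in self.pathways:
            if not p.genes:
                raise ValueError(f"pathway {p.name!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, name: str) -> GeneSet:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]


class ExpressionMatrix:
    """Normalized intensity matrix (rows x samples) with a case/control design.

    Parameters
    ----------
    values
        DataFrame indexed by probe or gene identifiers, one column per sample.
    group_labels
        Mapping from sample identifier to ``"case"`` or ``"control"``. Every
        sample column must be labeled.
    probe_to_gene
        Optional probe -> gene-symbol mapping; present at probe level, absent
        once probes have been collapsed to genes.
    """

    GROUPS = ("case", "control")

    def __init__(
        self,
        values: pd.DataFrame,
        group_labels: Mapping[str, str],
        probe_to_gene: Mapping[str, str] | None = None,
    ) -> None:
        values = values.astype(float)
        labels = {str(k): str(v) for k, v in group_labels.items()}
        missing = [s for s in values.columns if s not in labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        extra = [s for s in labels if s not in set(values.columns)]
        if extra:
            raise ValueError(f"group file lists samples absent from the matrix: {extra}")
        bad = sorted({v for v in labels.values() if v not in self.GROUPS})
        if bad:
            raise ValueError(f"group labels must be 'case' or 'control', got {bad}")
        self.values = values
        self.group_labels = labels
        self.probe_to_gene = (
            {str(k): normalize_symbol(v) for k, v in probe_to_gene.items()}
            if probe_to_gene is not None
            else None
        )

    @property
    def samples(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_labels[s] == group]

    @property
    def n_case(self) -> int:
        return len(self.group_samples("case"))

    @property
    def n_control(self) -> int:
        return len(self.group_samples("control"))

    def require_min_group_size(self, k: int = 2) -> None:
        if self.n_case < k or self.n_control < k:
            raise ValueError(
                f"need at least {k} samples per group (have {self.n_case} case, "
                f"{self.n_control} control)"
            )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.values.shape[0]} rows x {self.values.shape[1]} samples, "
            f"{self.n_case} case / {self.n_control} control)"
        )
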