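"""Readers and writers for the pipeline's external formats.

Supported inputs: two-column tab-delimited PPI edge lists, MITAB-style
tab-delimited interaction records ("mitab-lite": only the first two
interactor columns are consumed, with ``prefix:VALUE`` database prefixes
stripped and an optional user-supplied identifier -> symbol map), plain-text
gene lists, GMT pathway collections, and tab-delimited expression matrices
with a separate sample -> group file. Outputs: SIF, GraphML and TSV
subnetwork exports (Cytoscape-compatible) and GMT.

All parsers log the number of records they drop (self-loops, duplicate
edges, unmapped identifiers) so exclusions are visible in the run log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .model import ExpressionMatrix, GeneSet, Interactome, PathwayCollection, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "read_interactome",
    "write_interactome",
    "read_gene_set",
    "write_gene_set",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "write_subnetwork",
    "read_subnetwork_graphml",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending line."""


def _strip_prefix(field: str) -> str:
    """Drop a database prefix of the form ``prefix:VALUE`` from a MITAB field."""
    field = field.strip()
    if ":" in field:
        field = field.split(":", 1)[1]
    return field


def read_interactome(
    path: str | Path,
    dialect: str = "edge-list",
    symbol_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Interactome:
    """Read a PPI network as a simple undirected graph of gene symbols.

    ``edge-list``: two tab-separated symbol columns per line; ``#`` comments
    and blank lines are ignored. ``mitab-lite``: tab-separated records whose
    first two fields are interactor identifiers, each of the form
    ``prefix:VALUE``; ``symbol_map`` translates the stripped identifiers to
    gene symbols (identifiers without a mapping are dropped and counted).

    Self-loops and duplicate edges are dropped; the graph is simple.
    """
    path = Path(path)
    if dialect not in ("edge-list", "mitab-lite"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    g = nx.Graph()
    n_self, n_dup, n_unmapped = 0, 0, 0
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            a, b = fields[0], fields[1]
            if dialect == "mitab-lite":
                a, b = _strip_prefix(a), _strip_prefix(b)
                if symbol_map is not None:
                    if a not in symbol_map or b not in symbol_map:
                        n_unmapped += 1
                        continue
                    a, b = symbol_map[a], symbol_map[b]
            try:
                u, v = normalize_symbol(a), normalize_symbol(b)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            n_records += 1
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_records == 0 and n_unmapped == 0:
        raise ParseError(f"{path}: no interaction records found")
    logger.info(
        "read_interactome(%s): %d nodes, %d edges (dropped %d self-loops, %d duplicates, "
        "%d unmapped records)",
        path.name, g.number_of_nodes(), g.number_of_edges(), n_self, n_dup, n_unmapped,
    )
    return Interactome(graph=g, name=name or path.stem)


def write_interactome(net: Interactome, path: str | Path) -> None:
    """Write a two-column tab-delimited edge list, sorted for reproducibility."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one symbol per line; '#' comments ignored."""
    path = Path(path)
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line)
    if not genes:
        raise ParseError(f"{path}: empty gene set")
    gs = GeneSet.from_iterable(name or path.stem, genes)
    logger.info("read_gene_set(%s): %d unique symbols", path.name, len(gs))
    return gs


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gs.genes):
            fh.write(g + "\n")


def read_gmt(path: str | Path, source: str | None = None) -> PathwayCollection:
    """Read a GMT pathway collection (name, description, member genes per line).

    Descriptions are kept in the collection's provenance mapping; lines with
    no member genes are skipped with a warning; a duplicate pathway name is
    an error.
    """
    path = Path(path)
    pathways: list[GeneSet] = []
    descriptions: dict[str, str] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs name and description")
            pw_name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g.strip()]
            if pw_name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate pathway name {pw_name!r}")
            seen.add(pw_name)
            if not genes:
                logger.warning("read_gmt(%s):%d: pathway %r has no genes; skipped",
                               path.name, lineno, pw_name)
                continue
            pathways.append(GeneSet.from_iterable(pw_name, genes))
            descriptions[pw_name] = desc
    if not pathways:
        raise ParseError(f"{path}: no pathways found")
    return PathwayCollection(pathways=pathways, source=source or path.stem,
                             descriptions=descriptions)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection.pathways:
            desc = collection.descriptions.get(p.name, "na")
            fh.write("\t".join([p.name, desc] + sorted(p.genes)) + "\n")


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    probe_map_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited intensity matrix plus its sample -> group design.

    The matrix has row identifiers in the first column and a header row of
    sample identifiers; values must parse as reals. The groups file has two
    tab-separated columns: sample identifier, then ``case`` or ``control``.
    The matrix is assumed already normalized; no transformation is applied.
    """
    matrix_path = Path(matrix_path)
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-numeric cell ({exc})") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    groups: dict[str, str] = {}
    with open(groups_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{groups_path}:{lineno}: expected 'sample<TAB>group'")
            groups[fields[0]] = fields[1].strip().lower()

    probe_map = None
    if probe_map_path is not None:
        probe_map = {}
        with open(probe_map_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{probe_map_path}:{lineno}: expected 'probe<TAB>gene'")
                probe_map[fields[0]] = fields[1]

    expr = ExpressionMatrix(values, groups, probe_map)
    logger.info(
        "read_expression(%s): %d rows, %d case / %d control samples",
        matrix_path.name, values.shape[0], expr.n_case, expr.n_control,
    )
    return expr


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     groups_path: str | Path,
                     probe_map_path: str | Path | None = None) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="id")
    with open(groups_path, "w") as fh:
        for s in expr.samples:
            fh.write(f"{s}\t{expr.group_labels[s]}\n")
    if probe_map_path is not None and expr.probe_to_gene is not None:
        with open(probe_map_path, "w") as fh:
            for probe in sorted(expr.probe_to_gene):
                fh.write(f"{probe}\t{expr.probe_to_gene[probe]}\n")


def _sorted_copy(subnet) -> nx.Graph:
    """Copy a subnetwork graph with nodes/edges inserted in sorted order.

    GraphML/SIF writers iterate in insertion order; sorting makes the files
    byte-reproducible.
    """
    g = nx.Graph()
    roles = subnet.roles()
    for n in sorted(subnet.graph.nodes):
        g.add_node(n, role=roles[n])
    for u, v in sorted(tuple(sorted(e)) for e in subnet.graph.edges):
        g.add_edge(u, v)
    return g


def write_subnetwork(subnet, path: str | Path, format: str = "graphml") -> None:
    """Export a Steiner subnetwork as SIF, GraphML or TSV.

    SIF uses interaction type ``pp``; GraphML carries a node attribute
    ``role`` in {terminal, linker}; TSV writes an edge list followed by a
    node-annotation table. An empty subnetwork yields header-only files.
    """
    path = Path(path)
    fmt = format.lower()
    g = _sorted_copy(subnet)
    if fmt == "sif":
        with open(path, "w") as fh:
            in_edge = set()
            for u, v in g.edges:
                fh.write(f"{u}\tpp\t{v}\n")
                in_edge.update((u, v))
            for n in g.nodes:  # isolated nodes still listed
                if n not in in_edge:
                    fh.write(f"{n}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# edges\nsource\ttarget\n")
            for u, v in g.edges:
                fh.write(f"{u}\t{v}\n")
            fh.write("# nodes\nnode\trole\n")
            for n in g.nodes:
                fh.write(f"{n}\t{g.nodes[n]['role']}\n")
    else:
        raise ValueError(f"unknown subnetwork format: {format!r}")


def read_subnetwork_graphml(path: str | Path):
    """Re-read a GraphML subnetwork export (round-trip / Cytoscape checks)."""
    from .steiner import Subnetwork

    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    terminals = {n for n, d in g.nodes(data=True) if d.get("role") == "terminal"}
    linkers = {n for n, d in g.nodes(data=True) if d.get("role") == "linker"}
    clean = nx.Graph()
    clean.add_nodes_from(g.nodes)
    clean.add_edges_from(g.edges)
    return Subnetwork(graph=clean, terminals_included=terminals, linkers=linkers,
                      terminals_dropped={})
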