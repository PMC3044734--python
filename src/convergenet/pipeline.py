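"""End-to-end orchestration: one config, one reproducible run.

``run_pipeline`` executes the full convergent analysis — Steiner
subnetwork per seed list, node-set convergence with origin annotation,
optional probe collapse + differential expression, optional pathway
enrichment of both subnetworks followed by crosstalk mapping — and writes
every artifact plus a machine-readable manifest (input checksums,
parameters, per-stage counts, package version). Outputs are byte-stable:
re-running the same config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__, io as cio
from .convergence import annotate_origin, converge
from .crosstalk import build_crosstalk_graph, fisher_enrich, functional_groups
from .diffexpr import collapse_probes, t_test_de
from .model import GeneSet
from .steiner import SteinerParams, classify_nodes, steiner_subnetwork

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults mirror the published analysis thresholds: raw t-test alpha
    0.05, enrichment p < 0.01 with >= 5 interesting genes per pathway,
    crosstalk edges with >= 3 shared genes filtered to the top 1% (set A)
    and top 5% (set B) of scores.
    """

    ppi: str
    seeds_a: str
    seeds_b: str
    outdir: str
    expr: str | None = None
    groups: str | None = None
    probe_map: str | None = None
    gmt: str | None = None
    max_merge_cost: float = 2.0
    alpha: float = 0.05
    t_test_variant: str = "welch"
    min_hits: int = 5
    p_cutoff: float = 0.01
    min_shared: int = 3
    top_fraction_a: float = 0.01
    top_fraction_b: float = 0.05
    crosstalk_full_sets: bool = False
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("ppi", "seeds_a", "seeds_b"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {key}: {p} does not exist")
        expr_parts = [self.expr, self.groups]
        if any(expr_parts) and not all(expr_parts):
            raise ValueError("expression analysis needs both expr and groups paths")
        for key in ("expr", "groups", "probe_map", "gmt"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {key}: {p} does not exist")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.max_merge_cost < 0 or self.min_hits < 0 or self.min_shared < 0:
            raise ValueError("thresholds must be non-negative")
        for frac in (self.top_fraction_a, self.top_fraction_b):
            if not 0 < frac <= 1:
                raise ValueError("top fractions must lie in (0, 1]")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full convergent analysis; returns the manifest dict.

    Artifacts written to ``config.outdir``: subnet_a.graphml,
    subnet_b.graphml, node role tables, convergent_table.tsv and — when the
    optional inputs are present — de.tsv, enrich_a.tsv, enrich_b.tsv,
    crosstalk.graphml, groups.tsv, plus manifest.json. On stage failure a
    FAILED marker naming the stage is left in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for key in ("ppi", "seeds_a", "seeds_b", "expr", "groups", "probe_map", "gmt"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    try:
        net = _stage("read-ppi")(cio.read_interactome, config.ppi)
        seeds_a = _stage("read-seeds-a")(cio.read_gene_set, config.seeds_a, "seeds_a")
        seeds_b = _stage("read-seeds-b")(cio.read_gene_set, config.seeds_b, "seeds_b")
        manifest["stages"]["interactome"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}

        params = SteinerParams(max_merge_cost_per_terminal=config.max_merge_cost)
        subnets = {}
        for tag, seeds in (("a", seeds_a), ("b", seeds_b)):
            sub = _stage(f"subnet-{tag}")(steiner_subnetwork, net, seeds, params)
            subnets[tag] = sub
            cio.write_subnetwork(sub, outdir / f"subnet_{tag}.graphml", "graphml")
            roles, summary = classify_nodes(sub, seeds)
            roles.to_csv(outdir / f"subnet_{tag}_roles.tsv", sep="\t", index=False)
            with open(outdir / f"subnet_{tag}_dropped.tsv", "w") as fh:
                fh.write("seed\treason\n")
                for s in sorted(sub.terminals_dropped):
                    fh.write(f"{s}\t{sub.terminals_dropped[s]}\n")
            manifest["stages"][f"subnet_{tag}"] = {
                "n_terminals": summary["n_terminals"],
                "n_linkers": summary["n_linkers"],
                "n_dropped": summary["n_dropped"],
            }

        de_result = None
        if config.expr is not None:
            expr = _stage("read-expression")(
                cio.read_expression, config.expr, config.groups, config.probe_map
            )
            if expr.probe_to_gene is not None:
                expr = _stage("collapse-probes")(collapse_probes, expr)
            de_result = _stage("t-test")(
                t_test_de, expr, config.alpha, config.t_test_variant
            )
            de_result.write_tsv(outdir / "de.tsv", alpha=config.alpha)
            manifest["stages"]["diffexpr"] = {
                "n_genes": len(de_result.table),
                "n_significant": int((de_result.table["p"] < config.alpha).sum()),
                "variant": de_result.test_variant,
            }

        overlap = _stage("converge")(converge, subnets["a"], subnets["b"])
        table = _stage("annotate")(annotate_origin, overlap, seeds_a, seeds_b, de_result)
        table.write_tsv(outdir / "convergent_table.tsv")
        manifest["stages"]["convergence"] = {
            "n_overlap": len(table),
            "by_class": {
                cls: int((table.table["origin_class"] == cls).sum())
                for cls in sorted(table.table["origin_class"].unique())
            },
        }

        if config.gmt is not None:
            collection = _stage("read-gmt")(cio.read_gmt, config.gmt)
            background = GeneSet.from_iterable("interactome", net.nodes)
            enrich = {}
            for tag in ("a", "b"):
                query = GeneSet.from_iterable(
                    f"subnet_{tag}", subnets[tag].nodes & net.nodes
                )
                res = _stage(f"enrich-{tag}")(
                    fisher_enrich, query, collection, background,
                    config.min_hits, config.p_cutoff,
                )
                res.write_tsv(outdir / f"enrich_{tag}.tsv")
                enrich[tag] = res
                manifest["stages"][f"enrich_{tag}"] = {
                    "n_pathways": len(res.table),
                    "n_significant": len(res.significant),
                }
            xtalk = _stage("crosstalk")(
                build_crosstalk_graph, enrich["a"], enrich["b"],
                config.min_shared, config.top_fraction_a, config.top_fraction_b,
                collection, config.crosstalk_full_sets,
            )
            xtalk.write_graphml(outdir / "crosstalk.graphml")
            functional_groups(xtalk).to_csv(outdir / "groups.tsv", sep="\t", index=False)
            manifest["stages"]["crosstalk"] = {
                "n_pathways": xtalk.graph.number_of_nodes(),
                "n_edges": xtalk.graph.number_of_edges(),
                "n_groups": len(xtalk.groups),
            }
    except PipelineError as exc:
        failed_marker.write_text(str(exc) + "\n")
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", outdir)
    return manifest
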