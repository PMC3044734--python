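"""Probe collapse and case/control differential expression testing.

The expression input is an already-normalized intensity matrix. Probes are
collapsed to genes by keeping, per gene, the probe with the largest mean
intensity across all samples (ties go to the lexicographically smaller
probe identifier). Differential expression between cases and controls is a
per-gene two-sided two-sample t-test — Welch by default, with a pooled
(Student) variant available — reported as raw p-values; Benjamini–Hochberg
adjustment is optional and off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = ["collapse_probes", "t_test_de", "de_genes", "DEResult"]


@dataclass
class DEResult:
    """Per-gene t-test results plus the settings that produced them.

    ``table`` columns: gene, mean_case, mean_control, t, p, degenerate.
    ``test_variant`` is "welch" or "pooled"; ``adjusted`` marks whether an
    extra ``p_adj`` (Benjamini–Hochberg) column is present.
    """

    table: pd.DataFrame
    n_case: int
    n_control: int
    test_variant: str
    probe_summary: str = "max-mean"
    adjusted: bool = False
    metadata: dict = field(default_factory=dict)

    def p_values(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["p"]))

    def sorted_by_p(self) -> pd.DataFrame:
        return self.table.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)

    def write_tsv(self, path, alpha: float = 0.05) -> None:
        out = self.sorted_by_p().copy()
        out["significant"] = np.where(out["p"] < alpha, "Y", "N")
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def collapse_probes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse probes to genes, keeping each gene's max-mean-intensity probe.

    Probes without a gene mapping are dropped (count logged). The returned
    matrix is keyed by gene symbol and carries no probe map.
    """
    if expr.probe_to_gene is None or not expr.probe_to_gene:
        raise ValueError("probe collapse requires a probe -> gene mapping")
    values = expr.values
    mapped = [p for p in values.index if p in expr.probe_to_gene]
    n_dropped = len(values.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probe in the matrix has a gene mapping")

    sub = values.loc[mapped]
    means = sub.mean(axis=1)
    frame = pd.DataFrame({
        "probe": mapped,
        "gene": [expr.probe_to_gene[p] for p in mapped],
        "mean": means.to_numpy(),
    })
    # max mean wins; ties -> lexicographically smaller probe ID
    frame = frame.sort_values(["gene", "mean", "probe"],
                              ascending=[True, False, True], kind="mergesort")
    chosen = frame.drop_duplicates("gene", keep="first")
    collapsed = sub.loc[chosen["probe"]].copy()
    collapsed.index = chosen["gene"].to_numpy()
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, expr.group_labels, probe_to_gene=None)


def t_test_de(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    variant: str = "welch",
    adjust: bool = False,
) -> DEResult:
    """Two-sided two-sample t-test per gene between cases and controls.

    ``variant`` selects Welch (unequal variances, default) or ``"pooled"``
    (classical Student). Rows where both groups have zero variance are
    flagged degenerate: p = 1 and t = 0 when the means agree, p = 0 with
    infinite t otherwise. ``adjust=True`` appends Benjamini–Hochberg
    adjusted p-values; significance calls elsewhere use raw p.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    expr.require_min_group_size(2)
    case = expr.values[expr.group_samples("case")].to_numpy(float)
    ctrl = expr.values[expr.group_samples("control")].to_numpy(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=(variant == "pooled"))
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    equal_means = np.isclose(mean_case, mean_ctrl)
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    sign = np.where(mean_case >= mean_ctrl, np.inf, -np.inf)
    t = np.where(degenerate & ~equal_means, sign, t)
    p = np.where(degenerate & ~equal_means, 0.0, p)

    table = pd.DataFrame({
        "gene": [str(g) for g in expr.values.index],
        "mean_case": mean_case,
        "mean_control": mean_ctrl,
        "t": t,
        "p": p,
        "degenerate": degenerate,
    })
    adjusted = False
    if adjust:
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        adjusted = True
    n_sig = int((table["p"] < alpha).sum())
    logger.info("t_test_de(%s): %d/%d genes at p < %g", variant, n_sig, len(table), alpha)
    return DEResult(
        table=table,
        n_case=expr.n_case,
        n_control=expr.n_control,
        test_variant=variant,
        adjusted=adjusted,
        metadata={"alpha": alpha, "probe_summary": "max-mean"},
    )


def de_genes(result: DEResult, alpha: float = 0.05, use_adjusted: bool = False) -> GeneSet:
    """Genes with p < alpha (strict); raw p by default."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    col = "p_adj" if use_adjusted else "p"
    if use_adjusted and not result.adjusted:
        raise ValueError("result has no adjusted p-values")
    hits = result.table.loc[result.table[col] < alpha, "gene"]
    return GeneSet.from_iterable(f"de_p<{alpha:g}", hits) if len(hits) else GeneSet(
        name=f"de_p<{alpha:g}", genes=frozenset()
    )
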