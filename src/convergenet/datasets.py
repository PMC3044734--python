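"""Small bundled reference tables.

``load_high_priority_table`` returns the published table of 20 convergent
epilepsy candidate genes — the genes found in both the CNV-gene and the
HuGE-gene Steiner subnetworks — with flags marking which of them also sit
in the original seed lists (genes inside reported deletion CNV regions,
and genes with prior epilepsy association studies, respectively). Five
genes carry both flags; the rest entered one or both subnetworks as
recruited linkers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import GeneSet

__all__ = ["load_high_priority_table", "high_priority_seed_sets"]


def load_high_priority_table() -> pd.DataFrame:
    """The 20 published high-priority genes with their seed-list flags."""
    ref = resources.files("convergenet.data") / "high_priority_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def high_priority_seed_sets() -> tuple[GeneSet, GeneSet]:
    """Seed-membership flags of the published table as two gene sets."""
    table = load_high_priority_table()
    cnv = GeneSet.from_iterable("cnv_flagged", table.loc[table["cnv_seed"] == "Y", "gene"])
    huge = GeneSet.from_iterable("huge_flagged", table.loc[table["huge_seed"] == "Y", "gene"])
    return cnv, huge
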