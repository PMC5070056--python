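"""Case-control differential-expression signatures and ranked phenotypes.

The signature is the per-gene log2 fold change (difference of class means
on log2-scale expression) between case and control samples, together with
a Welch two-sample t statistic and p-value.  Downstream enrichment consumes
two rank orders derived from it:

* the *signed* order ("top-down phenotype"): highest to lowest logFC, used
  by the two-tailed mode-of-action analysis;
* the *absolute* order: by |logFC| descending, used by the one-tailed
  master-regulator enrichment.

Ties in either order break by gene id, ascending, so rankings (and the
permutation nulls built on them) are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError
from .expression import CASE, CONTROL, ExpressionMatrix


@dataclass
class RankedSignature:
    """Per-gene logFC / t / p with the two derived rank orders.

    ``table`` is indexed by gene id with columns ``logfc``, ``t``, ``p``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"logfc", "t", "p"}
        if not required.issubset(self.table.columns):
            raise InvalidInputError(f"signature table needs columns {sorted(required)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def signed_order(self) -> tuple[list[str], np.ndarray]:
        """Genes from highest to lowest logFC, with aligned logFC weights."""
        df = self.table.reset_index(names="gene").sort_values(
            ["logfc", "gene"], ascending=[False, True], kind="stable"
        )
        return df["gene"].tolist(), df["logfc"].to_numpy(dtype=float)

    def absolute_order(self) -> tuple[list[str], np.ndarray]:
        """Genes by |logFC| descending, with aligned |logFC| weights."""
        df = self.table.reset_index(names="gene")
        df["_abs"] = df["logfc"].abs()
        df = df.sort_values(["_abs", "gene"], ascending=[False, True], kind="stable")
        return df["gene"].tolist(), df["_abs"].to_numpy(dtype=float)

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


def compute_signature(expr: ExpressionMatrix) -> RankedSignature:
    """logFC (case mean - control mean) plus Welch t and p per gene.

    Expression must already be on log2 scale; each class needs at least two
    samples.  The Welch test stands in for moderated differential-expression
    statistics: only the logFC feeds the ranked phenotypes downstream.
    """
    if expr.labels is None:
        raise InvalidInputError("expression matrix has no class labels")
    lab = expr.labels
    case_ids = [s for s in expr.sample_ids if lab.get(s) == CASE]
    ctrl_ids = [s for s in expr.sample_ids if lab.get(s) == CONTROL]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise InvalidInputError("need >= 2 samples per class for a signature")

    case = expr.values.loc[:, case_ids].to_numpy(dtype=float)
    ctrl = expr.values.loc[:, ctrl_ids].to_numpy(dtype=float)
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    table = pd.DataFrame(
        {"logfc": logfc, "t": t, "p": p}, index=pd.Index(expr.gene_ids, name="gene")
    )
    return RankedSignature(table)


def read_signature(path: str | Path) -> RankedSignature:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return RankedSignature(df)
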