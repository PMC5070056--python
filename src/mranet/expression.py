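"""Gene-expression matrices with optional sample class labels.

The universal input of the pipeline is a genes x samples matrix of
log2-scale expression values, carried as a :class:`pandas.DataFrame` with
gene identifiers on the row index and sample identifiers on the columns.
Case/control (or cohort-tag) labels are a :class:`pandas.Series` indexed by
sample identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

#: Class labels understood by the differential-expression step.
CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """A genes x samples log2 expression matrix.

    Parameters
    ----------
    values:
        DataFrame with unique gene ids as index and unique sample ids as
        columns; all entries must be finite.
    labels:
        Optional Series mapping sample id -> class label. When both
        ``"case"`` and ``"control"`` are present, each must have at least
        two samples so a differential signature can be computed.
    """

    values: pd.DataFrame
    labels: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise InvalidInputError("expression matrix is empty")
        if v.index.duplicated().any():
            raise InvalidInputError("duplicate gene identifiers")
        if v.columns.duplicated().any():
            raise InvalidInputError("duplicate sample identifiers")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise InvalidInputError("expression values must be finite")
        if self.labels is not None:
            lab = self.labels
            missing = [s for s in lab.index if s not in v.columns]
            if missing:
                raise InvalidInputError(
                    f"labelled samples absent from matrix: {missing[:5]}"
                )
            counts = lab.value_counts()
            for cls in (CASE, CONTROL):
                if cls in counts.index and counts[cls] < 2:
                    raise InvalidInputError(
                        f"class '{cls}' has fewer than 2 samples"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order kept)."""
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise InvalidInputError(f"unknown sample ids: {missing[:5]}")
        lab = None
        if self.labels is not None:
            lab = self.labels.loc[[s for s in sample_ids if s in self.labels.index]]
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], lab)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise InvalidInputError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids), :], self.labels)

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (first column ``gene``, header = sample ids).

        If ``labels_path`` is given and labels are present, they are written
        as a two-column TSV ``sample<TAB>class``.
        """
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")
        if labels_path is not None and self.labels is not None:
            lab = self.labels.rename("class").to_frame()
            lab.index.name = "sample"
            lab.to_csv(labels_path, sep="\t")


def read_expression(path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression matrix (and optional labels) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    labels = read_labels(labels_path) if labels_path is not None else None
    return ExpressionMatrix(df, labels)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``sample<TAB>class`` TSV into a Series."""
    lab = pd.read_csv(path, sep="\t", index_col=0)
    ser = lab.iloc[:, 0].astype(str)
    ser.index = ser.index.astype(str)
    return ser


def read_tf_list(path: str | Path) -> list[str]:
    """Read a plain list of transcription-factor ids (one per line)."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            ids.append(token)
    return ids


def write_tf_list(tf_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in tf_ids))
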