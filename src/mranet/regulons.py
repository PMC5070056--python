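"""Regulons with signed mode of action, and the regulon association map.

A regulon is one transcription factor plus its inferred targets.  Each
target carries a mode of action: the sign of the Pearson correlation
between TF and target expression on the matrix used for network inference
(+1: the target rises with TF activity; -1: it falls).  The association map
summarises pairwise regulon overlap by the Jaccard coefficient of the
target sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidStageError

logger = logging.getLogger(__name__)


@dataclass
class Regulon:
    """One TF and its targets, each with (mode, pearson_r)."""

    tf: str
    targets: dict[str, tuple[int, float]]

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise InvalidInputError("a regulon cannot contain its own TF")
        for g, (mode, r) in self.targets.items():
            if mode not in (-1, 1) or mode != int(np.sign(r)) or r == 0:
                raise InvalidInputError(
                    f"target {g!r}: mode must equal sign of a nonzero correlation"
                )

    @property
    def size(self) -> int:
        return len(self.targets)

    def positive_targets(self) -> set[str]:
        return {g for g, (m, _) in self.targets.items() if m == 1}

    def negative_targets(self) -> set[str]:
        return {g for g, (m, _) in self.targets.items() if m == -1}

    def target_set(self) -> set[str]:
        return set(self.targets)


@dataclass
class AssociationMap:
    """Regulon sizes plus pairwise Jaccard overlap (zero-overlap pairs omitted)."""

    nodes: dict[str, int]
    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tf1", "tf2", "jaccard"])
    )

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def extract_regulons(
    net,
    expr,
    min_size: int = 15,
) -> list[Regulon]:
    """Build regulons from a relevance- or DPI-stage network.

    The mode of action is the sign of the Pearson correlation computed on
    ``expr`` (the same matrix used for inference).  Targets with an exactly
    zero or undefined correlation are dropped with a logged notice (a
    mode-less target cannot enter the two-tailed analysis); TFs ending up
    with fewer than ``min_size`` targets are dropped with a notice.
    TF-TF edges contribute the partner TF as a target of both regulons.
    """
    from .network import STAGE_DPI, STAGE_RELEVANCE  # local import avoids cycle

    if net.stage not in (STAGE_RELEVANCE, STAGE_DPI):
        raise InvalidStageError(
            f"regulons require a relevance or dpi network, got {net.stage!r}"
        )
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for row in net.edges.itertuples(index=False):
        if row.tf not in pos or row.target not in pos:
            raise InvalidInputError(
                f"edge endpoint missing from expression matrix: {row.tf}-{row.target}"
            )

    tf_set = set(net.tf_ids)
    members: dict[str, list[str]] = {}
    for row in net.edges.itertuples(index=False):
        members.setdefault(row.tf, []).append(row.target)
        if row.target in tf_set:  # symmetric TF-TF edge, stored once
            members.setdefault(row.target, []).append(row.tf)

    x = expr.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc * xc).sum(axis=1))

    regulons: list[Regulon] = []
    for tf in sorted(members):
        ti = pos[tf]
        targets: dict[str, tuple[int, float]] = {}
        for g in sorted(set(members[tf])):
            gi = pos[g]
            denom = norms[ti] * norms[gi]
            if denom == 0.0:
                logger.info("regulon %s: dropping %s (zero variance)", tf, g)
                continue
            r = float(np.dot(xc[ti], xc[gi]) / denom)
            if r == 0.0 or not np.isfinite(r):
                logger.info("regulon %s: dropping %s (correlation %r)", tf, g, r)
                continue
            targets[g] = (int(np.sign(r)), r)
        if len(targets) < min_size:
            logger.info(
                "dropping regulon %s: %d targets < min_size %d", tf, len(targets), min_size
            )
            continue
        regulons.append(Regulon(tf, targets))
    return regulons


def build_association_map(regulons: Sequence[Regulon]) -> AssociationMap:
    """Pairwise Jaccard coefficients over regulon target sets."""
    if not regulons:
        raise InvalidInputError("at least one regulon required")
    nodes = {r.tf: r.size for r in regulons}
    rows = []
    regs = sorted(regulons, key=lambda r: r.tf)
    for i in range(len(regs)):
        for j in range(i + 1, len(regs)):
            a, b = regs[i].target_set(), regs[j].target_set()
            inter = len(a & b)
            if inter == 0:
                continue
            jc = inter / len(a | b)
            rows.append((regs[i].tf, regs[j].tf, jc))
    edges = pd.DataFrame(rows, columns=["tf1", "tf2", "jaccard"])
    return AssociationMap(nodes, edges)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_regulons_tsv(regulons: Sequence[Regulon], path: str | Path) -> None:
    """Mode-annotated edge list: columns tf, target, mode."""
    rows = [
        (r.tf, g, mode)
        for r in sorted(regulons, key=lambda r: r.tf)
        for g, (mode, _) in sorted(r.targets.items())
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode"]).to_csv(
        path, sep="\t", index=False
    )


def write_regulons_gmt(regulons: Sequence[Regulon], path: str | Path) -> None:
    """GMT gene sets ``<tf>_pos`` / ``<tf>_neg`` (empty sets skipped)."""
    with open(path, "w") as fh:
        for r in sorted(regulons, key=lambda r: r.tf):
            pos = sorted(r.positive_targets())
            neg = sorted(r.negative_targets())
            if pos:
                fh.write("\t".join([f"{r.tf}_pos", "positive targets", *pos]) + "\n")
            if neg:
                fh.write("\t".join([f"{r.tf}_neg", "negative targets", *neg]) + "\n")


def read_regulons_tsv(path: str | Path) -> list[Regulon]:
    """Read a tf/target/mode TSV; stored correlations become +/-1."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    out = []
    for tf, grp in df.groupby("tf", sort=True):
        targets = {
            row.target: (int(row.mode), float(row.mode))
            for row in grp.itertuples(index=False)
        }
        out.append(Regulon(str(tf), targets))
    return out
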