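"""Regulon enrichment: one-tailed master-regulator GSEA, two-tailed
mode-of-action GSEA with the differential score ES_A - ES_B, permutation
nulls, Benjamini-Hochberg adjustment and consensus calling.

Enrichment score
----------------
The score is the weighted Kolmogorov-Smirnov running-sum statistic.
Walking down the ranked gene list, genes in the hit set add
``|weight|^exponent`` normalised by the total over hits, genes outside it
subtract ``1/(N - N_hits)``; the enrichment score (ES) is the value of the
running sum at its maximal absolute deviation from zero (signed), so
ES lies in [-1, 1].

One-tailed analysis ranks the phenotype by |logFC| and scores each
regulon's full target set.  The two-tailed analysis splits a regulon into
positive (A) and negative (B) targets, scores both against the signed
"top-down" phenotype (highest to lowest logFC), and tests the differential
enrichment dES = ES_A - ES_B: a significantly positive dES means the
phenotype induced the regulon, a significantly negative dES that it
repressed it (negative targets up, positive targets down).

The permutation null shuffles the gene labels of the ranked phenotype
(equivalently: redraws the hit positions uniformly), and p-values use the
pseudocount construction (1 + #{null >= observed}) / (n_perm + 1), so they
are never zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed
from .exceptions import InvalidInputError, InvalidParameterError
from .regulons import Regulon
from .signature import RankedSignature

logger = logging.getLogger(__name__)

INDUCED = "induced"
REPRESSED = "repressed"
INCONCLUSIVE = "inconclusive"


# ---------------------------------------------------------------------------
# core running-sum statistic
# ---------------------------------------------------------------------------

def _es_rows(wexp: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Signed ES for each row of the 0/1 hit-indicator matrix ``hits``.

    ``wexp`` holds |weight|^exponent aligned to the ranked list.  When a
    row's total hit weight is zero the hit increments fall back to uniform
    1/N_hits.  The maximal |running sum| position breaks ties at the first
    index, which is deterministic.
    """
    n = wexp.size
    hit_w = hits * wexp[None, :]
    totals = hit_w.sum(axis=1, keepdims=True)
    n_hits = hits.sum(axis=1, keepdims=True)
    inc = np.where(totals > 0, hit_w / np.where(totals > 0, totals, 1.0), hits / n_hits)
    dec = (1.0 - hits) / (n - n_hits)
    cum = np.cumsum(inc - dec, axis=1)
    idx = np.argmax(np.abs(cum), axis=1)
    return cum[np.arange(cum.shape[0]), idx]


def gsea_es(
    genes: Sequence[str],
    weights: Sequence[float],
    hit_set: Iterable[str],
    exponent: float = 1.0,
) -> float:
    """Signed weighted-KS enrichment score of ``hit_set`` in a ranked list.

    ``genes`` must be unique and ordered (rank 1 first); ``weights`` are the
    aligned rank weights.  Requires 1 <= |hit_set| < N and
    hit_set ⊆ genes.
    """
    if exponent < 0:
        raise InvalidParameterError("exponent must be >= 0")
    genes = list(genes)
    n = len(genes)
    if len(set(genes)) != n:
        raise InvalidInputError("ranked gene list contains duplicates")
    w = np.asarray(weights, dtype=float)
    if w.size != n:
        raise InvalidInputError("weights must align with the ranked genes")
    hit_set = set(hit_set)
    if not hit_set or len(hit_set) >= n:
        raise InvalidInputError("hit set must be non-empty and a proper subset")
    missing = hit_set - set(genes)
    if missing:
        raise InvalidInputError(f"hit genes absent from ranked list: {sorted(missing)[:5]}")
    ind = np.fromiter((1.0 if g in hit_set else 0.0 for g in genes), float, count=n)
    wexp = np.abs(w) ** exponent
    return float(_es_rows(wexp, ind[None, :])[0])


def _random_hit_rows(
    rng: np.random.Generator, n_rows: int, n: int, n_hits: int
) -> np.ndarray:
    """Uniformly random 0/1 indicator rows with ``n_hits`` ones each."""
    r = rng.random((n_rows, n))
    sel = np.argpartition(r, n_hits - 1, axis=1)[:, :n_hits]
    out = np.zeros((n_rows, n))
    np.put_along_axis(out, sel, 1.0, axis=1)
    return out


def _null_abs_es(
    wexp: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        hits = _random_hit_rows(rng, c, wexp.size, n_hits)
        out[done : done + c] = _es_rows(wexp, hits)
        done += c
    return np.abs(out)


# ---------------------------------------------------------------------------
# one-tailed master-regulator analysis
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    """One regulon x signature x network enrichment result."""

    tf: str
    network_id: str
    signature_id: str
    es: float
    p_perm: float
    p_adj: float = float("nan")


def mra(
    regulons: Sequence[Regulon],
    signature: RankedSignature,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    network_id: str = "net",
    signature_id: str = "sig",
    exponent: float = 1.0,
    min_size: int = 5,
) -> list[EnrichmentRecord]:
    """One-tailed regulon enrichment against the |logFC|-ranked phenotype.

    For each regulon the full target set is scored on the absolute-logFC
    ranking; the null redraws hit positions ``n_perm`` times;
    ``p_perm = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1)``; p-values
    are BH-adjusted across the regulons of this (network, signature) run.
    Targets absent from the signature are silently dropped; regulons left
    with fewer than ``min_size`` targets are skipped with a notice.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    genes, weights = signature.absolute_order()
    gene_pos = {g: i for i, g in enumerate(genes)}
    wexp = np.abs(weights) ** exponent
    n = len(genes)

    records: list[EnrichmentRecord] = []
    for reg in sorted(regulons, key=lambda r: r.tf):
        positions = sorted(gene_pos[g] for g in reg.target_set() if g in gene_pos)
        if len(positions) < min_size or len(positions) >= n:
            logger.info(
                "mra: skipping regulon %s (%d usable targets)", reg.tf, len(positions)
            )
            continue
        ind = np.zeros(n)
        ind[positions] = 1.0
        es = float(_es_rows(wexp, ind[None, :])[0])
        rng = np.random.default_rng(child_seed(seed, "mra", reg.tf))
        null = _null_abs_es(wexp, len(positions), n_perm, rng)
        p = (1.0 + int(np.sum(null >= abs(es)))) / (n_perm + 1.0)
        records.append(EnrichmentRecord(reg.tf, network_id, signature_id, es, p))

    if records:
        adj = multipletests([r.p_perm for r in records], method="fdr_bh")[1]
        records = [replace(r, p_adj=float(a)) for r, a in zip(records, adj)]
    return records


# ---------------------------------------------------------------------------
# two-tailed mode-of-action analysis
# ---------------------------------------------------------------------------

@dataclass
class TwoTailRecord:
    """Two-tailed result: subgroup scores, differential score and direction."""

    tf: str
    network_id: str
    signature_id: str
    es_a: float
    es_b: float
    des: float
    p_perm: float
    p_adj: float = float("nan")
    direction: str = INCONCLUSIVE
    reason: str = ""


def split_regulon(regulon: Regulon) -> tuple[set[str], set[str]]:
    """Partition targets by mode: (A = positive targets, B = negative)."""
    return regulon.positive_targets(), regulon.negative_targets()


def two_tailed_gsea(
    regulon: Regulon,
    signature: RankedSignature,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_tail: int = 5,
    seed: int = 0,
    network_id: str = "net",
    signature_id: str = "sig",
    exponent: float = 1.0,
) -> TwoTailRecord:
    """Two-tailed GSEA of one regulon on the signed-ranked phenotype.

    ES_A and ES_B are scored on the top-down phenotype (highest to lowest
    logFC); dES = ES_A - ES_B.  The null shuffles gene labels (one shuffle
    scores both subgroups) and the p-value is two-sided on |dES|.  When
    called stand-alone the adjusted p equals the permutation p; batch runs
    (:func:`two_tailed_mra`) BH-adjust across regulons before calling the
    direction.  A subgroup below ``min_tail`` usable targets yields an
    inconclusive record with a flagged reason.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    genes, weights = signature.signed_order()
    gene_pos = {g: i for i, g in enumerate(genes)}
    a_set, b_set = split_regulon(regulon)
    a_pos = sorted(gene_pos[g] for g in a_set if g in gene_pos)
    b_pos = sorted(gene_pos[g] for g in b_set if g in gene_pos)
    nan = float("nan")
    if len(a_pos) < min_tail or len(b_pos) < min_tail:
        return TwoTailRecord(
            regulon.tf, network_id, signature_id, nan, nan, nan, nan, nan,
            INCONCLUSIVE, reason=f"tail_below_min({len(a_pos)},{len(b_pos)})",
        )
    n = len(genes)
    if len(a_pos) + len(b_pos) >= n:
        raise InvalidInputError("regulon covers the whole ranked list")
    wexp = np.abs(weights) ** exponent
    ind_a = np.zeros(n)
    ind_a[a_pos] = 1.0
    ind_b = np.zeros(n)
    ind_b[b_pos] = 1.0
    es_a = float(_es_rows(wexp, ind_a[None, :])[0])
    es_b = float(_es_rows(wexp, ind_b[None, :])[0])
    des = es_a - es_b

    rng = np.random.default_rng(child_seed(seed, "gsea2", regulon.tf))
    n_a, n_b = len(a_pos), len(b_pos)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        c = min(512, n_perm - done)
        r = rng.random((c, n))
        # one gene-label shuffle per permutation: the n_a smallest entries
        # act as subgroup A, the n_b largest as subgroup B (disjoint,
        # jointly uniform over disjoint position sets)
        sel_a = np.argpartition(r, n_a - 1, axis=1)[:, :n_a]
        sel_b = np.argpartition(-r, n_b - 1, axis=1)[:, :n_b]
        ha = np.zeros((c, n))
        np.put_along_axis(ha, sel_a, 1.0, axis=1)
        hb = np.zeros((c, n))
        np.put_along_axis(hb, sel_b, 1.0, axis=1)
        null[done : done + c] = _es_rows(wexp, ha) - _es_rows(wexp, hb)
        done += c
    p = (1.0 + int(np.sum(np.abs(null) >= abs(des)))) / (n_perm + 1.0)
    rec = TwoTailRecord(
        regulon.tf, network_id, signature_id, es_a, es_b, des, p, p_adj=p
    )
    rec.direction = _call_direction(rec, alpha)
    return rec


def _call_direction(rec: TwoTailRecord, alpha: float) -> str:
    if not np.isfinite(rec.des) or not np.isfinite(rec.p_adj) or rec.p_adj > alpha:
        return INCONCLUSIVE
    if rec.des > 0:
        return INDUCED
    if rec.des < 0:
        return REPRESSED
    return INCONCLUSIVE


def two_tailed_mra(
    regulons: Sequence[Regulon],
    signature: RankedSignature,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_tail: int = 5,
    seed: int = 0,
    network_id: str = "net",
    signature_id: str = "sig",
    exponent: float = 1.0,
) -> list[TwoTailRecord]:
    """Two-tailed GSEA over a regulon batch with BH adjustment.

    Records that failed the ``min_tail`` precondition stay inconclusive and
    are excluded from the adjustment.
    """
    records = [
        two_tailed_gsea(
            r, signature, n_perm, alpha, min_tail, seed, network_id, signature_id, exponent
        )
        for r in sorted(regulons, key=lambda r: r.tf)
    ]
    testable = [r for r in records if np.isfinite(r.p_perm)]
    if testable:
        adj = multipletests([r.p_perm for r in testable], method="fdr_bh")[1]
        for r, a in zip(testable, adj):
            r.p_adj = float(a)
            r.direction = _call_direction(r, alpha)
    return records


# ---------------------------------------------------------------------------
# consensus across networks x signatures
# ---------------------------------------------------------------------------

@dataclass
class ConsensusReport:
    """Per-TF significance across every network x signature combination.

    A TF is a *standard* consensus master regulator when its adjusted p is
    <= alpha in all combinations, and a *stringent* one at alpha_strict.
    TFs missing from a combination count as non-significant there.
    """

    combos: list[tuple[str, str]]
    records: dict[str, dict[tuple[str, str], EnrichmentRecord]]
    alpha: float
    alpha_strict: float
    flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def standard_tfs(self) -> list[str]:
        return sorted(self.flags.index[self.flags["consensus_standard"]])

    @property
    def stringent_tfs(self) -> list[str]:
        return sorted(self.flags.index[self.flags["consensus_stringent"]])

    def write_tsv(self, path: str | Path) -> None:
        out = self.flags.copy()
        out.index.name = "tf"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "alpha_strict": self.alpha_strict,
            "combos": ["::".join(c) for c in self.combos],
            "consensus_standard": self.standard_tfs,
            "consensus_stringent": self.stringent_tfs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def consensus(
    records: Sequence[EnrichmentRecord],
    alpha: float = 0.05,
    alpha_strict: float = 0.001,
) -> ConsensusReport:
    """Consensus master-regulator calls over all (network, signature) runs."""
    if not records:
        raise InvalidInputError("no enrichment records supplied")
    if alpha_strict > alpha:
        logger.warning("alpha_strict > alpha: stringent no longer implies standard")
    combos = sorted({(r.network_id, r.signature_id) for r in records})
    by_tf: dict[str, dict[tuple[str, str], EnrichmentRecord]] = {}
    for r in records:
        by_tf.setdefault(r.tf, {})[(r.network_id, r.signature_id)] = r

    rows = {}
    for tf in sorted(by_tf):
        padj = {
            c: by_tf[tf][c].p_adj if c in by_tf[tf] else float("nan") for c in combos
        }
        std = all(np.isfinite(padj[c]) and padj[c] <= alpha for c in combos)
        strict = all(np.isfinite(padj[c]) and padj[c] <= alpha_strict for c in combos)
        row = {f"p_adj[{n}::{s}]": padj[(n, s)] for n, s in combos}
        row["consensus_standard"] = std
        row["consensus_stringent"] = strict
        rows[tf] = row
    flags = pd.DataFrame.from_dict(rows, orient="index")
    return ConsensusReport(combos, by_tf, alpha, alpha_strict, flags)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[EnrichmentRecord | TwoTailRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_records_tsv(
    records: Sequence[EnrichmentRecord | TwoTailRecord], path: str | Path
) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")
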