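"""TF-centric relevance networks: CV filter, MI, permutation threshold,
bootstrap consensus and data-processing-inequality (DPI) pruning.

The inference path mirrors the classic mutual-information reverse
engineering recipe: score every TF-gene pair by plug-in MI, drop pairs
below a permutation-derived significance threshold, keep only edges that
are stable under bootstrap resampling of samples (the *relevance* network),
and finally remove the weakest edge of every TF-TF-target triplet (the
*DPI* network), which eliminates most likely-indirect interactions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError, InvalidStageError
from .expression import ExpressionMatrix
from .mi import MIEstimatorConfig, equal_frequency_codes, mi_profile, mutual_information

logger = logging.getLogger(__name__)

STAGE_RAW = "raw"
STAGE_RELEVANCE = "relevance"
STAGE_DPI = "dpi"


@dataclass
class MINetwork:
    """A weighted TF->gene edge set at one inference stage.

    ``edges`` has columns ``tf``, ``target``, ``mi``; TF-TF edges are stored
    once with the lexicographically smaller id in the ``tf`` column.  For a
    single run the edge sets satisfy ``dpi  ⊆  relevance  ⊆  raw``.
    """

    edges: pd.DataFrame
    stage: str
    tf_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in (STAGE_RAW, STAGE_RELEVANCE, STAGE_DPI):
            raise InvalidStageError(f"unknown network stage {self.stage!r}")
        e = self.edges
        if len(e) and (e["mi"] < 0).any():
            raise InvalidInputError("mi weights must be >= 0")
        if len(e) and (e["tf"] == e["target"]).any():
            raise InvalidInputError("self edges are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["target"]))

    def mi_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (t, g): m
            for t, g, m in zip(self.edges["tf"], self.edges["target"], self.edges["mi"])
        }

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        out = self.edges.copy()
        out["stage"] = self.stage
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.edges.itertuples(index=False):
                fh.write(f"{row.tf}\t{row.mi:.10g}\t{row.target}\n")


def read_network(path: str | Path) -> MINetwork:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    stage = df["stage"].iloc[0] if len(df) else STAGE_RELEVANCE
    tf_ids = sorted(df["tf"].unique().tolist())
    return MINetwork(df[["tf", "target", "mi"]], stage, tf_ids)


# ---------------------------------------------------------------------------
# CV filter
# ---------------------------------------------------------------------------

def filter_probes_cv(
    expr: ExpressionMatrix, keep_fraction: float, tf_ids: Sequence[str] = ()
) -> ExpressionMatrix:
    """Keep the ``keep_fraction`` of genes with the highest coefficient of
    variation (sd / |mean|), always retaining genes on the TF list.

    Genes with |mean| below 1e-12 get an infinite CV sentinel and are
    retained only if their sd is positive; zero-variance genes rank last.
    Ties break by row position (stable).  Row order is preserved.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise InvalidParameterError("keep_fraction must lie in (0, 1]")
    if expr.n_genes == 0:
        raise InvalidInputError("empty expression matrix")
    if keep_fraction == 1.0:
        return ExpressionMatrix(expr.values.copy(), expr.labels)

    x = expr.values.to_numpy(dtype=float)
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=1)
    eps = 1e-12
    score = np.empty(len(means))
    for i, (m, s) in enumerate(zip(means, sds)):
        if s == 0.0:
            # constant gene: CV 0 when the mean is usable, unrankable otherwise
            score[i] = 0.0 if abs(m) >= eps else -np.inf
        elif abs(m) < eps:
            score[i] = np.inf
        else:
            score[i] = s / abs(m)

    n_keep = int(math.ceil(keep_fraction * expr.n_genes))
    order = sorted(range(expr.n_genes), key=lambda i: (-score[i], i))
    keep = set(order[:n_keep])
    tf_set = set(tf_ids)
    genes = expr.gene_ids
    kept = [g for i, g in enumerate(genes) if i in keep or g in tf_set]
    logger.info("CV filter kept %d of %d genes", len(kept), expr.n_genes)
    return expr.subset_genes(kept)


# ---------------------------------------------------------------------------
# internals shared by the MI-matrix stages
# ---------------------------------------------------------------------------

def _tf_indices(expr: ExpressionMatrix, tf_ids: Sequence[str]) -> list[int]:
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [t for t in tf_ids if t not in pos]
    if missing:
        raise InvalidInputError(f"TF ids absent from the matrix: {missing}")
    return [pos[t] for t in tf_ids]


def _mi_matrix(codes: np.ndarray, tf_idx: Sequence[int], n_bins: int) -> np.ndarray:
    """MI of every TF row against every gene row; self entries set to 0."""
    out = np.empty((len(tf_idx), codes.shape[0]))
    for k, ti in enumerate(tf_idx):
        out[k] = mi_profile(codes[ti], codes, n_bins)
        out[k, ti] = 0.0
    return np.maximum(out, 0.0)


def _assemble_edges(
    mask: np.ndarray,
    mi_full: np.ndarray,
    tf_ids: Sequence[str],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Build a deduplicated, deterministically ordered edge table.

    ``mask``/``mi_full`` are (n_tf, n_genes); TF-TF pairs are emitted once
    with the lexicographically smaller id first.
    """
    tf_row = {t: k for k, t in enumerate(tf_ids)}
    rows: list[tuple[str, str, float]] = []
    for k, tf in enumerate(tf_ids):
        for j in np.nonzero(mask[k])[0]:
            g = genes[j]
            if g == tf:
                continue
            if g in tf_row:
                if tf < g:  # store symmetric TF-TF edge once
                    rows.append((tf, g, float(mi_full[k, j])))
            else:
                rows.append((tf, g, float(mi_full[k, j])))
    df = pd.DataFrame(rows, columns=["tf", "target", "mi"])
    return df.sort_values(["tf", "target"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_mi_matrix(
    expr: ExpressionMatrix,
    tf_ids: Sequence[str],
    config: MIEstimatorConfig | None = None,
) -> MINetwork:
    """All TF-gene MI scores (stage ``raw``), including TF-TF edges."""
    config = config or MIEstimatorConfig()
    tf_idx = _tf_indices(expr, tf_ids)
    b = config.resolve_bins(expr.n_samples)
    codes = equal_frequency_codes(expr.values.to_numpy(dtype=float), b)
    mi_full = _mi_matrix(codes, tf_idx, b)
    mask = np.ones_like(mi_full, dtype=bool)
    for k, ti in enumerate(tf_idx):
        mask[k, ti] = False
    edges = _assemble_edges(mask, mi_full, list(tf_ids), expr.gene_ids)
    params = {"n_bins": b}
    return MINetwork(edges, STAGE_RAW, sorted(tf_ids), params)


def permutation_threshold(
    expr: ExpressionMatrix,
    tf_ids: Sequence[str],
    config: MIEstimatorConfig | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Global MI significance threshold from a permutation null.

    For each of ``n_perm`` draws a random gene row is sample-shuffled and
    scored against every TF row; the pooled null MI values give the
    (1 - alpha) nearest-rank quantile, used as a single minimum-MI
    threshold for all pairs.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError("alpha must lie in (0, 1)")
    config = config or MIEstimatorConfig()
    tf_idx = _tf_indices(expr, tf_ids)
    b = config.resolve_bins(expr.n_samples)
    codes = equal_frequency_codes(expr.values.to_numpy(dtype=float), b)
    tf_codes = codes[tf_idx]
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    null: list[np.ndarray] = []
    for _ in range(n_perm):
        gi = int(rng.integers(expr.n_genes))
        shuffled = codes[gi][rng.permutation(n)]
        null.append(mi_profile(shuffled, tf_codes, b))
    pooled = np.sort(np.concatenate(null))
    q = 1.0 - alpha
    k = max(1, int(math.ceil(q * pooled.size)))  # nearest-rank quantile
    return float(pooled[k - 1])


def bootstrap_consensus(
    expr: ExpressionMatrix,
    tf_ids: Sequence[str],
    config: MIEstimatorConfig | None = None,
    threshold: float = 0.0,
    n_boot: int = 1000,
    consensus_fraction: float = 0.95,
    seed: int = 0,
    null_alpha: float | None = None,
    n_null_per_boot: int = 30,
) -> MINetwork:
    """Bootstrap-consensus relevance network (stage ``relevance``).

    Samples (columns) are resampled with replacement ``n_boot`` times; an
    edge is kept iff its MI exceeds the pass threshold in at least
    ``consensus_fraction`` of the bootstraps.  Retained edges carry the MI
    computed on the full, unresampled matrix.

    Duplicated samples inflate the plug-in MI of independent pairs, so a
    null threshold calibrated on the unresampled matrix is too permissive
    inside a bootstrap.  With ``null_alpha`` set, each bootstrap therefore
    recalibrates its own pass threshold as the (1 - null_alpha)
    nearest-rank quantile of a within-bootstrap permutation null
    (``n_null_per_boot`` shuffled gene rows scored against all TFs), and
    the fixed ``threshold`` is additionally applied to the full-matrix MI.
    With ``null_alpha=None`` the fixed ``threshold`` alone is used in every
    bootstrap.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if not (0.0 < consensus_fraction <= 1.0):
        raise InvalidParameterError("consensus_fraction must lie in (0, 1]")
    if expr.n_samples < 8:
        raise InvalidInputError("bootstrap consensus requires >= 8 samples")
    config = config or MIEstimatorConfig()
    tf_idx = _tf_indices(expr, tf_ids)
    b = config.resolve_bins(expr.n_samples)
    x = expr.values.to_numpy(dtype=float)
    n = expr.n_samples

    codes_full = equal_frequency_codes(x, b)
    mi_full = _mi_matrix(codes_full, tf_idx, b)

    if null_alpha is not None and not (0.0 < null_alpha < 1.0):
        raise InvalidParameterError("null_alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_genes = x.shape[0]
    passes = np.zeros_like(mi_full, dtype=np.int64)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        codes_b = equal_frequency_codes(x[:, idx], b)
        mi_b = _mi_matrix(codes_b, tf_idx, b)
        thr_b = threshold
        if null_alpha is not None:
            null = []
            for _ in range(n_null_per_boot):
                gi = int(rng.integers(n_genes))
                shuffled = codes_b[gi][rng.permutation(n)]
                null.append(mi_profile(shuffled, codes_b[tf_idx], b))
            pooled = np.sort(np.concatenate(null))
            k = max(1, int(math.ceil((1.0 - null_alpha) * pooled.size)))
            thr_b = float(pooled[k - 1])
        passes += mi_b > thr_b
    need = consensus_fraction * n_boot - 1e-9
    mask = passes >= need
    if null_alpha is not None:
        mask &= mi_full > threshold
    for k, ti in enumerate(tf_idx):
        mask[k, ti] = False
    edges = _assemble_edges(mask, mi_full, list(tf_ids), expr.gene_ids)
    params = {
        "n_bins": b,
        "threshold": float(threshold),
        "n_boot": int(n_boot),
        "consensus_fraction": float(consensus_fraction),
        "seed": int(seed),
        "null_alpha": null_alpha,
        "n_null_per_boot": int(n_null_per_boot) if null_alpha is not None else None,
    }
    logger.info("bootstrap consensus kept %d edges", len(edges))
    return MINetwork(edges, STAGE_RELEVANCE, sorted(tf_ids), params)


def apply_dpi(net: MINetwork, tolerance: float = 0.0) -> MINetwork:
    """Remove likely-indirect TF-target edges via the data processing
    inequality (stage ``dpi``).

    For every triplet (TF1, TF2, g) whose three edges all exist, the
    TF-target edge ``e`` is marked for removal when
    ``mi(e) < min(other two) * (1 - tolerance)``.  All marks are computed
    against the input network and applied at once, so the result does not
    depend on traversal order.  TF-TF edges are never removed.  When the
    two TF-target edges tie as weakest, the lexicographically larger
    (tf, gene) pair is removed; a TF-target edge tying only with the TF-TF
    edge is removed itself.
    """
    if net.stage != STAGE_RELEVANCE:
        raise InvalidStageError(
            f"DPI expects a relevance-stage network, got {net.stage!r}"
        )
    if tolerance < 0:
        raise InvalidParameterError("tolerance must be >= 0")

    tf_set = set(net.tf_ids)
    tftf: dict[tuple[str, str], float] = {}
    tgt: dict[str, dict[str, float]] = {t: {} for t in net.tf_ids}
    for row in net.edges.itertuples(index=False):
        if row.target in tf_set:
            tftf[(row.tf, row.target)] = row.mi
        else:
            tgt[row.tf][row.target] = row.mi

    marked: set[tuple[str, str]] = set()
    factor = 1.0 - tolerance
    for (t1, t2), m_tt in sorted(tftf.items()):
        common = set(tgt[t1]) & set(tgt[t2])
        for g in sorted(common):
            m1, m2 = tgt[t1][g], tgt[t2][g]
            if m1 < min(m2, m_tt) * factor:
                marked.add((t1, g))
                continue
            if m2 < min(m1, m_tt) * factor:
                marked.add((t2, g))
                continue
            weak1 = m1 <= min(m2, m_tt) * factor
            weak2 = m2 <= min(m1, m_tt) * factor
            if weak1 and weak2:
                marked.add(max((t1, g), (t2, g)))
            elif weak1:
                marked.add((t1, g))
            elif weak2:
                marked.add((t2, g))

    keep = [
        (row.tf, row.target) not in marked for row in net.edges.itertuples(index=False)
    ]
    edges = net.edges.loc[keep].reset_index(drop=True)
    params = dict(net.params, tolerance=float(tolerance))
    logger.info("DPI removed %d of %d edges", len(net.edges) - len(edges), len(net.edges))
    return MINetwork(edges, STAGE_DPI, list(net.tf_ids), params)


__all__ = [
    "MINetwork",
    "MIEstimatorConfig",
    "mutual_information",
    "filter_probes_cv",
    "compute_mi_matrix",
    "permutation_threshold",
    "bootstrap_consensus",
    "apply_dpi",
    "read_network",
    "STAGE_RAW",
    "STAGE_RELEVANCE",
    "STAGE_DPI",
]
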