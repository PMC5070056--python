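"""Plug-in mutual information on equal-frequency bins.

The estimator discretises each variable into ``n_bins`` equal-frequency
bins (rank-based, stable tie-break by column position) and computes the
plug-in mutual information of the joint bin histogram in nats:

    MI = sum_ij p_ij * ln( p_ij / (p_i q_j) )

The default bin count is ``floor(sqrt(n))`` clamped to [2, 10], which keeps
expected counts per cell around sqrt(n) and the estimator deterministic and
cheap.  Constant vectors are mapped to a single bin, so their entropy -- and
any MI involving them -- is exactly zero.

``mi_profile`` computes one row of TF-versus-all-genes MI from precomputed
bin codes with a single flat ``bincount``, which is what makes bootstrap
and permutation loops affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Configuration of the discrete plug-in MI estimator.

    ``n_bins="auto"`` resolves to ``floor(sqrt(n_samples))`` clamped to
    [2, 10].  The log base is natural (nats).
    """

    n_bins: Union[int, str] = "auto"

    def __post_init__(self) -> None:
        if self.n_bins != "auto":
            if not isinstance(self.n_bins, (int, np.integer)) or self.n_bins < 2:
                raise InvalidParameterError("n_bins must be 'auto' or an int >= 2")

    def resolve_bins(self, n_samples: int) -> int:
        if self.n_bins == "auto":
            return int(np.clip(int(np.sqrt(n_samples)), 2, 10))
        return int(self.n_bins)


def equal_frequency_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Row-wise equal-frequency bin codes in {0, ..., n_bins-1}.

    ``x`` may be 1-D (one variable) or 2-D (variables x samples).  Ties are
    broken by sample position (stable sort), so codes are deterministic.
    Constant rows receive code 0 everywhere.
    """
    arr = np.asarray(x, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    n = arr.shape[1]
    order = np.argsort(arr, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(n), arr.shape), axis=1)
    codes = (ranks * n_bins) // n
    const = arr.max(axis=1) == arr.min(axis=1)
    if const.any():
        codes[const] = 0
    codes = codes.astype(np.int32)
    return codes[0] if squeeze else codes


def mi_from_joint(counts: np.ndarray) -> float:
    """Plug-in MI (nats) of one 2-D contingency table of counts."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    denom = px * py
    ratio = np.where(mask, p / np.where(denom > 0, denom, 1.0), 1.0)
    return float(np.sum(np.where(mask, p * np.log(ratio), 0.0)))


def mi_profile(ref_codes: np.ndarray, codes: np.ndarray, n_bins: int) -> np.ndarray:
    """MI between one reference code vector and every row of ``codes``.

    Returns an array of length ``codes.shape[0]``.  Uses a single flat
    bincount over joint codes, so the cost is O(n_genes * n_samples).
    """
    g, n = codes.shape
    b2 = n_bins * n_bins
    joint = ref_codes[None, :].astype(np.int64) * n_bins + codes
    joint += (np.arange(g, dtype=np.int64) * b2)[:, None]
    counts = np.bincount(joint.ravel(), minlength=g * b2).reshape(g, n_bins, n_bins)

    p = counts / n
    px = p.sum(axis=2, keepdims=True)  # marginal of the reference variable
    py = p.sum(axis=1, keepdims=True)  # marginal of each gene
    mask = p > 0
    denom = px * py
    ratio = np.where(mask, p / np.where(denom > 0, denom, 1.0), 1.0)
    return np.where(mask, p * np.log(ratio), 0.0).sum(axis=(1, 2))


def mutual_information(
    x: np.ndarray, y: np.ndarray, config: MIEstimatorConfig | None = None
) -> float:
    """Plug-in MI (nats) between two sample vectors.

    Symmetric in its arguments; bounded by the binned marginal entropies;
    returns 0 for a constant vector.  Requires at least 8 samples.
    """
    config = config or MIEstimatorConfig()
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise InvalidInputError("x and y must be 1-D sample vectors")
    if xa.shape[0] != ya.shape[0]:
        raise InvalidInputError("x and y must have the same length")
    if xa.shape[0] < 8:
        raise InvalidInputError("at least 8 samples required")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise InvalidInputError("inputs must be finite")
    b = config.resolve_bins(xa.shape[0])
    cx = equal_frequency_codes(xa, b)
    cy = equal_frequency_codes(ya, b)
    counts = np.bincount(cx.astype(np.int64) * b + cy, minlength=b * b).reshape(b, b)
    return max(0.0, mi_from_joint(counts))
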