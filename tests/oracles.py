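"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive (nested loops, explicit tables) and share no
code with the package beyond the documented conventions they check:
equal-frequency binning with stable tie-break, the weakest-edge triplet
rule, and the weighted running-sum enrichment statistic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def bin_codes(x, n_bins):
    """Equal-frequency bin codes; ordinal ranks (stable ties), constants -> 0."""
    x = np.asarray(x, dtype=float)
    if x.max() == x.min():
        return np.zeros(len(x), dtype=int)
    ranks = rankdata(x, method="ordinal") - 1  # 0-based, stable
    return (ranks * n_bins) // len(x)


def mi_bruteforce(x, y, n_bins):
    """Plug-in MI (nats) from an explicitly tabulated joint count table."""
    cx = bin_codes(x, n_bins)
    cy = bin_codes(y, n_bins)
    n = len(cx)
    joint = [[0] * n_bins for _ in range(n_bins)]
    for a, b in zip(cx, cy):
        joint[a][b] += 1
    px = [sum(row) / n for row in joint]
    py = [sum(joint[i][j] for i in range(n_bins)) / n for j in range(n_bins)]
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            p = joint[i][j] / n
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    return mi


def dpi_bruteforce(edges, tf_ids, tolerance=0.0):
    """Edges marked for removal by the weakest-edge triplet rule.

    ``edges``: dict (tf, target) -> mi, with TF-TF pairs stored once with
    the smaller id first.  Returns the set of removed (tf, target) pairs.
    Ties: two tied TF-target edges -> remove the lexicographically larger
    pair; a TF-target edge tied only with the TF-TF edge -> remove it.
    """
    tf_set = set(tf_ids)
    removed = set()
    factor = 1.0 - tolerance
    for t1 in tf_ids:
        for t2 in tf_ids:
            if t2 <= t1:
                continue
            m_tt = edges.get((t1, t2))
            if m_tt is None:
                continue
            for (tf, g), _ in list(edges.items()):
                if tf != t1 or g in tf_set:
                    continue
                if (t2, g) not in edges:
                    continue
                m1 = edges[(t1, g)]
                m2 = edges[(t2, g)]
                if m1 < min(m2, m_tt) * factor:
                    removed.add((t1, g))
                elif m2 < min(m1, m_tt) * factor:
                    removed.add((t2, g))
                else:
                    weak1 = m1 <= min(m2, m_tt) * factor
                    weak2 = m2 <= min(m1, m_tt) * factor
                    if weak1 and weak2:
                        removed.add(max((t1, g), (t2, g)))
                    elif weak1:
                        removed.add((t1, g))
                    elif weak2:
                        removed.add((t2, g))
    return removed


def es_bruteforce(genes, weights, hit_set, exponent):
    """Weighted KS running sum, computed step by step in pure Python."""
    n = len(genes)
    hit_set = set(hit_set)
    n_hits = len(hit_set)
    denom_hit = sum(abs(w) ** exponent for g, w in zip(genes, weights) if g in hit_set)
    running = 0.0
    best = 0.0
    for g, w in zip(genes, weights):
        if g in hit_set:
            if denom_hit > 0:
                running += abs(w) ** exponent / denom_hit
            else:
                running += 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def welch_t_bruteforce(case, ctrl):
    """Closed-form Welch t statistic for one gene."""
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    va = case.var(ddof=1) / len(case)
    vb = ctrl.var(ddof=1) / len(ctrl)
    return (case.mean() - ctrl.mean()) / math.sqrt(va + vb)
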