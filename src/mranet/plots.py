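"""Optional static plots: enrichment running-sum profiles and the regulon
association map.  Imported lazily by the CLI ``report`` command."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .enrich import _es_rows
from .regulons import AssociationMap
from .signature import RankedSignature


def plot_enrichment_profile(
    signature: RankedSignature,
    hit_set: Iterable[str],
    path: str | Path,
    signed: bool = True,
    exponent: float = 1.0,
    title: str = "",
) -> None:
    """Running-sum enrichment profile with hit ticks, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes, weights = (
        signature.signed_order() if signed else signature.absolute_order()
    )
    hit_set = set(hit_set)
    ind = np.fromiter((1.0 if g in hit_set else 0.0 for g in genes), float)
    wexp = np.abs(weights) ** exponent
    n = len(genes)
    hit_w = ind * wexp
    inc = hit_w / hit_w.sum() if hit_w.sum() > 0 else ind / ind.sum()
    dec = (1.0 - ind) / (n - ind.sum())
    running = np.cumsum(inc - dec)
    es = float(_es_rows(wexp, ind[None, :])[0])

    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(6, 4), sharex=True, height_ratios=[3, 1]
    )
    ax1.plot(np.arange(1, n + 1), running, color="tab:green")
    ax1.axhline(0.0, color="grey", lw=0.5)
    ax1.set_ylabel("running enrichment")
    ax1.set_title(title or f"ES = {es:.3f}")
    hits = np.nonzero(ind)[0] + 1
    ax2.vlines(hits, 0, 1, color="black", lw=0.5)
    ax2.set_yticks([])
    ax2.set_xlabel("rank in phenotype")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_association_map(
    amap: AssociationMap, path: str | Path, seed: int = 0
) -> None:
    """Regulon association map: node size = regulon size, edge width = Jaccard."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.Graph()
    for tf, size in amap.nodes.items():
        g.add_node(tf, size=size)
    for row in amap.edges.itertuples(index=False):
        g.add_edge(row.tf1, row.tf2, jaccard=row.jaccard)
    pos = nx.spring_layout(g, seed=seed)
    sizes = [40 + 4 * g.nodes[n]["size"] for n in g.nodes]
    widths = [6 * g.edges[e]["jaccard"] for e in g.edges]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(
        g, pos, ax=ax, node_size=sizes, width=widths, font_size=7,
        node_color="tab:blue", alpha=0.85,
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
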