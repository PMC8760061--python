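"""Thresholded Pearson co-expression network and degree centrality.

Expression is log2(RPKM + 1)-transformed, all pairwise Pearson correlations
are computed, and an edge connects two genes when signed r >= threshold
(default 0.7, positive co-expression only).  Degree centrality is the raw
neighbor count; display edge weights rescale r linearly over a window
(default [0.5, 1]).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CorrelationNetwork",
    "log_transform",
    "pearson_network",
    "degree_table",
    "degree_and_neighbors",
    "edge_weight_scaling",
]


@dataclass
class CorrelationNetwork:
    genes: list[str]
    r_matrix: pd.DataFrame
    threshold: float
    graph: nx.Graph
    dropped_zero_variance: tuple[str, ...] = ()


def log_transform(x: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); rejects negative expression values."""
    vals = x.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("expression values must be nonnegative")
    return pd.DataFrame(np.log2(vals + 1.0), index=x.index, columns=x.columns)


def pearson_network(x: pd.DataFrame, threshold: float = 0.7) -> CorrelationNetwork:
    """All-pairs Pearson network on an already log-transformed matrix.

    Rows are genes, columns samples.  Zero-variance genes are dropped (and
    reported on the result) rather than failing the run; an edge is present
    where signed r >= threshold, self-edges excluded.
    """
    if x.shape[1] < 3:
        raise ValidationError("pearson_network requires >= 3 samples")
    vals = x.to_numpy(dtype=float)
    variances = vals.var(axis=1)
    keep = variances > 0
    dropped = tuple(x.index[~keep])
    vals = vals[keep]
    genes = list(x.index[keep])
    if len(genes) < 2:
        raise ValidationError("fewer than 2 genes with nonzero variance")
    r = np.corrcoef(vals)
    r_df = pd.DataFrame(r, index=genes, columns=genes)

    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    sel = r[iu, ju] >= threshold
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(r[i, j])) for i, j in zip(iu[sel], ju[sel])
    )
    return CorrelationNetwork(
        genes=genes,
        r_matrix=r_df,
        threshold=threshold,
        graph=g,
        dropped_zero_variance=dropped,
    )


def degree_table(net: CorrelationNetwork) -> pd.DataFrame:
    """Degree centrality (raw neighbor count) for every gene."""
    rows = [
        {"gene": g, "degree": net.graph.degree(g)} for g in net.genes
    ]
    return pd.DataFrame(rows).set_index("gene")


def degree_and_neighbors(net: CorrelationNetwork, focal: str) -> tuple[int, set[str]]:
    """Degree and direct-neighbor set of one gene."""
    if focal not in net.graph:
        close = difflib.get_close_matches(focal, net.genes, n=3)
        raise ValidationError(
            f"gene {focal!r} not in the network; closest labels: {close}"
        )
    neighbors = set(net.graph.neighbors(focal))
    return len(neighbors), neighbors


def edge_weight_scaling(net: CorrelationNetwork, w_min_r: float = 0.5) -> pd.DataFrame:
    """Per-edge display weights: (r - w_min_r)/(1 - w_min_r), clipped to [0, 1]."""
    if w_min_r >= 1:
        raise ValidationError("w_min_r must be < 1")
    rows = []
    for a, b, data in net.graph.edges(data=True):
        r = float(data["weight"])
        w = float(np.clip((r - w_min_r) / (1.0 - w_min_r), 0.0, 1.0))
        rows.append({"gene_a": a, "gene_b": b, "r": r, "weight": w})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "weight"])
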