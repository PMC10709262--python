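"""Dimensionality reduction, SNN graph construction and Louvain communities.

The default clustering input is the top principal components of the residual
matrix. Neighbourhoods are the k nearest cells by Euclidean distance plus
the cell itself; two cells are connected iff their neighbourhoods intersect,
with Jaccard overlap of the neighbourhoods as edge weight.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger("scstate")


def pca(values: np.ndarray, n_pcs: int, scale_genes: bool = False
        ) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of a genes x cells matrix.

    Genes are centred (and optionally scaled to unit variance) across cells;
    the SVD sign is fixed so each component's largest-magnitude gene loading
    is positive, making the embedding deterministic.

    Returns ``(embedding, explained_variance)`` with embedding of shape
    (n_cells, n_pcs) and variances in decreasing order.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    if n_pcs >= min(n_genes, n_cells):
        raise ValueError(f"n_pcs={n_pcs} too large for {n_genes} genes x {n_cells} cells")
    X = values.T - values.mean(axis=1)  # cells x genes, centred per gene
    if scale_genes:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    u, vt = u * signs, vt * signs[:, None]
    emb = (u * s)[:, :n_pcs]
    explained = (s**2 / (n_cells - 1))[:n_pcs] if n_cells > 1 else s[:n_pcs] ** 2
    logger.info("pca: %d cells x %d genes -> %d components", n_cells, n_genes, n_pcs)
    return emb, explained


def knn_neighbourhoods(emb: np.ndarray, k: int) -> np.ndarray:
    """Boolean membership matrix of k-neighbourhoods (self included).

    Row i marks the k nearest other points by Euclidean distance (ties broken
    by point index) plus point i itself.
    """
    n = emb.shape[0]
    if k <= 0:
        raise ValueError("k must be > 0")
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    d = cdist(emb, emb)
    np.fill_diagonal(d, np.inf)  # self excluded from the k nearest, re-added below
    order = np.argsort(d, axis=1, kind="stable")
    member = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    member[rows, order[:, :k].ravel()] = True
    member[np.arange(n), np.arange(n)] = True
    return member


def build_snn_graph(emb: np.ndarray, k: int) -> nx.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Edge between i and j iff their k-neighbourhoods (including self) share at
    least one member; weight = |N(i) & N(j)| / |N(i) | N(j)|. The graph is
    undirected, has no self-loops, and all weights lie in (0, 1].
    """
    member = knn_neighbourhoods(np.asarray(emb, dtype=float), k)
    n = member.shape[0]
    inter = member.astype(np.int32) @ member.astype(np.int32).T
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(inter, 1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(i, j, weight=float(inter[i, j] / union[i, j]))
    logger.info("build_snn_graph: %d nodes, %d edges, k=%d", n, g.number_of_edges(), k)
    return g


def louvain(graph: nx.Graph, seed: int = 0) -> tuple[np.ndarray, float]:
    """Weighted-modularity Louvain communities with a seeded sweep order.

    Returns ``(labels, modularity)``. Labels are contiguous integers from 0,
    renumbered by each community's smallest node index so a fixed seed gives
    identical labels. An edgeless graph yields singleton communities.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        logger.warning("louvain: graph has no edges; every node is its own cluster")
        labels = np.arange(graph.number_of_nodes())
        return labels, 0.0
    communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    communities = sorted(communities, key=min)
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for cid, nodes in enumerate(communities):
        for node in nodes:
            labels[node] = cid
    mod = nx.community.modularity(graph, communities, weight="weight")
    logger.info("louvain: %d communities, modularity %.4f (seed=%d)",
                len(communities), mod, seed)
    return labels, float(mod)


def composition_table(labels: np.ndarray, annotations: pd.DataFrame
                      ) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame],
                                 pd.DataFrame, pd.Series]:
    """Cluster x annotation contingency summaries and Shannon entropies.

    For each annotation column, builds per-cluster counts and fractions
    (fractions sum to 1 within a cluster) and the per-cluster Shannon entropy
    in nats. Returns ``(counts, fractions, entropy, mean_entropy)`` where
    entropy is a clusters x annotations frame and mean_entropy its
    column-wise mean.
    """
    labels = np.asarray(labels)
    if len(annotations) != len(labels):
        raise ValueError("annotations must cover all cells")
    counts: dict[str, pd.DataFrame] = {}
    fractions: dict[str, pd.DataFrame] = {}
    entropies: dict[str, pd.Series] = {}
    for col in annotations.columns:
        ct = pd.crosstab(pd.Series(labels, name="cluster"), annotations[col].to_numpy())
        frac = ct.div(ct.sum(axis=1), axis=0)
        counts[col], fractions[col] = ct, frac
        p = frac.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        entropies[col] = pd.Series(-(p * logp).sum(axis=1), index=frac.index)
    entropy = pd.DataFrame(entropies)
    return counts, fractions, entropy, entropy.mean(axis=0)


__all__ = ["pca", "knn_neighbourhoods", "build_snn_graph", "louvain", "composition_table"]
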