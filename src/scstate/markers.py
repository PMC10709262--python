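"""Pairwise cluster markers with Holm correction and the "some" combined p.

For each target cluster, every gene is Welch-t-tested against every other
cluster. Per gene, the m pairwise p-values are Holm-corrected, and the
combined p is the k-th smallest corrected value with k = ceil(min_prop * m):
small iff the gene is differential in at least a min_prop fraction of the
comparisons. The summary logFC is taken from the comparison whose corrected
p equals the combined p (ties resolved to the largest absolute logFC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("scstate")


def pairwise_tests(values: np.ndarray, labels: np.ndarray,
                   ) -> tuple[list[int], dict[tuple[int, int], pd.DataFrame]]:
    """Welch two-sample t-test per gene for every ordered cluster pair.

    ``values`` is genes x cells; ``labels`` assigns each cell a cluster id.
    For the ordered pair (a, b): logFC = mean_a - mean_b on the input scale.
    Genes with zero variance in both groups get p = 1 and logFC = 0.
    Returns the sorted cluster ids and a frame (columns ``p``, ``logfc``) per
    ordered pair. Singleton clusters are an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ids = sorted(set(labels.tolist()))
    sizes = {c: int((labels == c).sum()) for c in ids}
    singletons = [c for c, n in sizes.items() if n < 2]
    if singletons:
        raise ValueError(
            f"clusters with < 2 cells: {singletons}; merge or exclude them before testing"
        )

    means, variances = {}, {}
    for c in ids:
        sub = values[:, labels == c]
        means[c] = sub.mean(axis=1)
        variances[c] = sub.var(axis=1, ddof=1)

    out: dict[tuple[int, int], pd.DataFrame] = {}
    for a in ids:
        for b in ids:
            if a == b:
                continue
            na, nb = sizes[a], sizes[b]
            va, vb = variances[a] / na, variances[b] / nb
            diff = means[a] - means[b]
            denom = np.sqrt(va + vb)
            both_flat = (variances[a] == 0.0) & (variances[b] == 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / denom
                df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            p = np.ones_like(diff)
            ok = ~both_flat
            p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
            logfc = np.where(both_flat, 0.0, diff)
            out[(a, b)] = pd.DataFrame({"p": p, "logfc": logfc})
    return ids, out


def holm_correct(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a p-value vector.

    adj_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the ascending
    order, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("holm_correct expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(scaled)
    adj = np.empty_like(p)
    adj[order] = adj_sorted
    return adj


def combine_some(holm_p: np.ndarray, min_prop: float = 0.2,
                 rule: str = "some") -> tuple[np.ndarray, np.ndarray]:
    """Combine Holm-corrected p-values across the m comparisons of each gene.

    ``holm_p`` is genes x m. Under the default "some" rule the combined p of
    a gene is its k-th smallest corrected p with k = max(1, ceil(min_prop*m)).
    The "any" rule (k = 1, the literal minimum) is available for comparison.

    Returns ``(combined, which)`` where ``which`` is the column index of the
    comparison attaining the combined value (first occurrence).
    """
    holm_p = np.atleast_2d(np.asarray(holm_p, dtype=float))
    m = holm_p.shape[1]
    if m < 1:
        raise ValueError("need at least one comparison")
    if not 0.0 < min_prop <= 1.0:
        raise ValueError("min_prop must lie in (0, 1]")
    if rule == "some":
        k = max(1, math.ceil(min_prop * m))
    elif rule == "any":
        k = 1
    else:
        raise ValueError(f"unknown rule {rule!r}")
    part = np.sort(holm_p, axis=1)
    combined = part[:, k - 1]
    which = np.argmax(holm_p == combined[:, None], axis=1)
    return combined, which


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty_like(p)
    adj[order] = adj_sorted
    return adj


def _marker_table(pair_frames: dict[tuple[int, int], pd.DataFrame], target: int,
                  others: list[int], genes: list[str], min_prop: float,
                  rule: str, summary: str) -> pd.DataFrame:
    m = len(others)
    raw = np.column_stack([pair_frames[(target, b)]["p"].to_numpy() for b in others])
    lfc = np.column_stack([pair_frames[(target, b)]["logfc"].to_numpy() for b in others])
    holm = np.vstack([holm_correct(raw[i]) for i in range(raw.shape[0])])
    combined, which = combine_some(holm, min_prop, rule)
    # summary logFC: comparison whose Holm p equals the combined p; on ties
    # pick the largest |logFC| among the attaining comparisons
    summary_lfc = np.empty(len(genes))
    for i in range(len(genes)):
        attain = np.flatnonzero(holm[i] == combined[i])
        summary_lfc[i] = lfc[i, attain[np.argmax(np.abs(lfc[i, attain]))]]
    if summary == "mean":
        summary_lfc = lfc.mean(axis=1)
    fdr = bh_adjust(combined)
    df = pd.DataFrame({
        "gene": genes, "combined_p": combined, "fdr": fdr, "summary_logfc": summary_lfc,
    })
    for j, b in enumerate(others):
        df[f"p_vs_{b}"] = raw[:, j]
        df[f"holm_vs_{b}"] = holm[:, j]
        df[f"logfc_vs_{b}"] = lfc[:, j]
    return df


def find_markers(values: np.ndarray, labels: np.ndarray, genes: list[str],
                 min_prop: float = 0.2, rule: str = "some",
                 summary: str = "representative") -> dict[int, pd.DataFrame]:
    """Full marker table per cluster: pairwise tests, Holm, combined p, FDR.

    FDR is Benjamini-Hochberg over the combined p-values within each cluster.
    Genes are returned ranked by summary logFC, descending.
    """
    ids, pair_frames = pairwise_tests(values, labels)
    if len(ids) < 2:
        raise ValueError("need >= 2 clusters for marker detection")
    out: dict[int, pd.DataFrame] = {}
    for target in ids:
        others = [b for b in ids if b != target]
        df = _marker_table(pair_frames, target, others, genes, min_prop, rule, summary)
        out[target] = df.sort_values("summary_logfc", ascending=False, kind="stable",
                                     ignore_index=True)
    logger.info("find_markers: %d clusters x %d genes, min_prop=%.2f rule=%s",
                len(ids), len(genes), min_prop, rule)
    return out


def rank_and_select(marker_df: pd.DataFrame, fdr_thr: float = 0.05,
                    top_n: int = 250, direction: str = "up") -> pd.DataFrame:
    """Top-N significant genes of one cluster by summary logFC.

    Keeps genes with FDR < ``fdr_thr``; "up" returns the top_n largest
    positive summary logFCs, "down" the top_n most negative, "both" the
    concatenation. Returns all available rows (with a warning) if fewer than
    ``top_n`` pass.
    """
    sig = marker_df[marker_df["fdr"] < fdr_thr]
    if direction == "up":
        sel = sig[sig["summary_logfc"] > 0].sort_values(
            "summary_logfc", ascending=False, kind="stable")
    elif direction == "down":
        sel = sig[sig["summary_logfc"] < 0].sort_values(
            "summary_logfc", ascending=True, kind="stable")
    elif direction == "both":
        up = rank_and_select(marker_df, fdr_thr, top_n, "up")
        down = rank_and_select(marker_df, fdr_thr, top_n, "down")
        return pd.concat([up, down], ignore_index=True)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if len(sel) < top_n:
        logger.warning("rank_and_select: only %d genes available for top_n=%d (%s)",
                       len(sel), top_n, direction)
    return sel.head(top_n).reset_index(drop=True)


def ranked_list(marker_df: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """(genes, scores) ordered by summary logFC descending — RNK input for enrichment."""
    df = marker_df.sort_values("summary_logfc", ascending=False, kind="stable")
    return df["gene"].tolist(), df["summary_logfc"].to_numpy()


__all__ = ["pairwise_tests", "holm_correct", "combine_some", "bh_adjust",
           "find_markers", "rank_and_select", "ranked_list"]
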