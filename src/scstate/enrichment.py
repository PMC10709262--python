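"""Preranked geneset enrichment (ES/NES) and NES-based superclusters.

The enrichment score is the signed maximum deviation of the weighted
Kolmogorov-Smirnov running sum over a ranked gene list: hits increment by
|score|^weight_exp (normalized over hits), misses decrement by 1/(N - Nh).
NES normalizes ES against random same-size genesets drawn from the ranked
genes (gene-permutation null). Clusters are grouped into superclusters by
average-linkage hierarchical clustering in NES space over the top-|NES|
genesets, and supercluster-specific up-signatures are extracted by contrast
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

logger = logging.getLogger("scstate")


@dataclass
class RankedList:
    """Genes ordered by score, descending; scores attached."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be in descending order")


def enrichment_score(ranked: RankedList, geneset: set[str] | list[str],
                     weight_exp: float = 1.0) -> tuple[float, np.ndarray]:
    """Signed maximum deviation of the running sum; returns (ES, running sum).

    Genes of the set absent from the list are ignored; a set with no gene in
    the list is an error. If every ranked gene is a hit there are no misses
    and ES is +1 by convention.
    """
    if weight_exp < 0:
        raise ValueError("weight_exp must be >= 0")
    members = set(geneset)
    hits = np.array([g in members for g in ranked.genes])
    n, nh = hits.size, int(hits.sum())
    if nh == 0:
        raise ValueError("geneset has no gene in the ranked list")
    weights = np.abs(ranked.scores) ** weight_exp
    hit_total = weights[hits].sum()
    if hit_total == 0.0:
        steps_hit = np.full(n, 1.0 / nh)  # all hit scores zero: equal weights
    else:
        steps_hit = weights / hit_total
    if nh == n:
        running = np.cumsum(steps_hit)
        return 1.0, running
    steps = np.where(hits, steps_hit, -1.0 / (n - nh))
    running = np.cumsum(steps)
    extreme = int(np.argmax(np.abs(running)))
    return float(running[extreme]), running


def _null_es(scores: np.ndarray, set_size: int, n_perm: int,
             weight_exp: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized ES of random same-size genesets (the permutation null).

    The running sum is only evaluated at positions adjacent to hits: its
    local maxima sit immediately after a hit and local minima immediately
    before one, which is where the signed maximum deviation must occur.
    """
    n = scores.size
    k = set_size
    w = np.abs(scores) ** weight_exp
    # sorted hit positions per permutation
    pos = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = np.sort(rng.choice(n, size=k, replace=False))
    hw = w[pos]
    totals = hw.sum(axis=1, keepdims=True)
    flat = totals[:, 0] == 0.0
    hw = np.where(flat[:, None], 1.0 / k, hw / np.where(totals == 0.0, 1.0, totals))
    cum = np.cumsum(hw, axis=1)
    miss = 1.0 / (n - k)
    i1 = np.arange(1, k + 1)
    after = cum - (pos + 1 - i1) * miss                 # just after each hit
    before = cum - hw - (pos - (i1 - 1)) * miss         # just before each hit
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def nes_and_p(ranked: RankedList, geneset: set[str] | list[str], n_perm: int = 2000,
              seed: int = 0, weight_exp: float = 1.0) -> dict[str, float]:
    """ES with permutation NES and p-value against a gene-permutation null.

    NES = ES / mean(|null ES| with matching sign);
    p = (1 + #{matching-sign nulls with |null| >= |ES|}) / (1 + #matching-sign).
    Deterministic for fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = [g for g in dict.fromkeys(geneset) if g in set(ranked.genes)]
    es, _ = enrichment_score(ranked, members, weight_exp)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.scores, len(members), n_perm, weight_exp, rng)
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones_like(null, bool)
    n_same = int(same_sign.sum())
    if n_same == 0:
        logger.warning("nes_and_p: no matching-sign null ES values; p set to 1")
        nes = 0.0
        n_extreme = 0
    else:
        nes = es / np.abs(null[same_sign]).mean()
        # 1e-12 slack: null ES comes from a closed-form evaluation that can
        # differ from the running-sum walk by float rounding at exact ties
        n_extreme = int((np.abs(null[same_sign]) >= abs(es) - 1e-12).sum())
    p = (1 + n_extreme) / (1 + n_same)
    return {"es": es, "nes": float(nes), "p": float(p),
            "n_more_extreme": n_extreme, "n_permutations": n_perm}


def run_enrichment(rankings: dict[object, RankedList], genesets, n_perm: int = 2000,
                   seed: int = 0, weight_exp: float = 1.0) -> pd.DataFrame:
    """ES/NES/p for every (cluster, geneset) pair.

    Per-pair RNG streams are derived from ``seed`` and the pair's position so
    results are independent of iteration order. Genesets with no gene in a
    ranking are skipped with a warning.
    """
    rows = []
    for ci, (cluster, ranked) in enumerate(sorted(rankings.items(), key=lambda kv: str(kv[0]))):
        gene_pool = set(ranked.genes)
        for gi, (name, members) in enumerate(genesets.items()):
            if not gene_pool.intersection(members):
                logger.warning("run_enrichment: geneset %s absent from cluster %s ranking",
                               name, cluster)
                continue
            pair_seed = seed * 100_003 + ci * 1_009 + gi
            res = nes_and_p(ranked, members, n_perm=n_perm, seed=pair_seed,
                            weight_exp=weight_exp)
            rows.append({"cluster": cluster, "geneset": name, **res})
    return pd.DataFrame(rows)


def top_genesets(results: pd.DataFrame, n: int = 25) -> list[str]:
    """The n genesets with largest max |NES| across clusters.

    Ties break lexicographically by geneset name. Returns all genesets with
    a warning when n exceeds the number available.
    """
    if results.empty:
        raise ValueError("empty enrichment results")
    best = results.groupby("geneset")["nes"].apply(lambda s: float(np.max(np.abs(s))))
    ordered = best.sort_index().sort_values(ascending=False, kind="stable")
    if n > len(ordered):
        logger.warning("top_genesets: requested %d of %d genesets", n, len(ordered))
    return ordered.index[:min(n, len(ordered))].tolist()


def nes_matrix(results: pd.DataFrame, genesets: list[str]) -> pd.DataFrame:
    """Clusters x genesets NES matrix (missing pairs filled with 0)."""
    wide = results.pivot(index="cluster", columns="geneset", values="nes")
    return wide.reindex(columns=genesets).fillna(0.0)


def assign_superclusters(nes: pd.DataFrame, n_super: int = 3,
                         proliferation_sets: list[str] | None = None
                         ) -> tuple[pd.Series, np.ndarray]:
    """Group clusters by average-linkage hierarchical clustering in NES space.

    Cuts the tree into ``n_super`` groups and labels them A, B, C, ... by
    dendrogram leaf order, or by increasing mean NES over
    ``proliferation_sets`` when given. Returns ``(labels, linkage_matrix)``.
    """
    if n_super > len(nes):
        raise ValueError(f"n_super={n_super} exceeds {len(nes)} clusters")
    X = nes.to_numpy(dtype=float)
    if len(nes) == n_super:
        groups = np.arange(1, n_super + 1)
        Z = linkage(X, method="average", metric="euclidean") if len(nes) > 1 else np.empty((0, 4))
    else:
        Z = linkage(X, method="average", metric="euclidean")
        groups = fcluster(Z, t=n_super, criterion="maxclust")

    if proliferation_sets:
        present = [g for g in proliferation_sets if g in nes.columns]
        score = {g: nes.loc[groups == g, present].to_numpy().mean()
                 for g in np.unique(groups)}
        order = sorted(score, key=lambda g: score[g])
    else:
        if len(nes) > 1 and Z.shape[0] > 0:
            leaf_order = leaves_list(Z)
            seen: list[int] = []
            for leaf in leaf_order:
                if groups[leaf] not in seen:
                    seen.append(groups[leaf])
            order = seen
        else:
            order = list(np.unique(groups))
    letter = {g: chr(ord("A") + i) for i, g in enumerate(order)}
    labels = pd.Series([letter[g] for g in groups], index=nes.index, name="supercluster")
    logger.info("assign_superclusters: %d clusters -> %d superclusters", len(nes), n_super)
    return labels, Z


def supercluster_signatures(up_lists: dict[tuple[str, str], list[str]]
                            ) -> dict[str, list[str]]:
    """Per-supercluster exclusive upregulated genes from pairwise contrasts.

    ``up_lists[(X, Y)]`` is the list of genes upregulated in X versus Y.
    Supercluster X's signature contains the genes present in every X-vs-*
    list and absent from every other supercluster's up-lists. Order follows
    X's first contrast list. Signatures are pairwise disjoint by construction.
    """
    supers = sorted({x for x, _ in up_lists} | {y for _, y in up_lists})
    signatures: dict[str, list[str]] = {}
    for x in supers:
        own = [up_lists[(x, y)] for y in supers if y != x and (x, y) in up_lists]
        if not own:
            signatures[x] = []
            continue
        common = set(own[0])
        for lst in own[1:]:
            common &= set(lst)
        others = set()
        for (a, _), lst in up_lists.items():
            if a != x:
                others.update(lst)
        sig = [g for g in own[0] if g in common and g not in others]
        if not sig:
            logger.warning("supercluster_signatures: empty signature for %s", x)
        signatures[x] = sig
    return signatures


__all__ = ["RankedList", "enrichment_score", "nes_and_p", "run_enrichment",
           "top_genesets", "nes_matrix", "assign_superclusters",
           "supercluster_signatures"]
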