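"""End-to-end orchestration of the inference chain on one dataset.

simulate (or load) -> QC -> cell-cycle calling -> covariate regression ->
PCA / SNN / Louvain -> pairwise markers -> enrichment -> superclusters ->
signatures. Used by the CLI subcommands and by the acceptance checks; every
step is the public function of its module, so results match piecewise runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scstate import cellcycle, clustering, correction, markers, qc
from scstate.enrichment import (
    RankedList, assign_superclusters, nes_matrix, run_enrichment,
    supercluster_signatures, top_genesets,
)
from scstate.io_core import CountMatrix, GeneSetCollection, LogExpressionMatrix, RunConfig
from scstate.markers import bh_adjust, find_markers, pairwise_tests, ranked_list

logger = logging.getLogger("scstate")


@dataclass
class PipelineResult:
    kept_cells: list[str]
    qc_report: pd.DataFrame
    expr: LogExpressionMatrix
    scores: cellcycle.StageScores
    stage_labels: np.ndarray
    stage_corr: np.ndarray
    theta: np.ndarray
    residuals: LogExpressionMatrix
    embedding: np.ndarray
    cluster_labels: np.ndarray
    modularity: float
    marker_tables: dict[int, pd.DataFrame]
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)
    top_sets: list[str] = field(default_factory=list)
    nes: pd.DataFrame = field(default_factory=pd.DataFrame)
    superclusters: pd.Series = field(default_factory=pd.Series)
    cell_superclusters: np.ndarray | None = None
    signatures: dict[str, list[str]] = field(default_factory=dict)


def run_qc(counts: CountMatrix, read_stats: pd.DataFrame, cfg: RunConfig
           ) -> tuple[list[str], pd.DataFrame, LogExpressionMatrix]:
    stats = qc.compute_library_stats(counts, read_stats)
    kept, report = qc.filter_libraries(stats, cfg)
    expr = qc.normalize_log(counts, kept, cfg)
    return kept, report, expr


def run_cellcycle(expr: LogExpressionMatrix, stage_sets: GeneSetCollection, cfg: RunConfig
                  ) -> tuple[cellcycle.StageScores, np.ndarray, np.ndarray, np.ndarray]:
    scores = cellcycle.score_stages(expr, stage_sets)
    labels, corr, _, _ = cellcycle.refine_assignments(
        scores, cor_thr=cfg.cor_thr, refine_iter=cfg.refine_iter)
    theta = cellcycle.fit_circular_phase(scores, labels)
    return scores, labels, corr, theta


def run_correction(expr: LogExpressionMatrix, theta: np.ndarray, pdg: np.ndarray
                   ) -> LogExpressionMatrix:
    cov = correction.build_covariates(theta=theta, pdg=pdg, cells=list(expr.cells))
    return correction.regress_out(expr, cov)


def run_clustering(values: np.ndarray, cfg: RunConfig
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    emb, _ = clustering.pca(values, cfg.n_pcs)
    graph = clustering.build_snn_graph(emb, cfg.knn_k)
    labels, mod = clustering.louvain(graph, seed=cfg.rng_seed)
    return emb, labels, mod


def pairwise_up_lists(values: np.ndarray, group_labels: np.ndarray, genes: list[str],
                      fdr_thr: float = 0.05, top_n: int = 250
                      ) -> dict[tuple[str, str], list[str]]:
    """Top-N upregulated genes per ordered group contrast (BH FDR < fdr_thr)."""
    ids, frames = pairwise_tests(values, group_labels)
    out: dict[tuple[str, str], list[str]] = {}
    for (a, b), df in frames.items():
        fdr = bh_adjust(df["p"].to_numpy())
        keep = (fdr < fdr_thr) & (df["logfc"].to_numpy() > 0)
        sub = df[keep].assign(gene=[genes[i] for i in np.flatnonzero(keep)])
        sub = sub.sort_values("logfc", ascending=False, kind="stable")
        out[(str(a), str(b))] = sub["gene"].head(top_n).tolist()
    return out


def run_pipeline(counts: CountMatrix, read_stats: pd.DataFrame,
                 stage_sets: GeneSetCollection, cfg: RunConfig,
                 hallmark_sets: GeneSetCollection | None = None) -> PipelineResult:
    """Run the full chain; enrichment steps require ``hallmark_sets``."""
    kept, report, expr = run_qc(counts, read_stats, cfg)
    scores, stage_labels, stage_corr, theta = run_cellcycle(expr, stage_sets, cfg)
    pdg = report.loc[kept, "pdg"].to_numpy()
    residuals = run_correction(expr, theta, pdg)
    emb, cluster_labels, mod = run_clustering(residuals.values, cfg)
    tables = find_markers(residuals.values, cluster_labels, list(expr.genes),
                          min_prop=cfg.min_prop)
    result = PipelineResult(
        kept_cells=kept, qc_report=report, expr=expr, scores=scores,
        stage_labels=stage_labels, stage_corr=stage_corr, theta=theta,
        residuals=residuals, embedding=emb, cluster_labels=cluster_labels,
        modularity=mod, marker_tables=tables,
    )
    if hallmark_sets is None:
        return result

    rankings = {c: RankedList(*ranked_list(df)) for c, df in tables.items()}
    result.enrichment = run_enrichment(rankings, hallmark_sets, n_perm=cfg.n_perm,
                                       seed=cfg.rng_seed, weight_exp=cfg.weight_exp)
    result.top_sets = top_genesets(result.enrichment, cfg.top_n_genesets)
    result.nes = nes_matrix(result.enrichment, result.top_sets)
    result.superclusters, _ = assign_superclusters(result.nes, cfg.n_superclusters)
    cell_super = np.array([result.superclusters.loc[c] for c in cluster_labels])
    result.cell_superclusters = cell_super
    if len(set(cell_super.tolist())) >= 2:
        up_lists = pairwise_up_lists(residuals.values, cell_super, list(expr.genes),
                                     fdr_thr=cfg.fdr_thr, top_n=cfg.top_n_deg)
        result.signatures = supercluster_signatures(up_lists)
    return result


__all__ = ["PipelineResult", "run_qc", "run_cellcycle", "run_correction",
           "run_clustering", "pairwise_up_lists", "run_pipeline"]
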