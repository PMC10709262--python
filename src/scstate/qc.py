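"""Library-level QC filters and normalization.

A library is kept iff, in this order of checks:

1. species: human_reads / mouse_reads >= species_ratio_min (a library with
   zero mouse reads and positive human reads passes);
2. depth: human_reads strictly greater than human_reads_min;
3. gene-band: genes_min <= n_genes_detected <= genes_max (closed band).

The first failing filter is recorded as the rejection reason. PDG (fraction
of detected genes) uses as denominator the number of genes detected in at
least one library of the input, unless a fixed denominator is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scstate.io_core import CountMatrix, LogExpressionMatrix, RunConfig

logger = logging.getLogger("scstate")

REASONS = ("species", "depth", "gene-band")


@dataclass
class LibraryStats:
    """Per-cell read statistics and derived detected-gene fraction."""

    table: pd.DataFrame  # index: cell_id; columns: human_reads, mouse_reads, n_genes_detected, pdg
    pdg_denominator: int

    def __post_init__(self) -> None:
        required = {"human_reads", "mouse_reads", "n_genes_detected", "pdg"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.table[["human_reads", "mouse_reads", "n_genes_detected"]] < 0).any().any():
            raise ValueError("read/gene counts must be >= 0")
        if ((self.table["pdg"] < 0) | (self.table["pdg"] > 1)).any():
            raise ValueError("pdg must lie in [0, 1]")


def compute_library_stats(counts: CountMatrix, read_table: pd.DataFrame,
                          pdg_denominator: int | None = None) -> LibraryStats:
    """Derive per-cell detected-gene counts and PDG from counts + read table.

    ``read_table`` must have columns cell_id, human_reads, mouse_reads and
    cover every cell of ``counts``. The PDG denominator defaults to the
    number of genes detected in >= 1 library of this input; pass
    ``pdg_denominator`` to fix it (cross-dataset comparability).
    """
    rt = read_table.set_index("cell_id") if "cell_id" in read_table.columns else read_table
    missing = [c for c in counts.cells if c not in rt.index]
    if missing:
        raise ValueError(f"read table missing cells: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    detected_per_cell = (counts.counts > 0).sum(axis=0)
    if pdg_denominator is None:
        pdg_denominator = int(((counts.counts > 0).any(axis=1)).sum())
    denom = max(pdg_denominator, 1)
    table = pd.DataFrame({
        "human_reads": rt.loc[counts.cells, "human_reads"].to_numpy(),
        "mouse_reads": rt.loc[counts.cells, "mouse_reads"].to_numpy(),
        "n_genes_detected": detected_per_cell,
        "pdg": detected_per_cell / denom,
    }, index=pd.Index(counts.cells, name="cell_id"))
    logger.info("compute_library_stats: %d cells, pdg denominator %d genes",
                len(counts.cells), pdg_denominator)
    return LibraryStats(table, pdg_denominator)


def filter_libraries(stats: LibraryStats, cfg: RunConfig) -> tuple[list[str], pd.DataFrame]:
    """Apply the three QC filters; return kept cell ids and a QC report.

    The report has one row per cell: the stats, a ``kept`` flag and the
    rejection ``reason`` ("" if kept; otherwise the first failing filter in
    the order species, depth, gene-band).
    """
    t = stats.table
    human = t["human_reads"].to_numpy(dtype=float)
    mouse = t["mouse_reads"].to_numpy(dtype=float)
    genes = t["n_genes_detected"].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mouse > 0, human / np.where(mouse > 0, mouse, 1.0), np.inf)
    ratio = np.where((mouse == 0) & (human == 0), 0.0, ratio)

    species_ok = ratio >= cfg.species_ratio_min
    depth_ok = human > cfg.human_reads_min
    band_ok = (genes >= cfg.genes_min) & (genes <= cfg.genes_max)

    reason = np.full(len(t), "", dtype=object)
    reason[~band_ok] = "gene-band"
    reason[~depth_ok] = "depth"
    reason[~species_ok] = "species"
    kept = species_ok & depth_ok & band_ok
    reason[kept] = ""

    report = t.copy()
    report["kept"] = kept
    report["reason"] = reason
    kept_ids = [c for c, k in zip(t.index, kept) if k]
    logger.info(
        "filter_libraries: kept %d/%d cells (species=%d, depth=%d, gene-band=%d rejected)",
        len(kept_ids), len(t), int((reason == "species").sum()),
        int((reason == "depth").sum()), int((reason == "gene-band").sum()),
    )
    if not kept_ids:
        logger.warning("filter_libraries: no cells passed QC")
    return kept_ids, report


def normalize_log(counts: CountMatrix, kept_cells: list[str] | None = None,
                  cfg: RunConfig | None = None) -> LogExpressionMatrix:
    """Library-normalize to ``cfg.norm_total`` reads per cell and log1p.

    Entry = log(1 + norm_total * count / cell_total); the scaled counts of a
    cell sum to norm_total exactly before the log. Natural log by default,
    base 2 via ``cfg.log_base``.
    """
    cfg = cfg or RunConfig()
    if kept_cells is None:
        kept_cells = counts.cells
    idx = [counts.cells.index(c) for c in kept_cells]
    sub = counts.counts[:, idx].astype(float)
    totals = sub.sum(axis=0)
    if (totals == 0).any():
        bad = [kept_cells[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"kept cells with zero total counts: {bad[:10]}")
    scaled = sub * (cfg.norm_total / totals)[None, :]
    values = np.log1p(scaled)
    if cfg.log_base == "2":
        values /= np.log(2.0)
    logger.info("normalize_log: %d genes x %d cells, norm_total=%d, base=%s",
                values.shape[0], values.shape[1], cfg.norm_total, cfg.log_base)
    return LogExpressionMatrix(counts.genes, list(kept_cells), values, kind="lognorm")


__all__ = ["LibraryStats", "compute_library_stats", "filter_libraries",
           "normalize_log", "REASONS"]
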