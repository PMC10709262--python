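"""Per-gene removal of cell-cycle and library-complexity covariates.

The continuous cycle position theta is encoded as (sin theta, cos theta) so
that no artificial discontinuity is imposed at 2*pi; discrete stage
indicator columns are available as an alternative encoding. Each gene is fit
by ordinary least squares (Gaussian identity-link GLM) on an intercept plus
the centred covariates, and the residuals are returned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from scstate.cellcycle import STAGES, UNASSIGNED
from scstate.io_core import LogExpressionMatrix

logger = logging.getLogger("scstate")


def build_covariates(theta: np.ndarray | None = None,
                     pdg: np.ndarray | None = None,
                     stage_labels: np.ndarray | None = None,
                     extra: pd.DataFrame | None = None,
                     encoding: str = "continuous",
                     cells: list[str] | None = None) -> pd.DataFrame:
    """Assemble the centred covariate table.

    Default encoding "continuous" uses (sin theta, cos theta, pdg);
    "stages" replaces the angle by discrete stage indicator columns (one per
    stage with members, minus a reference level). Constant columns are
    dropped with a warning. All columns are mean-centred.
    """
    cols: dict[str, np.ndarray] = {}
    n = None
    if encoding == "continuous":
        if theta is not None:
            theta = np.asarray(theta, dtype=float)
            cols["sin_theta"] = np.sin(theta)
            cols["cos_theta"] = np.cos(theta)
            n = len(theta)
    elif encoding == "stages":
        if stage_labels is None:
            raise ValueError("stage encoding requires stage_labels")
        stage_labels = np.asarray(stage_labels, dtype=object)
        present = [s for s in STAGES if (stage_labels == s).any()]
        for s in present[1:]:  # first present stage is the reference level
            cols[f"stage_{s}"] = (stage_labels == s).astype(float)
        n = len(stage_labels)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    if pdg is not None:
        pdg = np.asarray(pdg, dtype=float)
        cols["pdg"] = pdg
        n = len(pdg) if n is None else n
    if extra is not None:
        for name in extra.columns:
            cols[str(name)] = extra[name].to_numpy(dtype=float)
        n = len(extra) if n is None else n
    if n is None:
        raise ValueError("no covariates supplied")

    lengths = {name: len(v) for name, v in cols.items()}
    if any(l != n for l in lengths.values()):
        raise ValueError(f"covariate lengths differ: {lengths}")

    df = pd.DataFrame(cols, index=cells if cells is not None else range(n))
    df = df - df.mean(axis=0)
    constant = [c for c in df.columns if np.allclose(df[c].to_numpy(), 0.0)]
    if constant:
        logger.warning("build_covariates: dropping constant columns %s", constant)
        df = df.drop(columns=constant)
    return df


def regress_out(expr: LogExpressionMatrix, cov: pd.DataFrame) -> LogExpressionMatrix:
    """OLS-residualize every gene on intercept + covariates.

    Residuals are orthogonal to every covariate column (checked to 1e-8
    relative tolerance). A rank-deficient design raises, naming the
    collinear columns.
    """
    n_cells = len(expr.cells)
    if len(cov) != n_cells:
        raise ValueError(f"covariate rows ({len(cov)}) != cells ({n_cells})")
    if n_cells <= cov.shape[1] + 1:
        raise ValueError("need n_cells > n_covariates + 1")

    design = np.column_stack([np.ones(n_cells), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name offending columns: those whose removal restores full rank
        collinear = []
        for j, name in enumerate(cov.columns, start=1):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(str(name))
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    Y = expr.values.T  # cells x genes
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta

    scale = max(np.abs(expr.values).max(), 1.0)
    gram = np.abs(cov.to_numpy(dtype=float).T @ resid)
    if gram.size and gram.max() > 1e-8 * scale * n_cells:
        raise AssertionError("residuals not orthogonal to covariates")

    logger.info("regress_out: %d genes x %d cells on covariates %s",
                len(expr.genes), n_cells, list(cov.columns))
    return LogExpressionMatrix(list(expr.genes), list(expr.cells), resid.T, kind="residual")


__all__ = ["build_covariates", "regress_out"]
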