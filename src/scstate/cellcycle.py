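"""Five-stage cell-cycle calling and continuous circular phase.

The caller computes, per cell, five normalized stage scores from genesets
peaking at stages G1.S, S, G2, G2.M, M.G1 (cycle order), assigns each cell
to the expected stage profile it correlates with best (below ``cor_thr`` ->
unassigned), optionally refines profiles and labels iteratively, and places
every cell on a continuous circular trajectory by projecting the score
vectors onto their first two principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from scstate.io_core import GeneSetCollection, LogExpressionMatrix

logger = logging.getLogger("scstate")

#: Stage labels in cycle order. The four-label reporting convention maps
#: M.G1 -> G1, G1.S -> G1/S, S and G2 -> S/G2, G2.M -> G2/M.
STAGES = ("G1.S", "S", "G2", "G2.M", "M.G1")
UNASSIGNED = "unassigned"
FOUR_LABEL_MAP = {"M.G1": "G1", "G1.S": "G1/S", "S": "S/G2", "G2": "S/G2", "G2.M": "G2/M"}


@dataclass
class StageScores:
    """Per-cell 5-vectors of normalized stage scores, in cycle order.

    ``degenerate`` flags cells whose five raw scores were all equal; their
    normalized vector is left at zero.
    """

    cells: list[str]
    values: np.ndarray           # (n_cells, 5)
    degenerate: np.ndarray       # (n_cells,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), 5):
            raise ValueError("scores must be n_cells x 5")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite stage scores")


def default_profiles() -> np.ndarray:
    """Initial expected profiles: stage s peaks at its own position.

    Row s is the standardized indicator-like vector with +1 at s and -0.25
    elsewhere. Refinement replaces these with data-driven profiles.
    """
    p = np.full((5, 5), -0.25)
    np.fill_diagonal(p, 1.0)
    p = (p - p.mean(axis=1, keepdims=True)) / p.std(axis=1, keepdims=True)
    return p


def score_stages(expr: LogExpressionMatrix, stage_sets: GeneSetCollection) -> StageScores:
    """Mean stage-geneset expression per cell, z-normalized across the five stages.

    Raw score of cell c for stage s is the mean expression over stage-s genes
    present in ``expr`` (absent genes are dropped with a warning; a stage with
    no matching genes is an error). Each cell's 5-vector is then centred and
    scaled by its standard deviation across stages; all-equal vectors are
    flagged degenerate and left at zero.
    """
    for stage in STAGES:
        if stage not in stage_sets:
            raise ValueError(f"stage geneset missing: {stage}")
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    raw = np.zeros((len(expr.cells), 5))
    for j, stage in enumerate(STAGES):
        members = stage_sets[stage]
        idx = [gene_index[g] for g in members if g in gene_index]
        absent = len(members) - len(idx)
        if not idx:
            raise ValueError(f"no genes of stage {stage} present in expression matrix")
        if absent:
            logger.warning("score_stages: %d/%d genes of stage %s absent from matrix",
                           absent, len(members), stage)
        raw[:, j] = expr.values[idx, :].mean(axis=0)

    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=0, keepdims=True)
    degenerate = (sd[:, 0] == 0.0)
    sd[degenerate, 0] = 1.0
    values = (raw - mean) / sd
    values[degenerate, :] = 0.0
    logger.info("score_stages: scored %d cells, %d degenerate", len(expr.cells),
                int(degenerate.sum()))
    return StageScores(list(expr.cells), values, degenerate)


def _profile_correlations(values: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation of each cell's 5-vector with each profile row.

    Rows with zero variance yield nan correlations.
    """
    vc = values - values.mean(axis=1, keepdims=True)
    pc = profiles - profiles.mean(axis=1, keepdims=True)
    vn = np.linalg.norm(vc, axis=1)
    pn = np.linalg.norm(pc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (vc @ pc.T) / np.outer(vn, pn)
    corr[vn == 0.0, :] = np.nan
    return corr


def assign_stages(scores: StageScores, profiles: np.ndarray,
                  cor_thr: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Assign each cell to the best-correlating stage profile.

    Returns ``(labels, best_corr)``; cells whose maximum correlation is below
    ``cor_thr`` (or undefined for zero-variance score vectors) are labelled
    "unassigned". Argmax ties go to the first stage in cycle order.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape != (5, 5):
        raise ValueError("profiles must be 5 x 5")
    corr = _profile_correlations(scores.values, profiles)
    best = np.nanmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    which = np.argmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    labels = np.array([STAGES[w] for w in which], dtype=object)
    undefined = np.isnan(corr).all(axis=1)
    labels[undefined | (best < cor_thr)] = UNASSIGNED
    best = np.where(undefined, np.nan, best)
    return labels, best


def refine_assignments(scores: StageScores, init_profiles: np.ndarray | None = None,
                       cor_thr: float = 0.2, refine_iter: int = 200,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Iteratively re-estimate stage profiles from current labels and re-assign.

    Profile of stage s becomes the mean score vector of cells currently
    labelled s (kept unchanged if a stage loses all members); cells are then
    re-assigned by correlation. Stops at a label fixed point or after
    ``refine_iter`` iterations. ``refine_iter = 0`` reduces to
    :func:`assign_stages` with the initial profiles.

    Returns ``(labels, best_corr, final_profiles, n_iter)``.
    """
    profiles = default_profiles() if init_profiles is None else np.array(init_profiles, float)
    labels, best = assign_stages(scores, profiles, cor_thr)
    for it in range(refine_iter):
        new_profiles = profiles.copy()
        for j, stage in enumerate(STAGES):
            members = labels == stage
            if members.any():
                new_profiles[j] = scores.values[members].mean(axis=0)
        new_labels, new_best = assign_stages(scores, new_profiles, cor_thr)
        changed = int((new_labels != labels).sum())
        logger.info("refine_assignments: iteration %d, %d label changes", it + 1, changed)
        profiles, labels, best = new_profiles, new_labels, new_best
        if changed == 0:
            return labels, best, profiles, it + 1
    return labels, best, profiles, refine_iter


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))) % (2.0 * np.pi))


def fit_circular_phase(scores: StageScores, labels: np.ndarray) -> np.ndarray:
    """Continuous phase theta in [0, 2pi) for every cell.

    The 5-dimensional score vectors are projected onto their first two
    principal components; theta is the angle about the centroid in that
    plane. Orientation and origin are anchored on the discrete labels: the
    plane is reflected if the circular mean phases of the five stages run
    backwards, and rotated so the G1.S mean sits at theta = 0. Unassigned
    cells still receive a phase.
    """
    active = ~scores.degenerate
    if active.sum() < 3:
        raise ValueError("need >= 3 non-degenerate cells for circular phase")
    X = scores.values - scores.values[active].mean(axis=0, keepdims=True)
    # PCA of the non-degenerate cells; all cells are projected
    _, _, vt = np.linalg.svd(X[active], full_matrices=False)
    plane = X @ vt[:2].T
    raw = np.arctan2(plane[:, 1], plane[:, 0])

    labels = np.asarray(labels, dtype=object)
    best_theta, best_order = None, -1
    for orientation in (1.0, -1.0):
        theta = (orientation * raw) % (2.0 * np.pi)
        anchor_stage = next((s for s in STAGES if (labels == s).any()), None)
        if anchor_stage is None:
            best_theta = theta if best_theta is None else best_theta
            continue
        shift = _circular_mean(theta[labels == anchor_stage])
        theta = (theta - shift) % (2.0 * np.pi)
        means = [_circular_mean(theta[labels == s]) for s in STAGES if (labels == s).any()]
        order = sum(1 for a, b in zip(means, means[1:]) if b > a)
        if order > best_order:
            best_order, best_theta = order, theta
    assert best_theta is not None
    return best_theta


def packaged_stage_genesets() -> GeneSetCollection:
    """The stage genesets shipped with the package (indicative, versioned).

    Intended for real-data runs; the test suite relies exclusively on
    generator-emitted genesets.
    """
    from importlib.resources import files

    from scstate.io_core import read_gmt

    return read_gmt(files("scstate").joinpath("data/cellcycle_stages.gmt"))


def four_label(labels: np.ndarray) -> np.ndarray:
    """Collapse five-stage labels to the four-label reporting convention."""
    return np.array([FOUR_LABEL_MAP.get(l, UNASSIGNED) for l in labels], dtype=object)


__all__ = ["STAGES", "UNASSIGNED", "StageScores", "default_profiles", "score_stages",
           "assign_stages", "refine_assignments", "fit_circular_phase", "four_label",
           "packaged_stage_genesets"]
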