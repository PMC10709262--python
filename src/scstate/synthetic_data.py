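"""Synthetic count matrices with planted structure.

The generator plants everything the downstream pipeline is supposed to
recover: donor-specific baselines, latent biological states with signed
marker genes, a five-sector cell-cycle programme driving a subset of genes,
a per-cell capture-efficiency gradient that induces the detected-gene
fraction covariate, and a fraction of mouse-dominated libraries visible only
in the read-statistics table.

Expected log-expression of gene g in cell c:

    eta(g, c) = baseline_g + donor_effect(d(c), g) + state_effect(s(c), g)
                + A * cos(theta_c - peak_g)          [cycle genes only]

Counts are drawn negative-binomially from exp(eta) and then thinned
binomially by the cell's capture efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scstate.cellcycle import STAGES
from scstate.io_core import CountMatrix, GeneSetCollection, write_count_matrix, write_gmt

SECTOR = 2.0 * np.pi / 5.0  # five equal 72-degree stage arcs


@dataclass
class SimulationDesign:
    """Parameters of the generator. Fractions live in [0, 1]."""

    n_genes: int = 2000
    n_cells: int = 500
    n_donors: int = 3
    donor_effect_sd: float = 0.2
    n_states: int = 3
    state_marker_frac: float = 0.05
    state_logfc: float = 1.0
    cycle_gene_frac: float = 0.15
    cycle_amplitude: float = 1.5
    phase_concentration: float = 2.0
    pdg_range: tuple[float, float] = (0.2, 0.6)
    baseline_mean: float = 2.0
    baseline_log_sd: float = 0.6
    dispersion: float = 0.5
    mouse_contam_frac: float = 0.05
    reads_per_count: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("state_marker_frac", "cycle_gene_frac", "mouse_contam_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        lo, hi = self.pdg_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"pdg_range must lie within (0, 1], got {self.pdg_range}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.phase_concentration < 0:
            raise ValueError("phase_concentration must be >= 0")
        if self.n_genes < 5 or self.n_cells < 1:
            raise ValueError("need n_genes >= 5 and n_cells >= 1")
        if self.state_marker_frac * self.n_states * self.n_genes > self.n_genes * (1 - self.cycle_gene_frac):
            raise ValueError("state markers exceed available non-cycle genes")


@dataclass
class GroundTruth:
    """Planted per-cell and per-gene structure.

    Per cell: donor, state, theta_true (radians in [0, 2pi)), capture
    efficiency, species label. Per gene: cycle-regulated flag with peak
    phase, state-marker membership (-1 if none) with signed logFC.
    """

    donor: np.ndarray          # (n_cells,) int
    state: np.ndarray          # (n_cells,) int
    theta_true: np.ndarray     # (n_cells,) float
    capture: np.ndarray        # (n_cells,) float
    species: np.ndarray        # (n_cells,) str, "human" | "mouse"
    is_cycle: np.ndarray       # (n_genes,) bool
    peak_phase: np.ndarray     # (n_genes,) float, nan for non-cycle genes
    marker_state: np.ndarray   # (n_genes,) int, -1 if not a marker
    marker_logfc: np.ndarray   # (n_genes,) float, signed, 0 if not a marker

    def stage_true(self) -> np.ndarray:
        """Discrete stage label of each cell from its theta sector."""
        sector = (self.theta_true // SECTOR).astype(int) % 5
        return np.array([STAGES[s] for s in sector])

    def up_markers(self, state: int, genes: list[str]) -> list[str]:
        idx = np.flatnonzero((self.marker_state == state) & (self.marker_logfc > 0))
        return [genes[i] for i in idx]


def simulate(design: SimulationDesign) -> tuple[CountMatrix, pd.DataFrame, GroundTruth, GeneSetCollection]:
    """Generate counts, a read-statistics table, ground truth and stage genesets.

    Returns ``(counts, read_stats, truth, stage_sets)``. ``read_stats`` has
    columns cell_id, human_reads, mouse_reads. Stage genesets are the cycle
    genes binned by peak phase into the five 72-degree arcs, labelled
    G1.S, S, G2, G2.M, M.G1. Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(design.seed)
    G, C = design.n_genes, design.n_cells
    genes = [f"g{i:04d}" for i in range(G)]
    cells = [f"c{i:04d}" for i in range(C)]

    # --- per-gene structure -------------------------------------------------
    baseline = rng.normal(np.log(design.baseline_mean), design.baseline_log_sd, size=G)
    donor_eff = rng.normal(0.0, design.donor_effect_sd, size=(design.n_donors, G))

    n_cycle = int(round(design.cycle_gene_frac * G))
    is_cycle = np.zeros(G, dtype=bool)
    cycle_idx = rng.choice(G, size=n_cycle, replace=False)
    is_cycle[cycle_idx] = True
    peak_phase = np.full(G, np.nan)
    # genes spread evenly over the five sectors, peak uniform within sector
    sectors = np.arange(n_cycle) % 5
    peak_phase[cycle_idx] = sectors * SECTOR + rng.uniform(0.0, SECTOR, size=n_cycle)

    marker_state = np.full(G, -1, dtype=int)
    marker_logfc = np.zeros(G)
    n_markers = int(round(design.state_marker_frac * G))
    free = np.flatnonzero(~is_cycle)
    free = rng.permutation(free)
    pos = 0
    for s in range(design.n_states):
        chosen = free[pos:pos + n_markers]
        pos += n_markers
        marker_state[chosen] = s
        half = len(chosen) // 2
        marker_logfc[chosen[:half]] = design.state_logfc
        marker_logfc[chosen[half:]] = -design.state_logfc

    # --- per-cell structure -------------------------------------------------
    donor = rng.integers(0, design.n_donors, size=C)
    state = rng.integers(0, design.n_states, size=C)
    # theta: von Mises mixture centred on the five stage arcs; concentration 0
    # recovers a uniform circle. Nonzero concentration mimics unequal stage
    # occupancy and gives the discrete labels a margin around arc boundaries.
    arc = rng.integers(0, 5, size=C)
    theta = (arc * SECTOR + SECTOR / 2.0
             + rng.vonmises(0.0, design.phase_concentration, size=C)) % (2.0 * np.pi)
    capture = rng.uniform(design.pdg_range[0], design.pdg_range[1], size=C)

    # --- expected expression and counts ------------------------------------
    eta = baseline[:, None] + donor_eff[donor].T
    state_eff = np.zeros((G, design.n_states))
    for s in range(design.n_states):
        state_eff[marker_state == s, s] = marker_logfc[marker_state == s]
    eta += state_eff[:, state]
    cyc = np.flatnonzero(is_cycle)
    if cyc.size and design.cycle_amplitude != 0.0:
        eta[cyc, :] += design.cycle_amplitude * np.cos(theta[None, :] - peak_phase[cyc][:, None])

    mu = np.exp(eta)
    r = 1.0 / design.dispersion  # NB size parameter; var = mu + dispersion * mu^2
    counts = rng.negative_binomial(r, r / (r + mu))
    counts = rng.binomial(counts, capture[None, :])

    # --- read statistics ----------------------------------------------------
    totals = counts.sum(axis=0)
    human_reads = np.maximum((totals * design.reads_per_count).astype(np.int64), 1)
    ratio_clean = rng.uniform(20.0, 100.0, size=C)
    mouse_reads = np.maximum((human_reads / ratio_clean).astype(np.int64), 0)
    species = np.full(C, "human", dtype=object)
    n_contam = int(round(design.mouse_contam_frac * C))
    if n_contam:
        contam = rng.choice(C, size=n_contam, replace=False)
        species[contam] = "mouse"
        # ratio below any sane species threshold: mouse-dominated library
        mouse_reads[contam] = (human_reads[contam] * rng.uniform(1.2, 4.0, size=n_contam)).astype(np.int64)
    read_stats = pd.DataFrame(
        {"cell_id": cells, "human_reads": human_reads, "mouse_reads": mouse_reads}
    )

    truth = GroundTruth(
        donor=donor, state=state, theta_true=theta, capture=capture,
        species=np.asarray(species, dtype=str),
        is_cycle=is_cycle, peak_phase=peak_phase,
        marker_state=marker_state, marker_logfc=marker_logfc,
    )

    stage_sets = GeneSetCollection()
    for k, stage in enumerate(STAGES):
        members = [genes[i] for i in cyc if k == int(peak_phase[i] // SECTOR) % 5]
        if members:
            stage_sets.add(stage, members, f"cycle genes peaking in sector {k}")

    cm = CountMatrix(genes, cells, counts)
    return cm, read_stats, truth, stage_sets


def state_genesets(truth: GroundTruth, genes: list[str]) -> GeneSetCollection:
    """Planted state-marker genesets (up and down per state), for enrichment."""
    coll = GeneSetCollection()
    for s in sorted(set(truth.marker_state[truth.marker_state >= 0])):
        up = truth.up_markers(int(s), genes)
        down_idx = np.flatnonzero((truth.marker_state == s) & (truth.marker_logfc < 0))
        down = [genes[i] for i in down_idx]
        if up:
            coll.add(f"STATE_{s}_UP", up, f"genes upregulated in planted state {s}")
        if down:
            coll.add(f"STATE_{s}_DOWN", down, f"genes downregulated in planted state {s}")
    return coll


def truth_frames(truth: GroundTruth, genes: list[str], cells: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    cell_df = pd.DataFrame({
        "cell_id": cells,
        "donor": truth.donor,
        "state": truth.state,
        "theta_true": truth.theta_true,
        "capture": truth.capture,
        "species": truth.species,
        "stage_true": truth.stage_true(),
    })
    gene_df = pd.DataFrame({
        "gene_id": genes,
        "is_cycle": truth.is_cycle.astype(int),
        "peak_phase": truth.peak_phase,
        "marker_state": truth.marker_state,
        "marker_logfc": truth.marker_logfc,
    })
    return cell_df, gene_df


def write_fixture(prefix: str | Path, counts: CountMatrix, read_stats: pd.DataFrame,
                  truth: GroundTruth, stage_sets: GeneSetCollection) -> dict[str, Path]:
    """Write the simulated dataset to disk so CLI stages can run black-box.

    Emits ``<prefix>.counts.mtx`` (+ label files), ``<prefix>.stats.csv``,
    ``<prefix>.stages.gmt``, ``<prefix>.states.gmt`` and two ground-truth
    CSVs. Same inputs give byte-identical files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": prefix.with_suffix(".counts.mtx"),
        "stats": prefix.with_suffix(".stats.csv"),
        "stages": prefix.with_suffix(".stages.gmt"),
        "states": prefix.with_suffix(".states.gmt"),
        "truth_cells": prefix.with_suffix(".truth_cells.csv"),
        "truth_genes": prefix.with_suffix(".truth_genes.csv"),
    }
    write_count_matrix(counts, paths["counts"])
    read_stats.to_csv(paths["stats"], index=False)
    write_gmt(stage_sets, paths["stages"])
    write_gmt(state_genesets(truth, counts.genes), paths["states"])
    cell_df, gene_df = truth_frames(truth, counts.genes, counts.cells)
    cell_df.to_csv(paths["truth_cells"], index=False, float_format="%.10g")
    gene_df.to_csv(paths["truth_genes"], index=False, float_format="%.10g")
    return paths


__all__ = ["SimulationDesign", "GroundTruth", "simulate", "write_fixture",
           "state_genesets", "truth_frames", "SECTOR"]
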