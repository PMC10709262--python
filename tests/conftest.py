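import logging

import numpy as np
import pytest

from scstate.io_core import RunConfig
from scstate.pipeline import run_pipeline
from scstate.synthetic_data import SimulationDesign, simulate, state_genesets

logging.getLogger("scstate").setLevel(logging.WARNING)


def standard_design(seed: int = 1, **kwargs) -> SimulationDesign:
    """The standard synthetic design: 2000 genes x 500 cells, 3 donors,
    3 states, state_logfc 1.0, cycle_amplitude 1.5, pdg_range (0.2, 0.6)."""
    base = dict(n_genes=2000, n_cells=500, n_donors=3, n_states=3,
                state_logfc=1.0, cycle_gene_frac=0.15, cycle_amplitude=1.5,
                pdg_range=(0.2, 0.6), seed=seed)
    base.update(kwargs)
    return SimulationDesign(**base)


def standard_config(**kwargs) -> RunConfig:
    """Config scaled to the synthetic data: the gene band covers 10%-90% of
    the 2000 simulated genes (the published band is dataset-specific) and
    permutations are reduced to keep tests fast."""
    base = dict(genes_min=200, genes_max=1800, n_perm=500, rng_seed=0)
    base.update(kwargs)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def sim1():
    """Standard design at seed 1: (counts, read_stats, truth, stage_sets)."""
    return simulate(standard_design(seed=1))


@pytest.fixture(scope="session")
def cfg_std():
    return standard_config()


@pytest.fixture(scope="session")
def run1(sim1, cfg_std):
    """Full pipeline result (with enrichment) on the standard seed-1 dataset."""
    counts, stats, truth, stage_sets = sim1
    hallmarks = state_genesets(truth, counts.genes)
    return run_pipeline(counts, stats, stage_sets, cfg_std, hallmarks)


@pytest.fixture(scope="session")
def kept_idx1(sim1, run1):
    counts = sim1[0]
    return np.array([counts.cells.index(c) for c in run1.kept_cells])
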