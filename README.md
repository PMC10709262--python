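# scstate

Single-cell RNA-seq state inference for xenograft-derived tumour libraries:
from raw gene × cell counts and per-library read statistics to biological
"supercluster" states, with the confounders (cell-cycle stage and library
complexity) measured and regressed out along the way.

The pipeline chains eight stages:

1. **io_core** — MTX / CSV count matrices (with plain-text label files), GMT
   genesets, YAML run configuration.
2. **synthetic_data** — a negative-binomial generator with planted donors,
   latent biological states (signed marker genes), a five-stage cell-cycle
   programme, a capture-efficiency gradient (binomial thinning) and
   mouse-dominated libraries visible in the read table. Every downstream
   stage is validated against its ground truth.
3. **qc** — library filters in fixed order (human/mouse read ratio ≥ 5,
   human reads > 100 k, detected genes within [2,346, 9,884] by default),
   percentage-of-detected-genes (PDG), then normalization to 100 k reads and
   log1p.
4. **cellcycle** — five normalized stage scores (G1.S, S, G2, G2.M, M.G1),
   correlation-based assignment against expected profiles (threshold 0.2),
   iterative refinement (≤ 200 iterations), and a continuous circular phase
   θ from the first two principal components of the score vectors, anchored
   so the stage means run in cycle order with G1.S at θ = 0.
5. **correction** — per-gene least-squares (Gaussian identity-link GLM)
   removal of (sin θ, cos θ, PDG); residuals are exactly orthogonal to the
   covariates. Discrete stage-indicator encoding is available.
6. **clustering** — PCA (deterministic sign convention), shared-nearest-
   neighbour graph with Jaccard weights over k-neighbourhoods (self
   included), seeded Louvain communities, and cluster composition /
   entropy summaries.
7. **markers** — Welch t-tests for every ordered cluster pair, per-gene Holm
   correction across pairs, the "some" combined p (k-th smallest Holm p,
   k = ⌈min_prop · m⌉), Benjamini–Hochberg FDR, summary logFC from the
   comparison attaining the combined p, top-N up/down selection.
8. **enrichment** — weighted Kolmogorov–Smirnov enrichment score on
   preranked lists, permutation NES and p against random same-size genesets,
   top-|NES| geneset selection, average-linkage superclusters in NES space,
   and exclusive per-supercluster up-signatures from pairwise contrasts.

## CLI

Every stage is a subcommand of `scstate`; a full synthetic run:

```sh
scstate simulate --design design.yaml --out sim
scstate qc --counts sim.counts.mtx --stats sim.stats.csv --config cfg.yaml --out qc
scstate cellcycle --expr qc.lognorm.mtx --stages sim.stages.gmt --out cc.csv
scstate correct --expr qc.lognorm.mtx --cellcycle cc.csv --stats qc.qc_report.csv --out resid.mtx
scstate cluster --expr resid.mtx --k 10 --n-pcs 20 --seed 0 --out labels.csv
scstate markers --expr resid.mtx --labels labels.csv --out-dir markers/
scstate enrich --rnk-dir markers/ --gmt hallmarks.gmt --expr resid.mtx \
    --labels labels.csv --out enr
```

`design.yaml` maps `SimulationDesign` fields; `cfg.yaml` maps `RunConfig`
fields (all have published defaults; the gene band must be rescaled for
synthetic data, e.g. `genes_min: 200`, `genes_max: 1800` for 2,000 genes).
A small indicative stage geneset for real data ships with the package
(`scstate.cellcycle.packaged_stage_genesets()`); tests rely only on
generator-emitted genesets.

## Notes

- `tests/test_acceptance.py` carries one test per acceptance criterion. One
  assertion (mean |r| ≥ 0.3 between a scalar covariate and each of the
  top-10 uncorrected PCs) is mathematically capped at √(1/10) ≈ 0.316 by
  Cauchy–Schwarz and is left failing deliberately with an in-test
  explanation; the substantive claim (the capture gradient dominates an
  uncorrected PC and vanishes from residual PCs) is asserted and holds.
- All randomness is seeded; fixed seeds reproduce bit-identical simulations,
  fixtures, Louvain labels and permutation NES values.
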