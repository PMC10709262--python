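"""Readers/writers for the formats the pipeline touches, plus run configuration.

Supported formats: Matrix Market MTX (with plain-text row/column label files),
dense CSV with a header row, GMT genesets, and a YAML run configuration.
MTX files use 1-based indices per the Matrix Market standard; all internal
indexing is 0-based and conversion happens only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("scstate")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigError(ValueError):
    """Raised for unknown keys, bad types or invariant violations in config."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with identifiers.

    Invariants: no duplicate gene or cell identifiers, counts >= 0 and
    dimensions consistent with the identifier lists.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray  # (n_genes, n_cells), integer, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise ParseError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.cells)) != len(self.cells):
            dup = _first_duplicate(self.cells)
            raise ParseError(f"duplicate cell identifier: {dup!r}")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ParseError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ParseError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            g, c = np.unravel_index(int(np.argmin(self.counts)), self.counts.shape)
            raise ParseError(f"negative count at gene {self.genes[g]!r}, cell {self.cells[c]!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class LogExpressionMatrix:
    """Real-valued gene x cell expression matrix.

    ``kind`` records provenance: "lognorm" (log1p of library-normalized
    counts, entries >= 0) or "residual" (GLM residuals, any sign).
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    kind: str = "lognorm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("lognorm", "residual"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression entries")
        if self.kind == "lognorm" and self.values.size and self.values.min() < 0:
            raise ValueError("lognorm entries must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class GeneSetCollection:
    """Ordered collection of named genesets.

    Set names are unique; member lists are de-duplicated preserving order and
    must be non-empty.
    """

    def __init__(self, sets: Mapping[str, Sequence[str]] | None = None,
                 descriptions: Mapping[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        self._descriptions: dict[str, str] = {}
        if sets:
            for name, members in sets.items():
                desc = (descriptions or {}).get(name, "")
                self.add(name, members, desc)

    def add(self, name: str, members: Sequence[str], description: str = "") -> None:
        if name in self._sets:
            raise ParseError(f"duplicate geneset name: {name!r}")
        deduped = list(dict.fromkeys(members))
        if not deduped:
            raise ParseError(f"geneset {name!r} is empty")
        self._sets[name] = deduped
        self._descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def items(self):
        return self._sets.items()


_CONFIG_DEFAULTS = dict(
    species_ratio_min=5.0,
    human_reads_min=100_000,
    genes_min=2_346,
    genes_max=9_884,
    norm_total=100_000,
    log_base="e",
    cor_thr=0.2,
    refine_iter=200,
    knn_k=10,
    n_pcs=20,
    fdr_thr=0.05,
    min_prop=0.2,
    top_n_deg=250,
    top_n_genesets=25,
    n_superclusters=3,
    n_perm=2_000,
    weight_exp=1.0,
    rng_seed=0,
)


@dataclass
class RunConfig:
    """Pipeline parameters with the published defaults.

    QC thresholds: keep a library iff human/mouse ratio >= ``species_ratio_min``,
    human reads strictly > ``human_reads_min`` and detected genes within the
    closed band [``genes_min``, ``genes_max``].
    """

    species_ratio_min: float = _CONFIG_DEFAULTS["species_ratio_min"]
    human_reads_min: int = _CONFIG_DEFAULTS["human_reads_min"]
    genes_min: int = _CONFIG_DEFAULTS["genes_min"]
    genes_max: int = _CONFIG_DEFAULTS["genes_max"]
    norm_total: int = _CONFIG_DEFAULTS["norm_total"]
    log_base: str = _CONFIG_DEFAULTS["log_base"]  # "e" or "2"
    cor_thr: float = _CONFIG_DEFAULTS["cor_thr"]
    refine_iter: int = _CONFIG_DEFAULTS["refine_iter"]
    knn_k: int = _CONFIG_DEFAULTS["knn_k"]
    n_pcs: int = _CONFIG_DEFAULTS["n_pcs"]
    fdr_thr: float = _CONFIG_DEFAULTS["fdr_thr"]
    min_prop: float = _CONFIG_DEFAULTS["min_prop"]
    top_n_deg: int = _CONFIG_DEFAULTS["top_n_deg"]
    top_n_genesets: int = _CONFIG_DEFAULTS["top_n_genesets"]
    n_superclusters: int = _CONFIG_DEFAULTS["n_superclusters"]
    n_perm: int = _CONFIG_DEFAULTS["n_perm"]
    weight_exp: float = _CONFIG_DEFAULTS["weight_exp"]
    rng_seed: int = _CONFIG_DEFAULTS["rng_seed"]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "species_ratio_min", "human_reads_min", "genes_min", "genes_max",
            "norm_total", "refine_iter", "knn_k", "n_pcs", "fdr_thr",
            "top_n_deg", "top_n_genesets", "n_superclusters", "n_perm",
        )
        for name in positive:
            if getattr(self, name) <= 0 and name != "refine_iter":
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.refine_iter < 0:
            raise ConfigError("refine_iter must be >= 0")
        if self.genes_min >= self.genes_max:
            raise ConfigError(
                f"genes_min ({self.genes_min}) must be < genes_max ({self.genes_max})"
            )
        if not 0 < self.min_prop <= 1:
            raise ConfigError(f"min_prop must lie in (0, 1], got {self.min_prop}")
        if self.log_base not in ("e", "2"):
            raise ConfigError(f"log_base must be 'e' or '2', got {self.log_base!r}")
        if self.weight_exp < 0:
            raise ConfigError("weight_exp must be >= 0")


def load_config(path: str | Path | None = None, overrides: Mapping[str, object] | None = None) -> RunConfig:
    """Build a RunConfig from a YAML mapping plus keyword overrides.

    Overrides win over file values; both win over defaults. Unknown keys and
    non-numeric values for numeric fields raise :class:`ConfigError`.
    """
    values: dict[str, object] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    if overrides:
        values.update(overrides)

    known = {f.name for f in fields(RunConfig)}
    for key, val in values.items():
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")
        if key != "log_base" and not isinstance(val, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {val!r}")
    return RunConfig(**values)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Count / expression matrix IO
# ---------------------------------------------------------------------------


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def _label_paths(mtx_path: Path) -> tuple[Path, Path]:
    base = mtx_path.with_suffix("")
    return Path(f"{base}.genes.txt"), Path(f"{base}.cells.txt")


def _read_labels(path: Path) -> list[str]:
    if not path.exists():
        raise ParseError(f"label file not found: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def read_count_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a gene x cell count matrix from MTX (+ label files) or CSV.

    For ``X.mtx`` the gene and cell identifiers are read from ``X.genes.txt``
    and ``X.cells.txt`` (one identifier per line). CSV files carry gene
    identifiers in the first column and cell identifiers in the header.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "csv"
    if format == "mtx":
        genes_path, cells_path = _label_paths(path)
        genes = _read_labels(genes_path)
        cells = _read_labels(cells_path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise ParseError(f"malformed MTX file {path}: {exc}") from exc
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(cells)):
            raise ParseError(
                f"MTX dimensions {dense.shape} do not match label files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        cm = CountMatrix(genes, cells, dense)
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        cm = CountMatrix([str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy())
    else:
        raise ValueError(f"unknown format {format!r}")
    logger.info("read_count_matrix: %s -> %d genes x %d cells", path, *cm.shape)
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as sparse MTX plus gene/cell label files."""
    path = Path(path)
    _write_mtx(cm.counts, cm.genes, cm.cells, path, field="integer")


def read_expression_matrix(path: str | Path, kind: str = "lognorm") -> LogExpressionMatrix:
    """Read a real-valued expression matrix stored as MTX or CSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        genes = _read_labels(_label_paths(path)[0])
        cells = _read_labels(_label_paths(path)[1])
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ParseError(f"MTX dimensions {dense.shape} do not match label files")
        return LogExpressionMatrix(genes, cells, dense, kind=kind)
    df = pd.read_csv(path, index_col=0)
    return LogExpressionMatrix(
        [str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy(float), kind=kind
    )


def write_expression_matrix(expr: LogExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as real-valued MTX plus label files."""
    _write_mtx(expr.values, expr.genes, expr.cells, Path(path), field="real")


def _write_mtx(values: np.ndarray, genes: Sequence[str], cells: Sequence[str],
               path: Path, field: str) -> None:
    sparse = scipy.sparse.coo_matrix(values)
    # hand-formatted body for byte-stable fixtures across scipy versions
    with open(path, "w") as fh:
        fh.write(f"%%MatrixMarket matrix coordinate {field} general\n")
        fh.write(f"{values.shape[0]} {values.shape[1]} {sparse.nnz}\n")
        order = np.lexsort((sparse.row, sparse.col))
        for i in order:
            r, c, v = sparse.row[i] + 1, sparse.col[i] + 1, sparse.data[i]
            if field == "integer":
                fh.write(f"{r} {c} {int(v)}\n")
            else:
                fh.write(f"{r} {c} {v:.10g}\n")
    genes_path, cells_path = _label_paths(path)
    genes_path.write_text("".join(f"{g}\n" for g in genes))
    cells_path.write_text("".join(f"{c}\n" for c in cells))
    logger.info("wrote matrix %s (%d x %d, %d nonzero)", path, values.shape[0],
                values.shape[1], sparse.nnz)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read genesets from GMT: one tab-separated line per set
    (name, description, members...). Duplicate member genes collapse;
    duplicate set names are an error."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(parts)} fields, need >= 3")
            name, desc, *members = parts
            members = [m for m in members if m]
            coll.add(name, members, desc)
    logger.info("read_gmt: %s -> %d sets", path, len(coll))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.items():
            desc = coll.description(name)
            fh.write("\t".join([name, desc, *members]) + "\n")


__all__ = [
    "CountMatrix", "LogExpressionMatrix", "GeneSetCollection", "RunConfig",
    "ParseError", "ConfigError", "load_config",
    "read_count_matrix", "write_count_matrix",
    "read_expression_matrix", "write_expression_matrix",
    "read_gmt", "write_gmt",
]
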