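"""Count-matrix IO, cell quality control, normalisation, and pseudobulk.

The QC defaults mirror standard droplet scRNA-seq practice for cardiac
tissue: cells with fewer than 200 detected genes, fewer than 500 or more
than 30,000 total UMIs, or more than 25% mitochondrial UMIs are removed.
The mitochondrial ceiling is deliberately generous because cardiomyocytes
carry an unusually high mitochondrial load.

Normalisation divides each cell by its total UMI count, multiplies by
10,000, and applies ``log2(1 + x)``; an optional second step regresses the
per-gene log expression on per-cell totals (``n_umi``, ``n_genes``) and
standardises the residuals, the usual guard against library-size and
complexity covariates leaking into the embedding.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample", "group", "timepoint")


class FormatError(ValueError):
    """Raised when an input file set is malformed or incomplete."""


class ValidationError(ValueError):
    """Raised when data violate a container invariant."""


def _as_str_array(values: Sequence[str], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if len(set(arr)) != arr.size:
        raise ValidationError(f"duplicate identifiers in {name}")
    return arr


def default_mito_rule(gene_names: Sequence[str]) -> np.ndarray:
    """Flag genes whose symbol starts with ``MT-``/``mt-`` (case-insensitive)."""
    return np.array([str(g).lower().startswith("mt-") for g in gene_names], dtype=bool)


@dataclass
class RawCountMatrix:
    """Integer UMI counts, genes x cells, with identifiers and mito flags.

    ``counts`` is a dense integer array (desk-scale datasets); sparse
    inputs are densified on load. ``mito_flags`` marks mitochondrial genes
    for the QC fraction rule.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    mito_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if scipy.sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("counts must be integer-valued UMIs")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        if self.counts.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.gene_ids.size} genes x {self.cell_ids.size} cells"
            )
        if self.mito_flags is None:
            self.mito_flags = default_mito_rule(self.gene_ids)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.mito_flags.shape != self.gene_ids.shape:
            raise ValidationError("mito_flags length must match gene axis")

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def total_umi_per_cell(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def detected_genes_per_cell(self) -> np.ndarray:
        return (self.counts >= 1).sum(axis=0)

    def mito_fraction_per_cell(self) -> np.ndarray:
        total = self.total_umi_per_cell().astype(float)
        mito = self.counts[self.mito_flags, :].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / total, 0.0)
        return frac

    def subset_cells(self, mask_or_ids) -> "RawCountMatrix":
        idx = self._cell_index(mask_or_ids)
        return RawCountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            mito_flags=self.mito_flags.copy(),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "RawCountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return RawCountMatrix(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            mito_flags=self.mito_flags[idx],
        )

    def _cell_index(self, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.size != self.n_cells:
                raise ValidationError("boolean cell mask has wrong length")
            return np.flatnonzero(arr)
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in arr if c not in pos]
        if missing:
            raise ValidationError(f"cells not in matrix: {missing[:5]}")
        return np.array([pos[c] for c in arr], dtype=int)


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    Defaults: >= 200 detected genes, total UMI in [500, 30000], and
    mitochondrial UMI fraction <= 0.25.
    """

    min_genes_per_cell: int = 200
    min_umi: int = 500
    max_umi: int = 30000
    max_mito_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.min_umi < self.max_umi:
            raise ValidationError("min_umi must be < max_umi")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")


@dataclass
class NormalizedExpression:
    """Log2-scale (optionally covariate-adjusted) expression, genes x cells."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    n_umi: np.ndarray
    n_genes: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        if self.values.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValidationError("values shape does not match identifiers")
        if not np.isfinite(self.values).all():
            raise ValidationError("normalized values must be finite")
        self.n_umi = np.asarray(self.n_umi)
        self.n_genes = np.asarray(self.n_genes)
        if self.n_umi.shape != self.cell_ids.shape or self.n_genes.shape != self.cell_ids.shape:
            raise ValidationError("per-cell totals must match cell axis")

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def cell_index(self, cell_ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"cells not in matrix: {missing[:5]}")
        return np.array([pos[c] for c in cell_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "NormalizedExpression":
        idx = self.gene_index(gene_ids)
        return NormalizedExpression(
            values=self.values[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            n_umi=self.n_umi.copy(),
            n_genes=self.n_genes.copy(),
            adjusted=self.adjusted,
        )

    def subset_cells(self, cell_ids: Sequence[str]) -> "NormalizedExpression":
        idx = self.cell_index(cell_ids)
        return NormalizedExpression(
            values=self.values[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            n_umi=self.n_umi[idx],
            n_genes=self.n_genes[idx],
            adjusted=self.adjusted,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_triplet_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / f"{stem}{suffix}"
            if candidate.exists():
                return candidate
    raise FormatError(f"no {stems[0]}[.gz] found in {directory}")


def load_counts(
    path: str | Path,
    format: str = "auto",
    mito_genes: Sequence[str] | None = None,
) -> RawCountMatrix:
    """Read a count matrix from a 10x MTX triplet directory or delimited table.

    Parameters
    ----------
    path
        Directory containing ``matrix.mtx[.gz]``, ``barcodes.tsv[.gz]`` and
        ``features.tsv[.gz]`` (or ``genes.tsv``), or a delimited gene x cell
        table with a header row of cell ids and gene ids in the first column.
    format
        ``"mtx"``, ``"table"`` or ``"auto"`` (directory -> mtx, file -> table).
    mito_genes
        Explicit mitochondrial gene list; defaults to the ``MT-``/``mt-``
        symbol-prefix rule.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx" if path.is_dir() else "table"
    if format == "mtx":
        raw = _load_mtx_triplet(path)
    elif format == "table":
        raw = _load_table(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if mito_genes is not None:
        mito_set = set(mito_genes)
        raw = replace(raw, mito_flags=np.array([g in mito_set for g in raw.gene_ids]))
    return raw


def _load_mtx_triplet(directory: Path) -> RawCountMatrix:
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    mtx_path = _find_triplet_file(directory, ["matrix.mtx"])
    barcodes_path = _find_triplet_file(directory, ["barcodes.tsv"])
    features_path = _find_triplet_file(directory, ["features.tsv", "genes.tsv"])

    mat = scipy.io.mmread(str(mtx_path))
    dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
    if not np.allclose(dense, np.round(dense)):
        raise ValidationError(f"{mtx_path} contains non-integer entries")
    dense = np.round(dense).astype(np.int64)

    with _open_maybe_gz(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(features_path) as fh:
        feature_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    gene_ids = [row[0] for row in feature_rows]
    # mito detection works on symbols (2nd column) when present
    gene_names = [row[1] if len(row) > 1 else row[0] for row in feature_rows]

    if dense.shape[0] != len(gene_ids):
        raise FormatError(
            f"feature count mismatch: matrix has {dense.shape[0]} rows, "
            f"{features_path.name} has {len(gene_ids)}"
        )
    if dense.shape[1] != len(barcodes):
        raise FormatError(
            f"barcode count mismatch: matrix has {dense.shape[1]} columns, "
            f"{barcodes_path.name} has {len(barcodes)}"
        )
    return RawCountMatrix(
        counts=dense,
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(barcodes, dtype=object),
        mito_flags=default_mito_rule(gene_names),
    )


def _load_table(path: Path) -> RawCountMatrix:
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    sep = "," if path.suffix.lower() in (".csv",) else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values.astype(float))):
        raise ValidationError(f"{path} contains non-integer entries")
    return RawCountMatrix(
        counts=np.round(values.astype(float)).astype(np.int64),
        gene_ids=np.asarray(df.index.astype(str), dtype=object),
        cell_ids=np.asarray(df.columns.astype(str), dtype=object),
    )


def write_mtx(raw: RawCountMatrix, directory: str | Path) -> Path:
    """Write a plain-text 10x-style MTX triplet (round-trips via load_counts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"),
        scipy.sparse.coo_matrix(raw.counts),
        field="integer",
    )
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{c}\n" for c in raw.cell_ids)
    with open(directory / "features.tsv", "w") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in raw.gene_ids)
    return directory


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata (TSV: cell_id, sample, group, timepoint)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise FormatError("metadata must contain a cell_id column")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id rows in metadata")
    return df.set_index("cell_id")


def check_metadata_covers(meta: pd.DataFrame, cell_ids: Sequence[str]) -> None:
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells missing from metadata, e.g. {missing[:5]}"
        )


# ---------------------------------------------------------------------------
# QC / normalisation
# ---------------------------------------------------------------------------


def qc_filter_cells(raw: RawCountMatrix, thresholds: QCThresholds | None = None) -> RawCountMatrix:
    """Remove low-quality cells; the gene axis is left untouched.

    A cell is retained iff detected genes >= ``min_genes_per_cell``,
    ``min_umi`` <= total UMI <= ``max_umi``, and mitochondrial fraction
    <= ``max_mito_fraction``. Idempotent by construction.
    """
    thresholds = thresholds or QCThresholds()
    n_genes = raw.detected_genes_per_cell()
    n_umi = raw.total_umi_per_cell()
    mito = raw.mito_fraction_per_cell()
    keep = (
        (n_genes >= thresholds.min_genes_per_cell)
        & (n_umi >= thresholds.min_umi)
        & (n_umi <= thresholds.max_umi)
        & (mito <= thresholds.max_mito_fraction)
    )
    removed = {
        "low_genes": int((n_genes < thresholds.min_genes_per_cell).sum()),
        "low_umi": int((n_umi < thresholds.min_umi).sum()),
        "high_umi": int((n_umi > thresholds.max_umi).sum()),
        "high_mito": int((mito > thresholds.max_mito_fraction).sum()),
    }
    logger.info("QC removal counts (per rule, overlapping): %s", removed)
    if raw.n_cells > 0 and not keep.any():
        warnings.warn("all cells removed by QC", stacklevel=2)
    return raw.subset_cells(keep)


def normalize_log(raw: RawCountMatrix, scale_factor: float = 10_000.0) -> NormalizedExpression:
    """Library-size normalise and log-transform: log2(1 + sf * count / total)."""
    total = raw.total_umi_per_cell().astype(float)
    if raw.n_cells and (total <= 0).any():
        raise ValidationError(
            "cells with zero total UMI present; run qc_filter_cells first"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(1.0 + scale_factor * raw.counts / total[None, :])
    if raw.n_cells == 0:
        values = np.zeros_like(raw.counts, dtype=float)
    return NormalizedExpression(
        values=values,
        gene_ids=raw.gene_ids.copy(),
        cell_ids=raw.cell_ids.copy(),
        n_umi=raw.total_umi_per_cell(),
        n_genes=raw.detected_genes_per_cell(),
        adjusted=False,
    )


def regress_and_scale(
    norm: NormalizedExpression,
    clip: float = 10.0,
) -> NormalizedExpression:
    """Regress out per-cell totals and standardise each gene.

    For every gene an OLS fit of log expression on (n_umi, n_genes) is
    computed; the residuals are centred to mean 0 / unit variance per gene
    and clipped to ``+-clip`` to bound outlier leverage. Genes with zero
    residual variance map to all-zero rows.
    """
    if norm.adjusted:
        raise ValidationError("expression is already covariate-adjusted")
    n_cells = norm.cell_ids.size
    if n_cells < 3:
        raise ValidationError("need at least 3 cells for covariate regression")
    design = np.column_stack(
        [np.ones(n_cells), norm.n_umi.astype(float), norm.n_genes.astype(float)]
    )
    # one least-squares solve for all genes at once
    coef, *_ = np.linalg.lstsq(design, norm.values.T, rcond=None)
    residuals = norm.values - (design @ coef).T
    mean = residuals.mean(axis=1, keepdims=True)
    std = residuals.std(axis=1, keepdims=True)
    # a perfectly fit gene leaves numerically-zero residuals; treat its
    # variance as zero rather than amplifying rounding noise
    tol = 1e-10 * (np.abs(norm.values).max() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(std > tol, (residuals - mean) / std, 0.0)
    scaled = np.clip(scaled, -clip, clip)
    return NormalizedExpression(
        values=scaled,
        gene_ids=norm.gene_ids.copy(),
        cell_ids=norm.cell_ids.copy(),
        n_umi=norm.n_umi.copy(),
        n_genes=norm.n_genes.copy(),
        adjusted=True,
    )


def select_embedding_genes(raw: RawCountMatrix, min_total_umi: int = 1000) -> list[str]:
    """Genes with summed UMI across (post-QC) cells >= ``min_total_umi``.

    Keeps the autoencoder input restricted to robustly detected genes; the
    result preserves the input gene order.
    """
    totals = raw.counts.sum(axis=1)
    selected = [g for g, t in zip(raw.gene_ids, totals) if t >= min_total_umi]
    if not selected:
        raise ValidationError(
            f"no gene reaches {min_total_umi} total UMIs; embedding impossible"
        )
    return selected


def pseudobulk(
    norm: NormalizedExpression,
    meta: pd.DataFrame,
    cells_per_replicate: int = 5000,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Average expression per sample into bulk-like profiles.

    With ``n_replicates == 1`` each column is the mean over all cells of a
    sample; with more replicates, each column averages a seeded random
    subset of ``cells_per_replicate`` cells drawn without replacement from
    that sample, emulating synthetic bulk samples for enrichment tools.
    """
    check_metadata_covers(meta, norm.cell_ids)
    samples = meta.loc[norm.cell_ids, "sample"].to_numpy()
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for sample in pd.unique(samples):
        idx = np.flatnonzero(samples == sample)
        if n_replicates == 1:
            columns[str(sample)] = norm.values[:, idx].mean(axis=1)
            continue
        if idx.size < cells_per_replicate:
            raise ValidationError(
                f"sample {sample!r} has {idx.size} cells, fewer than "
                f"cells_per_replicate={cells_per_replicate}"
            )
        for rep in range(n_replicates):
            chosen = rng.choice(idx, size=cells_per_replicate, replace=False)
            columns[f"{sample}_rep{rep + 1}"] = norm.values[:, chosen].mean(axis=1)
    return pd.DataFrame(columns, index=norm.gene_ids)
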