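"""L1-sparse linear scoring of gene sets via an exact linear program.

Given two designated reference populations — "positive" cells (label
y=+1, e.g. proliferating neonatal cardiomyocytes) and "negative" cells
(y=-1) — and a gene set, the model finds a per-gene coefficient vector w
and intercept b by minimising

    (1/2) * ||w||_1  +  C * sum_i eps_i
    subject to   y_i (w . x_i + b) + eps_i >= 1,   eps_i >= 0

i.e. a soft-margin linear separator with an L1 (sparsity-inducing)
penalty. With the L1 norm the problem is a linear program and is solved
exactly via the standard split w = w+ - w- (w+, w- >= 0) with the HiGHS
solver. Every cell is then scored with y = w . x + b and binned
high (y > 1) / middle (-1 <= y <= 1) / low (y < -1); per-cell scores of
two groups are compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from scregenai.io_qc import NormalizedExpression, ValidationError, check_metadata_covers

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("score", "category")


@dataclass
class GeneSet:
    """Named gene list (cell-cycle phase, signalling pathway, or custom)."""

    name: str
    genes: list[str]
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT (name <tab> description <tab> gene1 <tab> gene2 ...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], genes=parts[2:], source=parts[1] or "gmt"))
    if not sets:
        raise ValidationError(f"no gene sets in {path}")
    return sets


def packaged_genesets() -> list[GeneSet]:
    """Editable default gene sets shipped with the package.

    Covers the five cell-cycle phases (G1S, S, G2M, M, cytokinesis) and
    six signalling pathways (MAPK, HIPPO, cAMP, JAK-STAT, RAS, TGF-beta)
    relevant to cardiomyocyte proliferation. The lists are deliberately
    compact, user-replaceable starting points, not a pinned pathway
    database release.
    """
    from importlib.resources import files

    return read_gmt(str(files("scregenai").joinpath("data/genesets.gmt")))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-gene-per-line text file."""
    path = Path(path)
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneSet(name=name or path.stem, genes=genes)


@dataclass
class SparseModel:
    """Fitted coefficients for one gene set and reference-group pair."""

    w: np.ndarray
    b: float
    C: float
    slack: np.ndarray  # eps_i per training cell, >= 0
    gene_ids: np.ndarray
    objective: float
    positive_label: str = "positive"
    negative_label: str = "negative"

    def __post_init__(self) -> None:
        if self.w.shape != self.gene_ids.shape:
            raise ValidationError("w must be indexed by gene_ids")
        if (self.slack < -1e-9).any():
            raise ValidationError("slack variables must be >= 0")


def _resolve_cells(norm: NormalizedExpression, cells: Sequence[str], role: str) -> np.ndarray:
    cells = list(cells)
    if not cells:
        raise ValidationError(f"{role} cell group is empty")
    return norm.cell_index(cells)


def fit_sparse_model(
    norm: NormalizedExpression,
    positive_cells: Sequence[str],
    negative_cells: Sequence[str],
    geneset: GeneSet,
    C: float = 1.0,
) -> SparseModel:
    """Fit the L1-sparse linear model as an exact linear program.

    Training labels are +1 for ``positive_cells`` and -1 for
    ``negative_cells``. Features are the log-normalised expression values of
    the genes in ``geneset`` that are present in the matrix. The LP

        min  0.5 * sum(w+ + w-) + C * sum(eps)
        s.t. y_i ((w+ - w-) . x_i + b) + eps_i >= 1, eps_i, w+, w- >= 0

    is solved with HiGHS; infeasibility/unboundedness raises with the
    solver's diagnostic.
    """
    pos = set(positive_cells)
    neg = set(negative_cells)
    if pos & neg:
        raise ValidationError("positive and negative groups must be disjoint")
    genes = [g for g in geneset.genes if g in set(norm.gene_ids)]
    if not genes:
        raise ValidationError(
            f"no gene of set {geneset.name!r} is present in the matrix"
        )
    pos_idx = _resolve_cells(norm, sorted(pos), "positive")
    neg_idx = _resolve_cells(norm, sorted(neg), "negative")
    gidx = norm.gene_index(genes)
    X = np.vstack(
        [norm.values[np.ix_(gidx, pos_idx)].T, norm.values[np.ix_(gidx, neg_idx)].T]
    )
    y = np.concatenate([np.ones(pos_idx.size), -np.ones(neg_idx.size)])
    n, g = X.shape

    # variables: [w+ (g), w- (g), b+ , b-, eps (n)]
    c = np.concatenate([np.full(2 * g, 0.5), [0.0, 0.0], np.full(n, C)])
    yX = y[:, None] * X
    A_ub = np.hstack([-yX, yX, -y[:, None], y[:, None], -np.eye(n)])
    b_ub = -np.ones(n)
    res = scipy.optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, bounds=[(0, None)] * (2 * g + 2 + n), method="highs"
    )
    if not res.success:
        raise ValidationError(f"sparse-model LP failed: {res.message}")
    sol = res.x
    w = sol[:g] - sol[g : 2 * g]
    b = float(sol[2 * g] - sol[2 * g + 1])
    eps = np.clip(sol[2 * g + 2 :], 0.0, None)
    return SparseModel(
        w=w,
        b=b,
        C=C,
        slack=eps,
        gene_ids=np.asarray(genes, dtype=object),
        objective=float(res.fun),
    )


def categorize(scores: np.ndarray) -> np.ndarray:
    """high iff y > 1, low iff y < -1, middle otherwise (strict bounds)."""
    out = np.full(scores.shape, "middle", dtype=object)
    out[scores > 1] = "high"
    out[scores < -1] = "low"
    return out


def score_cells(model: SparseModel, norm: NormalizedExpression) -> pd.DataFrame:
    """Score every cell with y = w . x + b and bin into high/middle/low.

    Returns a DataFrame indexed by cell id with ``score`` and ``category``
    columns; model genes missing from the matrix contribute 0 (warned).
    """
    present = set(norm.gene_ids)
    keep = np.array([g in present for g in model.gene_ids])
    if not keep.all():
        logger.warning(
            "model genes missing from matrix scored as 0: %s",
            list(model.gene_ids[~keep]),
        )
    genes = list(model.gene_ids[keep])
    w = model.w[keep]
    if genes:
        gidx = norm.gene_index(genes)
        scores = w @ norm.values[gidx, :] + model.b
    else:
        scores = np.full(norm.cell_ids.size, model.b)
    return pd.DataFrame(
        {"score": scores, "category": categorize(scores)},
        index=pd.Index(norm.cell_ids, name="cell_id"),
    )


def compare_groups(
    scores: pd.DataFrame | Mapping[str, pd.DataFrame],
    meta: pd.DataFrame,
    group_pairs: Sequence[tuple[str, str]],
    group_col: str = "group",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of per-cell scores.

    ``scores`` is one score table or a mapping of gene-set name -> table.
    Returns one row per (gene set, pair) with the p-value, the difference
    of group medians, and a significance flag at ``alpha`` (no
    multiple-testing correction; each gene set is a planned comparison).
    """
    tables = scores if isinstance(scores, Mapping) else {"scores": scores}
    rows = []
    for set_name, table in tables.items():
        check_metadata_covers(meta, table.index)
        groups = meta.loc[table.index, group_col]
        for a, b in group_pairs:
            sa = table.loc[(groups == a).to_numpy(), "score"].to_numpy()
            sb = table.loc[(groups == b).to_numpy(), "score"].to_numpy()
            if sa.size < 2 or sb.size < 2:
                raise ValidationError(
                    f"groups {a!r}/{b!r} need >= 2 cells each "
                    f"(got {sa.size}/{sb.size})"
                )
            stat, p = scipy.stats.ranksums(sa, sb)
            p = float(min(max(p, np.finfo(float).tiny), 1.0))
            rows.append(
                {
                    "gene_set": set_name,
                    "group_a": a,
                    "group_b": b,
                    "statistic": float(stat),
                    "p_value": p,
                    "median_diff": float(np.median(sa) - np.median(sb)),
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def high_fraction(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    by: str = "sample",
) -> pd.Series:
    """Per-sample fraction of cells in the ``high`` score category."""
    check_metadata_covers(meta, scores.index)
    cats = meta.loc[scores.index, by]
    out = {}
    for sample, sub in scores.groupby(cats.to_numpy()):
        if sub.empty:
            raise ValidationError(f"empty sample {sample!r}")
        out[sample] = float((sub["category"] == "high").mean())
    return pd.Series(out, name="high_fraction")
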