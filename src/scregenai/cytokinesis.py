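"""Cytokinesis-specific gene panel from GO annotations, and cell counting.

Cytokinesis (GO:0032506, "regulation of cytokinesis" subtree) is the only
cell-cycle stage that unambiguously marks a dividing cardiomyocyte, but
most genes annotated to it also act in unrelated processes. The panel
derivation therefore keeps only genes whose GO annotations are dominated
by cytokinesis subprocesses: for each candidate gene the ratio

    (# cytokinesis-subprocess terms) / (# other terms)

is computed, and genes with ratio <= 0.9 are filtered out (a gene with no
non-cytokinesis term has infinite ratio and is retained). Applied to the
full GO annotation this leaves five genes — ALKBH4, ANLN, AURKB, CNTROB,
KLHDC8B — which ship as the default panel. A cell expressing at least 3
of the 5 panel genes is counted as cytokinetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from scregenai.io_qc import (
    NormalizedExpression,
    RawCountMatrix,
    ValidationError,
    check_metadata_covers,
)

#: the packaged default cytokinesis-specific panel
DEFAULT_PANEL_GENES = ("ALKBH4", "ANLN", "AURKB", "CNTROB", "KLHDC8B")

ANNOTATION_COLUMNS = ("gene_id", "go_id", "is_cytokinesis")


@dataclass
class GOAnnotationTable:
    """Flattened gene -> GO-term rows with a cytokinesis-subprocess flag.

    The boolean flag column is authoritative (it marks terms under
    GO:0032506); deriving it from an OBO release is an optional helper so
    results do not drift with ontology versions.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        if self.table.duplicated(["gene_id", "go_id"]).any():
            raise ValidationError("duplicate (gene, term) annotation rows")
        self.table = self.table.assign(
            is_cytokinesis=self.table["is_cytokinesis"].astype(bool)
        )
        if not self.table["is_cytokinesis"].any():
            raise ValidationError("no cytokinesis-flagged term in annotation table")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GOAnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "go_id": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.assign(is_cytokinesis=self.table["is_cytokinesis"].astype(int))
        out.to_csv(path, sep="\t", index=False)


@dataclass
class CytokinesisPanel:
    """Derived gene panel plus the per-candidate ratio record."""

    genes: list[str]
    derivation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("cytokinesis panel is empty")


def default_panel() -> CytokinesisPanel:
    return CytokinesisPanel(genes=list(DEFAULT_PANEL_GENES))


def derive_specific_genes(
    annotations: GOAnnotationTable, ratio_threshold: float = 0.9
) -> CytokinesisPanel:
    """Apply the term-ratio rule to every gene with a flagged annotation.

    ratio = flagged / unflagged term counts; genes with ratio strictly
    greater than ``ratio_threshold`` are retained (zero unflagged terms
    counts as infinite ratio). Monotone: raising the threshold never adds
    genes.
    """
    df = annotations.table
    per_gene = df.groupby("gene_id")["is_cytokinesis"].agg(["sum", "count"])
    per_gene["n_flagged"] = per_gene["sum"].astype(int)
    per_gene["n_unflagged"] = (per_gene["count"] - per_gene["sum"]).astype(int)
    candidates = per_gene[per_gene["n_flagged"] >= 1].copy()
    if candidates.empty:
        raise ValidationError("no candidate gene carries a cytokinesis term")
    with np.errstate(divide="ignore"):
        candidates["ratio"] = np.where(
            candidates["n_unflagged"] > 0,
            candidates["n_flagged"] / candidates["n_unflagged"],
            np.inf,
        )
    candidates["retained"] = candidates["ratio"] > ratio_threshold
    derivation = (
        candidates[["n_flagged", "n_unflagged", "ratio", "retained"]]
        .reset_index()
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    genes = sorted(candidates.index[candidates["retained"]])
    if not genes:
        raise ValidationError(
            f"no gene passes the ratio threshold {ratio_threshold}"
        )
    return CytokinesisPanel(genes=genes, derivation=derivation)


def flag_cytokinesis_terms(obo_path: str | Path, root: str = "GO:0032506") -> set[str]:
    """Optional helper: terms under ``root`` (is_a/part_of) from an OBO file.

    Requires ``obonet``; the flattened TSV flag column remains the
    authoritative input for panel derivation.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(str(obo_path))
    if root not in graph:
        raise ValidationError(f"{root} not found in {obo_path}")
    # obonet edges point child -> parent, so descendants are ancestors here
    return {root} | set(nx.ancestors(graph, root))


def count_cytokinetic_cells(
    expr: RawCountMatrix | NormalizedExpression,
    panel: CytokinesisPanel | Sequence[str] | None = None,
    meta: pd.DataFrame | None = None,
    by: str = "group",
    min_genes: int = 3,
    expr_threshold: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Count cells expressing >= ``min_genes`` panel genes above threshold.

    "Expressing" means value strictly greater than ``expr_threshold``
    (default 0, i.e. raw count >= 1). Returns the per-cell boolean mask and
    a per-group table of counts and fractions (one ``all`` row when no
    metadata is given).
    """
    if panel is None:
        panel = default_panel()
    genes = list(panel.genes) if isinstance(panel, CytokinesisPanel) else list(panel)
    if isinstance(expr, RawCountMatrix):
        values, gene_ids, cell_ids = expr.counts, expr.gene_ids, expr.cell_ids
    else:
        values, gene_ids, cell_ids = expr.values, expr.gene_ids, expr.cell_ids
    present = [g for g in genes if g in set(gene_ids)]
    if len(present) < min_genes:
        raise ValidationError(
            f"only {len(present)} of {len(genes)} panel genes in matrix; "
            f"need >= {min_genes}"
        )
    pos = {g: i for i, g in enumerate(gene_ids)}
    rows = values[[pos[g] for g in present], :]
    n_expressed = (rows > expr_threshold).sum(axis=0)
    mask = np.asarray(n_expressed >= min_genes)

    if meta is None:
        groups = pd.Series(["all"] * len(cell_ids), index=cell_ids)
    else:
        check_metadata_covers(meta, cell_ids)
        groups = meta.loc[cell_ids, by]
    summary = (
        pd.DataFrame({"group": groups.to_numpy(), "cytokinetic": mask})
        .groupby("group")["cytokinetic"]
        .agg(n_cells="size", n_cytokinetic="sum")
        .assign(fraction=lambda d: d["n_cytokinetic"] / d["n_cells"])
    )
    return mask, summary
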