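"""Graft/host species demultiplexing for xenograft single-cell data.

After mapping reads to a combined human + pig reference, every cell has a
human-mapped and a pig-mapped UMI total. Species separation is strong:
human cells have a pig:human ratio below 1, pig cells above 5. Calls are
therefore made per cluster on summed UMIs (damping low-count cells): a
cluster is human when its summed human UMIs are at least ``fold`` (default
10) times its pig UMIs, pig otherwise; clusters whose larger total is less
than ``gray_band`` times the smaller are flagged ambiguous, since the two
printed rules leave a gap between them. Every cell inherits its cluster's
call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scregenai.clustering import NOISE_LABEL, ClusterAssignment
from scregenai.io_qc import RawCountMatrix, ValidationError


@dataclass
class DualSpeciesCounts:
    """Per-cell human-mapped and pig-mapped UMI totals."""

    cell_ids: np.ndarray
    human_umi: np.ndarray
    pig_umi: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.human_umi = np.asarray(self.human_umi, dtype=np.int64)
        self.pig_umi = np.asarray(self.pig_umi, dtype=np.int64)
        if not (self.cell_ids.shape == self.human_umi.shape == self.pig_umi.shape):
            raise ValidationError("per-cell arrays must align")
        if (self.human_umi < 0).any() or (self.pig_umi < 0).any():
            raise ValidationError("UMI totals must be >= 0")
        if ((self.human_umi == 0) & (self.pig_umi == 0)).any():
            raise ValidationError("every cell needs at least one mapped UMI")

    @classmethod
    def from_matrices(
        cls, human: RawCountMatrix, pig: RawCountMatrix
    ) -> "DualSpeciesCounts":
        """Combine two count matrices over the same barcodes."""
        if list(human.cell_ids) != list(pig.cell_ids):
            raise ValidationError("human and pig matrices must share barcodes")
        return cls(
            cell_ids=human.cell_ids.copy(),
            human_umi=human.total_umi_per_cell(),
            pig_umi=pig.total_umi_per_cell(),
        )

    @classmethod
    def from_combined(
        cls,
        raw: RawCountMatrix,
        human_prefix: str = "GRCh38_",
        pig_prefix: str = "Sscrofa_",
        housekeeping: Sequence[str] | None = None,
    ) -> "DualSpeciesCounts":
        """Split a combined matrix with species-prefixed gene ids.

        ``housekeeping`` optionally restricts the totals to a gene list
        (ids given without the species prefix).
        """
        is_h = np.array([g.startswith(human_prefix) for g in raw.gene_ids])
        is_p = np.array([g.startswith(pig_prefix) for g in raw.gene_ids])
        if not is_h.any() or not is_p.any():
            raise ValidationError("combined matrix needs both species prefixes")
        if housekeeping is not None:
            hk = set(housekeeping)
            stripped = np.array(
                [
                    g[len(human_prefix):] if h else (g[len(pig_prefix):] if p else g)
                    for g, h, p in zip(raw.gene_ids, is_h, is_p)
                ]
            )
            in_hk = np.array([g in hk for g in stripped])
            is_h &= in_hk
            is_p &= in_hk
        return cls(
            cell_ids=raw.cell_ids.copy(),
            human_umi=raw.counts[is_h, :].sum(axis=0),
            pig_umi=raw.counts[is_p, :].sum(axis=0),
        )


@dataclass
class SpeciesCall:
    """Cluster-level species calls and per-cell diagnostics."""

    cluster_species: dict[int, str]
    cell_species: pd.Series
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)


def call_cluster_species(
    counts: DualSpeciesCounts,
    clusters: ClusterAssignment,
    fold: float = 10.0,
    gray_band: float = 3.0,
) -> SpeciesCall:
    """Call each cluster human / pig / ambiguous from summed mapped UMIs."""
    pos = {c: i for i, c in enumerate(counts.cell_ids)}
    missing = [c for c in clusters.cell_ids if c not in pos]
    if missing:
        raise ValidationError(f"cells without dual-species counts: {missing[:5]}")
    idx = np.array([pos[c] for c in clusters.cell_ids])
    h = counts.human_umi[idx].astype(float)
    p = counts.pig_umi[idx].astype(float)

    calls: dict[int, str] = {}
    rows = []
    for cluster in clusters.cluster_ids:
        mask = clusters.labels == cluster
        if not mask.any():
            warnings.warn(f"empty cluster {cluster}; skipped", stacklevel=2)
            continue
        sh, sp = float(h[mask].sum()), float(p[mask].sum())
        hi, lo = max(sh, sp), min(sh, sp)
        if lo > 0 and hi / lo < gray_band:
            call = "ambiguous"
        elif sh >= fold * sp:
            call = "human"
        else:
            call = "pig"
        calls[int(cluster)] = call
        rows.append(
            {
                "cluster": int(cluster),
                "human_umi": sh,
                "pig_umi": sp,
                "pig_to_human_ratio": sp / sh if sh > 0 else np.inf,
                "species": call,
            }
        )
    cell_species = pd.Series(
        [calls.get(int(l), "ambiguous") if l != NOISE_LABEL else "noise" for l in clusters.labels],
        index=pd.Index(clusters.cell_ids, name="cell_id"),
        name="species",
    )
    return SpeciesCall(
        cluster_species=calls,
        cell_species=cell_species,
        diagnostics=pd.DataFrame(rows),
    )


def per_cell_ratio_report(
    counts: DualSpeciesCounts, clusters: ClusterAssignment | None = None
) -> pd.DataFrame:
    """Pig:human UMI ratio per cell (+inf when no human UMI).

    Human cells land in [0, 1), pig cells above 5. With ``clusters``
    supplied, per-cluster quantiles are attached for diagnostics.
    """
    with np.errstate(divide="ignore"):
        ratio = np.where(
            counts.human_umi > 0, counts.pig_umi / counts.human_umi, np.inf
        )
    report = pd.DataFrame(
        {
            "human_umi": counts.human_umi,
            "pig_umi": counts.pig_umi,
            "pig_to_human_ratio": ratio,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )
    if clusters is not None:
        lab = pd.Series(clusters.labels, index=clusters.cell_ids)
        report["cluster"] = lab.reindex(report.index).to_numpy()
        quant = (
            report[report["cluster"].notna()]
            .groupby("cluster")["pig_to_human_ratio"]
            .quantile([0.25, 0.5, 0.75])
            .unstack()
        )
        report.attrs["cluster_quantiles"] = quant
    return report
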