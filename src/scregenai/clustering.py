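"""Clustering in the embedded space, 2-D projection, and marker annotation.

Cells are clustered on the autoencoder's 10-D embedded coordinates by
default (UMAP is used for visualisation only). Three interchangeable
algorithms are exposed — DBSCAN (eps=0.2, min_samples=50), k-means, and
Louvain community detection on a kNN graph — because on a well-separated
embedding they should agree almost perfectly; that agreement is itself a
useful check that the embedding, not the clustering algorithm, determines
the cell-type structure.

Note on DBSCAN defaults: eps is a distance in embedding units and must be
rescaled if the coordinates are not on the logistic-activation scale used
here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from scregenai.autoencoder import (
    AutoencoderConfig,
    AutoencoderModel,
    EmbeddingResult,
    embed,
    train_autoencoder,
)
from scregenai.io_qc import (
    NormalizedExpression,
    RawCountMatrix,
    ValidationError,
    check_metadata_covers,
    normalize_log,
    select_embedding_genes,
)

logger = logging.getLogger(__name__)

NOISE_LABEL = -1


@dataclass
class ClusterAssignment:
    """Per-cell integer cluster labels (-1 marks density-based noise)."""

    cell_ids: np.ndarray
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.cell_ids.shape != self.labels.shape:
            raise ValidationError("cell_ids and labels must align")

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels != NOISE_LABEL])

    def cells_in(self, cluster: int) -> np.ndarray:
        return self.cell_ids[self.labels == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels})


@dataclass
class MarkerPanel:
    """Cell-type name -> canonical marker gene ids."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("marker panel is empty")
        for cell_type, genes in self.markers.items():
            if not genes:
                raise ValidationError(f"no markers for {cell_type!r}")

    def restrict_to(self, gene_ids: Sequence[str]) -> "MarkerPanel":
        present = set(gene_ids)
        kept: dict[str, list[str]] = {}
        for cell_type, genes in self.markers.items():
            found = [g for g in genes if g in present]
            missing = [g for g in genes if g not in present]
            if missing:
                logger.warning("markers for %s missing from matrix: %s", cell_type, missing)
            if found:
                kept[cell_type] = found
        if not kept:
            raise ValidationError("no panel gene present in the matrix")
        return MarkerPanel(kept)


#: canonical mouse cardiac panel used throughout the toolkit
MOUSE_CARDIAC_PANEL = {
    "cardiomyocyte": ["Myh7", "Ryr2"],
    "fibroblast": ["Col1a1", "Col1a2"],
    "endothelial": ["Pecam1", "Kdr"],
    "immune": ["Bin2", "Ifi30"],
    "smooth_muscle": ["Tagln"],
}

#: pig cardiomyocyte markers; ACTC1 is used for the sarcomeric actin marker
PIG_CARDIOMYOCYTE_MARKERS = ["ACTC1", "MYH7", "RYR2"]


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber non-noise labels to 0..k-1 in order of first appearance."""
    out = np.full(labels.shape, NOISE_LABEL, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE_LABEL:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _coords_and_cells(emb) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(emb, EmbeddingResult):
        return emb.coordinates, emb.cell_ids
    arr = np.asarray(emb, dtype=float)
    return arr, np.array([f"cell{i}" for i in range(arr.shape[0])], dtype=object)


def cluster_cells(emb, method: str = "dbscan", **params) -> ClusterAssignment:
    """Cluster embedded cells.

    Parameters
    ----------
    emb
        :class:`EmbeddingResult` or an N x d coordinate array.
    method
        ``"dbscan"`` (eps=0.2, minpts=50), ``"kmeans"`` (k=7, seed) or
        ``"louvain"`` (knn_k=30, resolution=1.0, seed) on a kNN graph.
    """
    coords, cell_ids = _coords_and_cells(emb)
    if method == "dbscan":
        from sklearn.cluster import DBSCAN

        eps = params.pop("eps", 0.2)
        minpts = params.pop("minpts", 50)
        labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(coords)
        used = {"eps": eps, "minpts": minpts}
        if (labels == NOISE_LABEL).all():
            warnings.warn("dbscan labelled every cell as noise", stacklevel=2)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        k = params.pop("k", 7)
        seed = params.pop("seed", 0)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(coords)
        used = {"k": k, "seed": seed}
    elif method == "louvain":
        knn_k = params.pop("knn_k", 30)
        resolution = params.pop("resolution", 1.0)
        seed = params.pop("seed", 0)
        labels = _louvain_knn(coords, knn_k=knn_k, resolution=resolution, seed=seed)
        used = {"knn_k": knn_k, "resolution": resolution, "seed": seed}
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    if params:
        raise ValidationError(f"unknown parameters for {method}: {sorted(params)}")
    return ClusterAssignment(
        cell_ids=cell_ids, labels=_compact_labels(labels), method=method, params=used
    )


def _louvain_knn(coords: np.ndarray, knn_k: int, resolution: float, seed: int) -> np.ndarray:
    import random

    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    k = min(knn_k, n - 1)
    # identical points give an arbitrary tie-broken kNN graph; the only
    # meaningful partition of degenerate geometry is a single community
    if k < 1 or np.allclose(coords, coords[0]):
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {tuple(sorted((i, j))) for i, row in enumerate(idx) for j in row[1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def project_umap(emb, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP layout of the embedding, for plotting only."""
    coords, _ = _coords_and_cells(emb)
    if coords.shape[0] < 10:
        raise ValidationError("need at least 10 cells for a UMAP projection")
    import umap  # heavy import kept local

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    return np.asarray(reducer.fit_transform(coords), dtype=float)


def annotate_clusters(
    norm: NormalizedExpression,
    clusters: ClusterAssignment,
    panel: MarkerPanel | Mapping[str, Sequence[str]],
    min_fold: float = 2.0,
    min_fraction: float = 0.25,
) -> dict[int, str]:
    """Assign each cluster a cell type from canonical markers.

    A cluster receives a type when *every* marker of that type has mean
    expression >= ``min_fold`` times its mean over all other clusters and
    is detected (> 0) in >= ``min_fraction`` of the cluster's cells. No
    matching type -> ``"unassigned"``; more than one -> ``"ambiguous"``.

    Fold changes are computed on the de-logged scale (``2^v - 1``), so a
    ``min_fold`` of 2 means a genuine two-fold difference in normalised
    counts rather than two log2 units.
    """
    if not isinstance(panel, MarkerPanel):
        panel = MarkerPanel(dict(panel))
    panel = panel.restrict_to(norm.gene_ids)
    cell_idx = norm.cell_index(clusters.cell_ids)
    values = np.expm1(norm.values[:, cell_idx] * np.log(2.0))  # back to count scale
    labels = clusters.labels
    result: dict[int, str] = {}
    for cluster in clusters.cluster_ids:
        inside = labels == cluster
        outside = ~inside & (labels != NOISE_LABEL)
        hits = []
        for cell_type, genes in panel.markers.items():
            ok = True
            for gene in genes:
                row = values[norm.gene_index([gene])[0]]
                mean_in = row[inside].mean()
                mean_out = row[outside].mean() if outside.any() else 0.0
                detected = float((row[inside] > 0).mean())
                if mean_in < min_fold * mean_out or detected < min_fraction:
                    ok = False
                    break
            if ok:
                hits.append(cell_type)
        if not hits:
            result[int(cluster)] = "unassigned"
        elif len(hits) == 1:
            result[int(cluster)] = hits[0]
        else:
            result[int(cluster)] = "ambiguous"
    return result


@dataclass
class ClusterComposition:
    """Cluster x category counts/proportions plus exclusivity flags."""

    counts: pd.DataFrame  # clusters x categories
    proportions: pd.DataFrame  # within-category proportions, columns sum to 1
    exclusive: dict[int, str]
    by: str


def composition(
    clusters: ClusterAssignment,
    meta: pd.DataFrame,
    by: str = "sample",
    exclusivity_threshold: float = 0.9,
) -> ClusterComposition:
    """Tabulate cluster membership per sample/group/timepoint.

    ``proportions`` columns give, within each category, the fraction of its
    cells falling into each cluster (columns sum to 1). A cluster drawing
    >= ``exclusivity_threshold`` of its own cells from one category is
    flagged exclusive to it.
    """
    if by not in ("sample", "group", "timepoint"):
        raise ValidationError(f"unknown composition axis {by!r}")
    check_metadata_covers(meta, clusters.cell_ids)
    cats = meta.loc[clusters.cell_ids, by].to_numpy()
    mask = clusters.labels != NOISE_LABEL
    table = pd.crosstab(
        pd.Series(clusters.labels[mask], name="cluster"),
        pd.Series(cats[mask], name=by),
    )
    proportions = table / table.sum(axis=0)
    row_frac = table.div(table.sum(axis=1), axis=0)
    exclusive = {
        int(cluster): str(row.idxmax())
        for cluster, row in row_frac.iterrows()
        if row.max() >= exclusivity_threshold
    }
    return ClusterComposition(
        counts=table, proportions=proportions, exclusive=exclusive, by=by
    )


def subset_and_reembed(
    raw: RawCountMatrix,
    clusters: ClusterAssignment,
    annotations: Mapping[int, str],
    type_label: str,
    ae_config: AutoencoderConfig | None = None,
    min_total_umi: int = 1000,
    min_cells: int = 20,
    cluster_method: str = "kmeans",
    **cluster_params,
) -> tuple[list[str], AutoencoderModel, EmbeddingResult, ClusterAssignment]:
    """Second-level analysis: re-embed and re-cluster one annotated cell type.

    Extracts every cell whose cluster is annotated ``type_label``, reselects
    embedding genes on the subset, retrains the autoencoder, and reclusters —
    the two-level scheme that first isolates a lineage (e.g. cardiomyocytes)
    and then resolves its subpopulations.
    """
    wanted = {c for c, t in annotations.items() if t == type_label}
    if not wanted:
        raise ValidationError(f"no cluster annotated {type_label!r}")
    keep_cells = clusters.cell_ids[np.isin(clusters.labels, sorted(wanted))]
    if keep_cells.size < min_cells:
        raise ValidationError(
            f"only {keep_cells.size} cells labelled {type_label!r}; "
            f"need >= {min_cells}"
        )
    sub_raw = raw.subset_cells(keep_cells)
    genes = select_embedding_genes(sub_raw, min_total_umi=min_total_umi)
    sub_norm = normalize_log(sub_raw)
    model = train_autoencoder(sub_norm, ae_config, gene_ids=genes)
    emb = embed(model, sub_norm.subset_genes(genes))
    assignment = cluster_cells(emb, method=cluster_method, **cluster_params)
    return genes, model, emb, assignment
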