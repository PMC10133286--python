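"""Clustering algorithms, UMAP projection, annotation, composition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import scregenai as s
from scregenai.clustering import NOISE_LABEL, cluster_cells
from scregenai.io_qc import ValidationError

from conftest import make_norm


class TestClusterCells:
    def test_dbscan_recovers_separated_blobs(self, blob_embedding):
        coords, truth = blob_embedding
        assignment = cluster_cells(coords, "dbscan")
        assert len(assignment.cluster_ids) == 3
        assert adjusted_rand_score(truth, assignment.labels) == 1.0

    def test_kmeans_matches_lloyd_oracle(self, blob_embedding):
        coords, _ = blob_embedding
        assignment = cluster_cells(coords, "kmeans", k=3, seed=0)
        # independent Lloyd iteration from the same kmeans++-free start:
        # deterministic farthest-point init makes the oracle self-contained
        centers = [coords[0]]
        for _ in range(2):
            d = np.min(
                [np.sum((coords - c) ** 2, axis=1) for c in centers], axis=0
            )
            centers.append(coords[int(np.argmax(d))])
        centers = np.array(centers)
        for _ in range(50):
            dists = ((coords[:, None, :] - centers[None]) ** 2).sum(axis=2)
            labels = dists.argmin(axis=1)
            centers = np.array(
                [coords[labels == j].mean(axis=0) for j in range(3)]
            )
        assert adjusted_rand_score(labels, assignment.labels) == 1.0

    def test_identical_points_single_cluster(self):
        coords = np.zeros((120, 4))
        for method, params in [
            ("dbscan", {}),
            ("kmeans", {"k": 1}),
            ("louvain", {}),
        ]:
            assignment = cluster_cells(coords, method, **params)
            assert len(set(assignment.labels)) == 1

    def test_labels_stable_under_permutation(self, blob_embedding):
        coords, _ = blob_embedding
        perm = np.random.default_rng(0).permutation(coords.shape[0])
        a = cluster_cells(coords, "kmeans", k=3, seed=1)
        b = cluster_cells(coords[perm], "kmeans", k=3, seed=1)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError, match="unknown clustering"):
            cluster_cells(np.zeros((5, 2)), "spectral")

    def test_dbscan_all_noise_warns(self):
        coords = np.arange(60, dtype=float).reshape(-1, 1) * 100
        with pytest.warns(UserWarning, match="noise"):
            assignment = cluster_cells(coords, "dbscan", eps=0.1, minpts=5)
        assert (assignment.labels == NOISE_LABEL).all()


def test_three_algorithms_agree_on_separated_embedding(blob_embedding):
    """Embedding, not algorithm choice, determines the cluster structure."""
    coords, _ = blob_embedding
    results = [
        cluster_cells(coords, "dbscan"),
        cluster_cells(coords, "kmeans", k=3, seed=0),
        cluster_cells(coords, "louvain", seed=0),
    ]
    for i in range(3):
        for j in range(i + 1, 3):
            ari = adjusted_rand_score(results[i].labels, results[j].labels)
            assert ari >= 0.9


class TestProjectUMAP:
    def test_shape_and_determinism(self, blob_embedding):
        coords, _ = blob_embedding
        a = s.project_umap(coords[:80], seed=5)
        b = s.project_umap(coords[:80], seed=5)
        assert a.shape == (80, 2)
        np.testing.assert_array_equal(a, b)

    def test_blobs_stay_separated(self, blob_embedding):
        coords, truth = blob_embedding
        layout = s.project_umap(coords, seed=5)
        intra, inter = [], []
        for i in range(3):
            pts = layout[truth == i]
            centroid = pts.mean(axis=0)
            intra.append(np.linalg.norm(pts - centroid, axis=1).mean())
        centroids = np.array([layout[truth == i].mean(axis=0) for i in range(3)])
        for i in range(3):
            for j in range(i + 1, 3):
                inter.append(np.linalg.norm(centroids[i] - centroids[j]))
        assert min(inter) > max(intra)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError, match="10 cells"):
            s.project_umap(np.zeros((5, 3)), seed=0)


class TestAnnotateClusters:
    @staticmethod
    def _setup(fold=8.0):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.5, 1.0, size=(4, 60))
        values[0, :30] *= fold  # Myh7 up in cluster 0
        values[1, :30] *= fold  # Ryr2 up in cluster 0
        values[2, 30:] *= fold  # Col1a1 up in cluster 1
        values[3, 30:] *= fold  # Col1a2 up in cluster 1
        norm = make_norm(values, genes=["Myh7", "Ryr2", "Col1a1", "Col1a2"])
        clusters = s.ClusterAssignment(
            cell_ids=norm.cell_ids,
            labels=np.repeat([0, 1], 30),
            method="planted",
        )
        return norm, clusters

    def test_planted_fold_change_recovered(self):
        norm, clusters = self._setup()
        panel = {"cardiomyocyte": ["Myh7", "Ryr2"], "fibroblast": ["Col1a1", "Col1a2"]}
        result = s.annotate_clusters(norm, clusters, panel)
        assert result == {0: "cardiomyocyte", 1: "fibroblast"}

    def test_no_marker_expression_unassigned(self):
        norm, clusters = self._setup()
        zero = make_norm(np.zeros((1, 60)), genes=["Tagln"], cells=norm.cell_ids)
        result = s.annotate_clusters(
            zero, clusters, {"smooth_muscle": ["Tagln"]}
        )
        assert set(result.values()) == {"unassigned"}

    def test_two_matching_types_ambiguous(self):
        norm, clusters = self._setup()
        panel = {"typeA": ["Myh7"], "typeB": ["Ryr2"]}
        result = s.annotate_clusters(norm, clusters, panel)
        assert result[0] == "ambiguous"

    def test_empty_panel_rejected(self):
        norm, clusters = self._setup()
        with pytest.raises(ValidationError, match="empty"):
            s.annotate_clusters(norm, clusters, {})


class TestComposition:
    @staticmethod
    def _meta(cells, samples):
        return pd.DataFrame(
            {"sample": samples, "group": "G1", "timepoint": "D1"},
            index=pd.Index(cells, name="cell_id"),
        )

    def test_single_cluster_single_sample(self):
        clusters = s.ClusterAssignment(
            cell_ids=np.array([f"c{i}" for i in range(5)], dtype=object),
            labels=np.zeros(5, dtype=int),
            method="planted",
        )
        comp = s.composition(clusters, self._meta(clusters.cell_ids, "A"))
        assert comp.proportions.loc[0, "A"] == 1.0
        assert comp.exclusive == {0: "A"}

    def test_planted_split_recovered_and_normalised(self):
        cells = np.array([f"c{i}" for i in range(100)], dtype=object)
        labels = np.array([0] * 90 + [1] * 10)
        clusters = s.ClusterAssignment(cell_ids=cells, labels=labels, method="planted")
        comp = s.composition(clusters, self._meta(cells, "A"))
        assert comp.proportions.loc[0, "A"] == pytest.approx(0.9)
        assert comp.proportions.loc[1, "A"] == pytest.approx(0.1)
        np.testing.assert_allclose(comp.proportions.sum(axis=0), 1.0)
        assert comp.counts.to_numpy().sum() == 100

    def test_missing_metadata_rejected(self):
        clusters = s.ClusterAssignment(
            cell_ids=np.array(["a", "b"], dtype=object),
            labels=np.array([0, 0]),
            method="planted",
        )
        with pytest.raises(ValidationError, match="missing"):
            s.composition(clusters, self._meta(np.array(["a"]), "A"))


class TestSubsetAndReembed:
    def test_second_level_recovers_subprograms(self):
        from scregenai import simulate as sim

        # one "cardiomyocyte" lineage hiding two subprograms + one other type
        spec = sim.SimulationSpec(
            populations=[
                sim.PopulationSpec(name="cm_prolif", n_cells=80),
                sim.PopulationSpec(name="cm_hyper", n_cells=80),
                sim.PopulationSpec(name="fibro", n_cells=80, marker_fold=20.0),
            ],
            n_genes=500,
            seed=21,
        )
        raw, truth, _ = sim.simulate_counts(spec)
        level1 = s.ClusterAssignment(
            cell_ids=raw.cell_ids,
            labels=(truth["population"] == "fibro").to_numpy().astype(int),
            method="planted",
        )
        genes, model, emb, level2 = s.subset_and_reembed(
            raw,
            level1,
            {0: "cardiomyocyte", 1: "fibroblast"},
            "cardiomyocyte",
            ae_config=s.AutoencoderConfig(embedding_dim=10, epochs=100, seed=2),
            min_total_umi=500,
            cluster_method="kmeans",
            k=2,
            seed=0,
        )
        sub_truth = truth.loc[list(level2.cell_ids), "population"]
        assert adjusted_rand_score(sub_truth, level2.labels) >= 0.9
        # gene list was re-selected on the subset
        full_genes = s.select_embedding_genes(raw, min_total_umi=500)
        assert set(genes) <= set(full_genes)
        assert len(genes) < len(full_genes)

    def test_unknown_label_rejected(self, two_population_data):
        raw, truth, _ = two_population_data
        clusters = s.ClusterAssignment(
            cell_ids=raw.cell_ids,
            labels=np.zeros(raw.n_cells, dtype=int),
            method="planted",
        )
        with pytest.raises(ValidationError, match="no cluster annotated"):
            s.subset_and_reembed(raw, clusters, {0: "cardiomyocyte"}, "immune")
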