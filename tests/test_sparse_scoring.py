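"""Sparse linear model fit (LP), scoring, categorisation, group comparison."""

import numpy as np
import pandas as pd
import pytest

import scregenai as s
from scregenai.io_qc import ValidationError
from scregenai.sparse_scoring import categorize

from conftest import lp_oracle_objective, make_norm


def _fit_random_instance(seed):
    rng = np.random.default_rng(seed)
    n_pos = int(rng.integers(3, 11))
    n_neg = int(rng.integers(3, 11))
    g = int(rng.integers(2, 11))
    X = rng.normal(size=(n_pos + n_neg, g)) + np.concatenate(
        [np.full(n_pos, rng.uniform(0, 1.5)), np.zeros(n_neg)]
    )[:, None]
    cells = [f"c{i}" for i in range(n_pos + n_neg)]
    norm = make_norm(X.T, cells=cells)
    C = float(rng.choice([0.1, 1.0, 10.0]))
    geneset = s.GeneSet("random", list(norm.gene_ids))
    model = s.fit_sparse_model(norm, cells[:n_pos], cells[n_pos:], geneset, C=C)
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    return model, X, y, C


class TestFitSparseModel:
    def test_1d_separable_fixture(self):
        norm = make_norm([[1.0, 1.0, -1.0, -1.0]], genes=["gA"],
                         cells=["p1", "p2", "n1", "n2"])
        model = s.fit_sparse_model(
            norm, ["p1", "p2"], ["n1", "n2"], s.GeneSet("g", ["gA"]), C=1.0
        )
        assert model.w[0] == pytest.approx(1.0, abs=1e-9)
        assert model.b == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(model.slack, 0.0, atol=1e-9)
        assert model.objective == pytest.approx(0.5, abs=1e-9)

    def test_identical_groups_unseparable(self):
        norm = make_norm(np.ones((2, 6)), cells=[f"c{i}" for i in range(6)])
        model = s.fit_sparse_model(
            norm, ["c0", "c1", "c2"], ["c3", "c4", "c5"],
            s.GeneSet("g", ["g0", "g1"]), C=1.0,
        )
        np.testing.assert_allclose(model.w, 0.0, atol=1e-9)
        # optimum cost is C * 2 * min(n_pos, n_neg): check against oracle
        oracle = lp_oracle_objective(np.ones((6, 2)),
                                     np.array([1.0, 1, 1, -1, -1, -1]), 1.0)
        assert model.objective == pytest.approx(oracle, abs=1e-6)
        scores = s.score_cells(model, norm)["score"]
        assert scores.nunique() == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_objective_matches_generic_lp_oracle(self, seed):
        model, X, y, C = _fit_random_instance(seed)
        assert model.objective == pytest.approx(
            lp_oracle_objective(X, y, C), abs=1e-6
        )

    def test_sparsity_as_cost_vanishes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 20)) + np.array([1.0] * 10 + [-1.0] * 10)
        norm = make_norm(X, cells=[f"c{i}" for i in range(20)])
        model = s.fit_sparse_model(
            norm, [f"c{i}" for i in range(10)], [f"c{i}" for i in range(10, 20)],
            s.GeneSet("g", list(norm.gene_ids)), C=1e-6,
        )
        assert np.abs(model.w).sum() < 1e-3

    def test_missing_geneset_rejected(self):
        norm = make_norm(np.ones((2, 4)))
        with pytest.raises(ValidationError, match="no gene"):
            s.fit_sparse_model(
                norm, ["c0"], ["c1"], s.GeneSet("g", ["absent"]), C=1.0
            )

    def test_overlapping_groups_rejected(self):
        norm = make_norm(np.ones((2, 4)))
        with pytest.raises(ValidationError, match="disjoint"):
            s.fit_sparse_model(
                norm, ["c0", "c1"], ["c1", "c2"], s.GeneSet("g", ["g0"]), C=1.0
            )


def test_packaged_genesets_cover_phases_and_pathways():
    from scregenai.sparse_scoring import packaged_genesets

    sets = {gs.name: gs for gs in packaged_genesets()}
    assert {"cell_cycle_G1S", "cell_cycle_S", "cell_cycle_G2M", "cell_cycle_M",
            "cell_cycle_cytokinesis", "pathway_MAPK", "pathway_HIPPO",
            "pathway_cAMP", "pathway_JAK_STAT", "pathway_RAS"} <= set(sets)
    assert set(s.DEFAULT_PANEL_GENES) <= set(sets["cell_cycle_cytokinesis"].genes)


class TestScoreCells:
    def test_zero_model_all_middle(self):
        norm = make_norm(np.random.default_rng(0).normal(size=(3, 5)))
        model = s.SparseModel(
            w=np.zeros(3), b=0.0, C=1.0, slack=np.zeros(2),
            gene_ids=norm.gene_ids.copy(), objective=0.0,
        )
        table = s.score_cells(model, norm)
        assert (table["score"] == 0).all()
        assert (table["category"] == "middle").all()

    def test_boundary_categories_strict(self):
        delta = 1e-9
        cats = categorize(np.array([-1 - delta, -1.0, 0.0, 1.0, 1 + delta]))
        assert list(cats) == ["low", "middle", "middle", "middle", "high"]

    def test_linearity_of_mean(self):
        rng = np.random.default_rng(2)
        norm = make_norm(rng.normal(size=(4, 20)))
        model = s.SparseModel(
            w=rng.normal(size=4), b=0.3, C=1.0, slack=np.zeros(2),
            gene_ids=norm.gene_ids.copy(), objective=0.0,
        )
        table = s.score_cells(model, norm)
        mean_profile = make_norm(norm.values.mean(axis=1, keepdims=True))
        mean_score = s.score_cells(model, mean_profile)["score"].iloc[0]
        assert mean_score == pytest.approx(table["score"].mean())

    def test_held_out_program_cells_dominate(self, trajectory_data):
        """Cells generated from the positive program score above negatives."""
        raw, truth = trajectory_data
        norm = s.normalize_log(raw)
        roles = truth.loc[norm.cell_ids, "role"]
        pos = list(norm.cell_ids[(roles == "positive").to_numpy()])[:150]
        neg = list(norm.cell_ids[(roles == "negative").to_numpy()])[:150]
        model = s.fit_sparse_model(
            norm, pos, neg, s.GeneSet("all", list(norm.gene_ids)), C=1.0
        )
        table = s.score_cells(model, norm)
        origin = truth.loc[norm.cell_ids, "role"] == "origin"
        gen = truth.loc[norm.cell_ids, "generating_endpoint"]
        pos_scores = table.loc[(origin & (gen == "positive")).to_numpy(), "score"]
        neg_scores = table.loc[(origin & (gen == "negative")).to_numpy(), "score"]
        assert np.median(pos_scores) > np.median(neg_scores)
        assert (np.quantile(pos_scores, 0.1) > np.quantile(neg_scores, 0.9))


class TestCompareGroups:
    @staticmethod
    def _meta(cells, groups):
        return pd.DataFrame(
            {"sample": "A", "group": groups, "timepoint": "D1"},
            index=pd.Index(cells, name="cell_id"),
        )

    @staticmethod
    def _table(scores):
        return pd.DataFrame(
            {"score": scores, "category": categorize(np.asarray(scores))},
            index=pd.Index([f"c{i}" for i in range(len(scores))], name="cell_id"),
        )

    def test_null_calibration(self):
        """Same-distribution groups are significant in <= 5% of repeats."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            scores = rng.normal(size=400)
            table = self._table(scores)
            meta = self._meta(table.index, ["a"] * 200 + ["b"] * 200)
            out = s.compare_groups(table, meta, [("a", "b")])
            hits += int(out["significant"].iloc[0])
        assert hits <= 5

    def test_two_sd_shift_detected(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        table = self._table(scores)
        meta = self._meta(table.index, ["a"] * 100 + ["b"] * 100)
        out = s.compare_groups(table, meta, [("a", "b")])
        assert out["p_value"].iloc[0] < 0.01
        assert out["median_diff"].iloc[0] < 0

    def test_self_comparison_p_one(self):
        # identical score distributions in both groups
        scores = np.tile(np.linspace(-1, 1, 20), 2)
        table = self._table(scores)
        meta = self._meta(table.index, ["a"] * 20 + ["b"] * 20)
        out = s.compare_groups(table, meta, [("a", "b")])
        assert out["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_small_group_rejected(self):
        table = self._table([0.0, 1.0, 2.0])
        meta = self._meta(table.index, ["a", "a", "b"])
        with pytest.raises(ValidationError, match=">= 2 cells"):
            s.compare_groups(table, meta, [("a", "b")])


class TestHighFraction:
    def test_counting_oracle(self):
        scores = np.array([2.0, 1.5, 3.0] + [0.0] * 7)
        table = pd.DataFrame(
            {"score": scores, "category": categorize(scores)},
            index=pd.Index([f"c{i}" for i in range(10)], name="cell_id"),
        )
        meta = pd.DataFrame(
            {"sample": "h1", "group": "G", "timepoint": "D1"},
            index=table.index,
        )
        out = s.high_fraction(table, meta)
        assert out["h1"] == pytest.approx(0.3)

    def test_all_zero_scores(self):
        scores = np.zeros(6)
        table = pd.DataFrame(
            {"score": scores, "category": categorize(scores)},
            index=pd.Index([f"c{i}" for i in range(6)], name="cell_id"),
        )
        meta = pd.DataFrame(
            {"sample": ["h1"] * 3 + ["h2"] * 3, "group": "G", "timepoint": "D1"},
            index=table.index,
        )
        out = s.high_fraction(table, meta)
        assert (out == 0.0).all()
        assert out.between(0, 1).all()
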