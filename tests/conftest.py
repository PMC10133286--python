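"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from scregenai.io_qc import NormalizedExpression, RawCountMatrix


def make_norm(values, genes=None, cells=None, **kwargs) -> NormalizedExpression:
    """Build a NormalizedExpression straight from a genes x cells array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    cells = cells if cells is not None else [f"c{i}" for i in range(n_cells)]
    return NormalizedExpression(
        values=values,
        gene_ids=np.asarray(genes, dtype=object),
        cell_ids=np.asarray(cells, dtype=object),
        n_umi=kwargs.get("n_umi", np.ones(n_cells)),
        n_genes=kwargs.get("n_genes", np.ones(n_cells)),
        adjusted=kwargs.get("adjusted", False),
    )


def make_raw(counts, genes=None, cells=None, mito_flags=None) -> RawCountMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    cells = cells if cells is not None else [f"c{i}" for i in range(n_cells)]
    return RawCountMatrix(
        counts=counts,
        gene_ids=np.asarray(genes, dtype=object),
        cell_ids=np.asarray(cells, dtype=object),
        mito_flags=mito_flags,
    )


def lp_oracle_objective(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Independent LP solve of the sparse-margin program.

    Dense assembly with a different variable ordering ([b+, b-, eps, w+,
    w-]) and the interior-point HiGHS algorithm, so it shares no code path
    with the package's formulation beyond the generic solver library.
    """
    n, g = X.shape
    n_var = 2 + n + 2 * g
    c = np.zeros(n_var)
    c[2 : 2 + n] = C
    c[2 + n :] = 0.5
    A = np.zeros((n, n_var))
    A[:, 0] = -y
    A[:, 1] = y
    A[:, 2 : 2 + n] = -np.eye(n)
    A[:, 2 + n : 2 + n + g] = -(y[:, None] * X)
    A[:, 2 + n + g :] = y[:, None] * X
    res = scipy.optimize.linprog(
        c,
        A_ub=A,
        b_ub=-np.ones(n),
        bounds=[(0, None)] * n_var,
        method="highs-ipm",
    )
    assert res.success, res.message
    return float(res.fun)


@pytest.fixture(scope="session")
def two_population_data():
    """Two cell types with planted markers, shared across tests."""
    from scregenai import simulate as sim

    spec = sim.SimulationSpec(
        populations=[
            sim.PopulationSpec(name="cardiomyocyte", n_cells=150),
            sim.PopulationSpec(name="fibroblast", n_cells=150),
        ],
        n_genes=600,
        seed=11,
    )
    raw, truth, markers = sim.simulate_counts(spec)
    return raw, truth, markers


@pytest.fixture(scope="session")
def trajectory_data():
    """60/40 two-endpoint mixture fixture with truth labels."""
    from scregenai import simulate as sim

    raw, truth = sim.simulate_trajectory_data(sim.TrajectorySpec(seed=7))
    return raw, truth


@pytest.fixture(scope="session")
def blob_embedding():
    from scregenai import simulate as sim

    return sim.simulate_embedding_blobs(seed=11)
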