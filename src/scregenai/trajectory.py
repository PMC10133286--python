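"""Semisupervised self-training assignment of origin cells to two endpoints.

Given an origin cluster (e.g. the regeneration-primed cardiomyocytes) and
two endpoint clusters it may transform into, the procedure is:

1. fit the sparse linear model on the endpoints (positive y=+1,
   negative y=-1) over the chosen gene scope;
2. score every origin cell; label y > tau as ``to_positive``, y < -tau as
   ``to_negative``, the rest ``inconclusive``;
3. refit with the labelled origin cells merged into their endpoints and
   relabel *all* origin cells;
4. repeat until the three label sets repeat exactly. Revisiting any
   earlier state stops the loop: the immediately preceding state means a
   fixed point (converged), an older one a genuine oscillation (reported
   as non-converged rather than silently broken).

The loop is deterministic: the inner LP solve is deterministic, and the
endpoint roles are canonicalised internally so that swapping the positive
and negative inputs yields the exactly mirrored assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scregenai.io_qc import NormalizedExpression, ValidationError
from scregenai.sparse_scoring import GeneSet, SparseModel, fit_sparse_model

LABELS = ("to_positive", "to_negative", "inconclusive")


@dataclass
class TrajectoryConfig:
    """Self-training parameters.

    ``assign_threshold`` (tau) is the score magnitude beyond which an
    origin cell is committed to an endpoint at each iteration; ``C`` is the
    slack cost of the inner sparse fits; ``gene_set`` restricts the feature
    space (default: all genes of the supplied matrix, i.e. the level-2
    embedding gene list).
    """

    assign_threshold: float = 0.1
    C: float = 1.0
    max_iterations: int = 100
    gene_set: GeneSet | None = None

    def __post_init__(self) -> None:
        if self.assign_threshold <= 0:
            raise ValidationError("assign_threshold must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class TrajectoryAssignment:
    """Final origin-cell labels with the per-iteration history."""

    labels: pd.Series  # origin cell_id -> label in LABELS
    scores: pd.Series  # final-iteration score per origin cell
    history: list[dict] = field(default_factory=list)
    converged: bool = False
    oscillating: bool = False
    iterations: int = 0
    final_model: SparseModel | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "score": self.scores, "iterations": self.iterations}
        )


def _label_state(labels: np.ndarray, cells: np.ndarray) -> tuple[frozenset, frozenset]:
    return (
        frozenset(cells[labels == "to_positive"]),
        frozenset(cells[labels == "to_negative"]),
    )


def infer_trajectory(
    norm: NormalizedExpression,
    origin_cells: Sequence[str],
    positive_cells: Sequence[str],
    negative_cells: Sequence[str],
    config: TrajectoryConfig | None = None,
) -> TrajectoryAssignment:
    """Run the self-training loop; see the module docstring for the scheme."""
    config = config or TrajectoryConfig()
    origin = list(dict.fromkeys(origin_cells))
    pos = list(dict.fromkeys(positive_cells))
    neg = list(dict.fromkeys(negative_cells))
    sets = [set(origin), set(pos), set(neg)]
    if not all(sets):
        raise ValidationError("origin/positive/negative sets must be non-empty")
    if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
        raise ValidationError("origin/positive/negative sets must be disjoint")

    # canonical orientation: always solve with the lexicographically smaller
    # endpoint set as "positive" so that swapping the roles flips the result
    # exactly (the LP is sign-symmetric but its solver need not be).
    flipped = sorted(pos) > sorted(neg)
    if flipped:
        pos, neg = neg, pos

    geneset = config.gene_set or GeneSet(
        name="all_genes", genes=list(norm.gene_ids), source="embedding"
    )
    origin_arr = np.asarray(origin, dtype=object)
    origin_norm = norm.subset_cells(origin)
    tau = config.assign_threshold

    assigned_pos: list[str] = []
    assigned_neg: list[str] = []
    seen_states: list[tuple[frozenset, frozenset]] = []
    history: list[dict] = []
    labels = np.full(origin_arr.shape, "inconclusive", dtype=object)
    scores = np.zeros(origin_arr.shape)
    converged = False
    oscillating = False
    model: SparseModel | None = None

    for iteration in range(1, config.max_iterations + 1):
        model = fit_sparse_model(
            norm, pos + assigned_pos, neg + assigned_neg, geneset, C=config.C
        )
        table = _score(model, origin_norm)
        scores = table.to_numpy()
        labels = np.full(origin_arr.shape, "inconclusive", dtype=object)
        labels[scores > tau] = "to_positive"
        labels[scores < -tau] = "to_negative"
        state = _label_state(labels, origin_arr)
        history.append(
            {
                "iteration": iteration,
                "n_to_positive": int((labels == "to_positive").sum()),
                "n_to_negative": int((labels == "to_negative").sum()),
                "n_inconclusive": int((labels == "inconclusive").sum()),
            }
        )
        if seen_states and state == seen_states[-1]:
            converged = True
            break
        if state in seen_states:
            oscillating = True  # cycle of length > 1: no fixed point
            break
        seen_states.append(state)
        assigned_pos = sorted(state[0])
        assigned_neg = sorted(state[1])

    if flipped:
        swap = {"to_positive": "to_negative", "to_negative": "to_positive"}
        labels = np.array([swap.get(l, l) for l in labels], dtype=object)
        scores = -scores
        for record in history:
            record["n_to_positive"], record["n_to_negative"] = (
                record["n_to_negative"],
                record["n_to_positive"],
            )

    return TrajectoryAssignment(
        labels=pd.Series(labels, index=pd.Index(origin_arr, name="cell_id"), name="label"),
        scores=pd.Series(scores, index=pd.Index(origin_arr, name="cell_id"), name="score"),
        history=history,
        converged=converged,
        oscillating=oscillating,
        iterations=len(history),
        final_model=model,
    )


def _score(model: SparseModel, origin_norm: NormalizedExpression) -> pd.Series:
    gidx = origin_norm.gene_index(list(model.gene_ids))
    vals = model.w @ origin_norm.values[gidx, :] + model.b
    return pd.Series(vals, index=origin_norm.cell_ids)


def trajectory_summary(assignment: TrajectoryAssignment) -> dict[str, float]:
    """Proportions of to_positive / to_negative / inconclusive (sum to 1)."""
    n = assignment.labels.size
    if n == 0:
        raise ValidationError("empty assignment")
    counts = assignment.labels.value_counts()
    return {label: float(counts.get(label, 0)) / n for label in LABELS}
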