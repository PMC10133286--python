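"""Seeded synthetic datasets with ground truth for every pipeline stage.

The generators emulate the structure the analyses assume rather than any
particular tissue: distinct cell types expressing marker-gene blocks,
lineage subprograms (proliferative vs hypertrophic), a three-cluster
trajectory whose origin cells are convex mixtures of two endpoint
programs, dual-species UMI totals with the separation seen in xenograft
mapping, and a toy GO annotation from which the cytokinesis panel rule
recovers its five published genes.

Counts are negative-binomial (variance = mu + dispersion * mu^2) around
per-cell expected profiles; library sizes are log-normal with a median of
5,000 UMIs so the QC window (500-30,000) is actually exercised. All
randomness flows from the spec seed; truth labels are returned as
sidecar tables, never embedded in the matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scregenai.clustering import ClusterAssignment
from scregenai.cytokinesis import DEFAULT_PANEL_GENES, GOAnnotationTable
from scregenai.io_qc import RawCountMatrix, ValidationError, write_mtx
from scregenai.species import DualSpeciesCounts


@dataclass
class PopulationSpec:
    """One cell population: size and its marker block."""

    name: str
    n_cells: int
    n_markers: int = 20
    marker_fold: float = 8.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"population {self.name!r} needs >= 1 cell")
        if self.marker_fold <= 1:
            raise ValidationError("marker_fold must be > 1")


@dataclass
class SimulationSpec:
    """Global parameters of the count simulator."""

    populations: list[PopulationSpec]
    n_genes: int = 1000
    n_mito_genes: int = 10
    library_log_mean: float = math.log(5000.0)
    library_log_sigma: float = 0.4
    mito_fraction_mean: float = 0.05
    mito_fraction_concentration: float = 60.0
    mito_high_fraction: float = 0.0  # share of cells planted at ~0.5 mito
    dispersion: float = 0.5
    n_samples: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("need at least one population")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        total_markers = sum(p.n_markers for p in self.populations)
        if total_markers > self.n_genes - self.n_mito_genes:
            raise ValidationError("marker blocks exceed available genes")
        if not 0 <= self.mito_high_fraction <= 1:
            raise ValidationError("mito_high_fraction must be in [0, 1]")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with mean mu and variance mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    positive = mu > 0
    out[positive] = rng.negative_binomial(r, p[positive])
    return out


def _gene_names(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    n_nuclear = spec.n_genes - spec.n_mito_genes
    names = [f"Gene{i + 1:05d}" for i in range(n_nuclear)]
    names += [f"mt-Gene{i + 1:02d}" for i in range(spec.n_mito_genes)]
    mito = np.zeros(spec.n_genes, dtype=bool)
    mito[n_nuclear:] = True
    return np.asarray(names, dtype=object), mito


def simulate_counts(
    spec: SimulationSpec,
) -> tuple[RawCountMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Simulate a multi-population count matrix with planted markers.

    Returns the raw matrix, a truth/metadata table (population, sample,
    group, timepoint, planted library size and mito fraction per cell),
    and the marker panel (population -> marker gene ids) for annotation.
    """
    rng = np.random.default_rng(spec.seed)
    gene_names, mito_flags = _gene_names(spec)
    n_nuclear = spec.n_genes - spec.n_mito_genes

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_nuclear)
    marker_blocks: dict[str, list[str]] = {}
    profiles: dict[str, np.ndarray] = {}
    offset = 0
    for pop in spec.populations:
        idx = np.arange(offset, offset + pop.n_markers)
        offset += pop.n_markers
        marker_blocks[pop.name] = [str(gene_names[i]) for i in idx]
        prof = base.copy()
        prof[idx] *= pop.marker_fold
        profiles[pop.name] = prof / prof.sum()

    cells = []
    truth_rows = []
    counts = np.zeros((spec.n_genes, sum(p.n_cells for p in spec.populations)), dtype=np.int64)
    col = 0
    a = spec.mito_fraction_mean * spec.mito_fraction_concentration
    b = (1 - spec.mito_fraction_mean) * spec.mito_fraction_concentration
    for pop in spec.populations:
        for i in range(pop.n_cells):
            cell_id = f"{pop.name}_c{i + 1:04d}"
            library = rng.lognormal(spec.library_log_mean, spec.library_log_sigma)
            if spec.mito_high_fraction > 0 and rng.random() < spec.mito_high_fraction:
                f_mito = rng.uniform(0.45, 0.6)
            else:
                f_mito = rng.beta(a, b)
            mu = np.empty(spec.n_genes)
            mu[:n_nuclear] = (1 - f_mito) * library * profiles[pop.name]
            mu[n_nuclear:] = f_mito * library / max(spec.n_mito_genes, 1)
            counts[:, col] = _nb_sample(rng, mu, spec.dispersion)
            sample = f"S{(i % spec.n_samples) + 1}"
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "population": pop.name,
                    "sample": sample,
                    "group": f"G{(i % spec.n_samples) % 2 + 1}",
                    "timepoint": "D1",
                    "library_size": library,
                    "mito_fraction": f_mito,
                }
            )
            cells.append(cell_id)
            col += 1

    raw = RawCountMatrix(
        counts=counts,
        gene_ids=gene_names,
        cell_ids=np.asarray(cells, dtype=object),
        mito_flags=mito_flags,
    )
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return raw, truth, marker_blocks


def simulate_qc_fixture(seed: int = 0) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Matrix with planted violations of each QC rule plus valid cells.

    The truth table records which rule (if any) each cell was planted to
    violate; realised counts are constructed directly so the planted and
    realised QC status coincide.
    """
    rng = np.random.default_rng(seed)
    n_genes = 300
    gene_names = np.asarray(
        [f"Gene{i + 1:04d}" for i in range(n_genes - 5)]
        + [f"mt-Gene{i + 1}" for i in range(5)],
        dtype=object,
    )
    mito = np.zeros(n_genes, dtype=bool)
    mito[-5:] = True

    def make_cell(kind: str) -> np.ndarray:
        vec = np.zeros(n_genes, dtype=np.int64)
        if kind == "valid":
            genes = rng.choice(n_genes - 5, size=250, replace=False)
            vec[genes] = rng.integers(1, 20, size=250)
            deficit = 2000 - vec.sum()
            if deficit > 0:
                vec[genes[0]] += deficit
        elif kind == "low_genes":  # 199 detected genes, healthy totals
            genes = rng.choice(n_genes - 5, size=199, replace=False)
            vec[genes] = rng.integers(3, 20, size=199)
            vec[genes[0]] += max(0, 2000 - vec.sum())
        elif kind == "low_umi":  # 499 UMIs over >= 200 genes
            genes = rng.choice(n_genes - 5, size=240, replace=False)
            vec[genes] = 1
            vec[genes[:259]] += 1  # 240 + 259 = 499
        elif kind == "high_umi":  # 30001 UMIs
            genes = rng.choice(n_genes - 5, size=250, replace=False)
            vec[genes] = 1
            vec[genes[0]] += 30001 - vec.sum()
        elif kind == "high_mito":  # > 25% mitochondrial
            genes = rng.choice(n_genes - 5, size=220, replace=False)
            vec[genes] = 5
            vec[-5:] = 150  # 750 mito of 1850 total
        else:  # pragma: no cover
            raise ValidationError(kind)
        return vec

    kinds = ["valid"] * 12 + ["low_genes", "low_umi", "high_umi", "high_mito"] * 3
    rng.shuffle(kinds)
    counts = np.column_stack([make_cell(k) for k in kinds])
    cell_ids = np.asarray([f"cell{i + 1:03d}" for i in range(len(kinds))], dtype=object)
    raw = RawCountMatrix(counts=counts, gene_ids=gene_names, cell_ids=cell_ids, mito_flags=mito)
    truth = pd.DataFrame({"cell_id": cell_ids, "planted": kinds}).set_index("cell_id")
    return raw, truth


@dataclass
class TrajectorySpec:
    """Two endpoint programs plus an origin population of mixtures."""

    n_origin: int = 500
    n_per_endpoint: int = 200
    n_genes: int = 300
    n_program_genes: int = 40
    program_fold: float = 6.0
    positive_fraction: float = 0.6
    weight_loc: float = 0.8  # mixture weight toward the generating endpoint
    weight_scale: float = 0.06
    library_log_mean: float = math.log(5000.0)
    library_log_sigma: float = 0.3
    dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_program_genes > self.n_genes:
            raise ValidationError("program blocks exceed available genes")
        if not 0 <= self.positive_fraction <= 1:
            raise ValidationError("positive_fraction must be in [0, 1]")


def simulate_trajectory_data(
    spec: TrajectorySpec | None = None,
    mixture_weights: np.ndarray | None = None,
) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Simulate endpoint and origin cells for the self-training loop.

    Origin cells are convex mixtures of the two endpoint mean programs
    (weight lambda toward the positive endpoint) plus count noise; the
    per-cell generating weight and endpoint are recorded in the truth
    table. ``mixture_weights`` overrides the drawn lambdas.
    """
    spec = spec or TrajectorySpec()
    rng = np.random.default_rng(spec.seed)
    gene_names = np.asarray(
        [f"Gene{i + 1:04d}" for i in range(spec.n_genes)], dtype=object
    )
    base = rng.lognormal(0.0, 1.0, size=spec.n_genes)
    pos_prof = base.copy()
    pos_prof[: spec.n_program_genes] *= spec.program_fold
    neg_prof = base.copy()
    neg_prof[spec.n_program_genes : 2 * spec.n_program_genes] *= spec.program_fold
    pos_prof /= pos_prof.sum()
    neg_prof /= neg_prof.sum()

    if mixture_weights is not None:
        lam = np.asarray(mixture_weights, dtype=float)
        if lam.ndim != 1 or ((lam < 0) | (lam > 1)).any():
            raise ValidationError("mixture weights must be in [0, 1]")
        n_origin = lam.size
    else:
        n_origin = spec.n_origin
        n_pos = int(round(spec.positive_fraction * n_origin))
        toward_pos = np.zeros(n_origin, dtype=bool)
        toward_pos[rng.permutation(n_origin)[:n_pos]] = True
        lam = np.where(
            toward_pos,
            np.clip(rng.normal(spec.weight_loc, spec.weight_scale, n_origin), 0.55, 0.98),
            np.clip(rng.normal(1 - spec.weight_loc, spec.weight_scale, n_origin), 0.02, 0.45),
        )

    roles = (
        [("positive", 1.0)] * spec.n_per_endpoint
        + [("negative", 0.0)] * spec.n_per_endpoint
        + [("origin", w) for w in lam]
    )
    counts = np.zeros((spec.n_genes, len(roles)), dtype=np.int64)
    rows = []
    for i, (role, weight) in enumerate(roles):
        library = rng.lognormal(spec.library_log_mean, spec.library_log_sigma)
        profile = weight * pos_prof + (1 - weight) * neg_prof
        counts[:, i] = _nb_sample(rng, library * profile, spec.dispersion)
        cell_id = f"{role}_c{i + 1:04d}"
        rows.append(
            {
                "cell_id": cell_id,
                "role": role,
                "weight": weight,
                "generating_endpoint": (
                    role if role != "origin" else ("positive" if weight > 0.5 else "negative")
                ),
            }
        )
    truth = pd.DataFrame(rows).set_index("cell_id")
    raw = RawCountMatrix(
        counts=counts,
        gene_ids=gene_names,
        cell_ids=np.asarray(truth.index, dtype=object),
        mito_flags=np.zeros(spec.n_genes, dtype=bool),
    )
    return raw, truth


def simulate_dual_species(
    n_cells: int = 500,
    pig_fraction: float = 0.95,
    clusters_per_species: int = 2,
    seed: int = 0,
) -> tuple[DualSpeciesCounts, pd.DataFrame, ClusterAssignment]:
    """Dual-species UMI totals mimicking xenograft mapping separation.

    Pig cells get pig:human UMI ratios > 5 and human cells ratios in
    [0, 1); each species is split into ``clusters_per_species`` clusters so
    cluster-level demultiplexing can be checked against truth.
    """
    if not 0 <= pig_fraction <= 1:
        raise ValidationError("pig_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pig = int(round(pig_fraction * n_cells))
    species = np.array(["pig"] * n_pig + ["human"] * (n_cells - n_pig), dtype=object)
    human_umi = np.zeros(n_cells, dtype=np.int64)
    pig_umi = np.zeros(n_cells, dtype=np.int64)
    for i, sp in enumerate(species):
        primary = max(int(rng.lognormal(math.log(5000.0), 0.4)), 200)
        if sp == "pig":
            ratio = rng.uniform(6.0, 30.0)
            pig_umi[i] = primary
            human_umi[i] = int(primary // ratio)  # keeps pig:human > 5
        else:
            # low cross-mapping for graft cells: ratio in [0, 1), mostly near 0
            frac = min(rng.beta(1.0, 20.0), 0.95)
            human_umi[i] = primary
            pig_umi[i] = int(primary * frac)
    cell_ids = np.asarray([f"cell{i + 1:04d}" for i in range(n_cells)], dtype=object)
    counts = DualSpeciesCounts(cell_ids=cell_ids, human_umi=human_umi, pig_umi=pig_umi)

    labels = np.empty(n_cells, dtype=int)
    next_label = 0
    for sp in ("pig", "human"):
        idx = np.flatnonzero(species == sp)
        if idx.size == 0:
            continue
        k = min(clusters_per_species, idx.size)
        for j, chunk in enumerate(np.array_split(idx, k)):
            labels[chunk] = next_label + j
        next_label += k
    assignment = ClusterAssignment(
        cell_ids=cell_ids, labels=labels, method="planted", params={"seed": seed}
    )
    truth = pd.DataFrame(
        {"cell_id": cell_ids, "species": species, "cluster": labels}
    ).set_index("cell_id")
    return counts, truth, assignment


def simulate_go_annotations() -> GOAnnotationTable:
    """Deterministic toy GO annotation reproducing the five-gene panel.

    Exactly the default panel genes have a flagged/unflagged term ratio
    above 0.9; every other gene in the table sits at or below it.
    """
    flagged_terms = [f"GO:00325{i:02d}" for i in range(6, 20)]  # cytokinesis subtree
    other_terms = [f"GO:00081{i:02d}" for i in range(50)]

    rows: list[dict] = []

    def add(gene: str, n_flagged: int, n_unflagged: int) -> None:
        for i in range(n_flagged):
            rows.append(
                {"gene_id": gene, "go_id": flagged_terms[i], "is_cytokinesis": True}
            )
        start = (7 * len(rows)) % 30  # spread the unflagged terms around
        for i in range(n_unflagged):
            rows.append(
                {
                    "gene_id": gene,
                    "go_id": other_terms[(start + i) % len(other_terms)],
                    "is_cytokinesis": False,
                }
            )

    # the five panel genes: ratio > 0.9
    add("ALKBH4", 2, 1)
    add("ANLN", 4, 2)
    add("AURKB", 3, 0)
    add("CNTROB", 2, 2)
    add("KLHDC8B", 1, 1)
    # candidates that fail the ratio rule (ratio <= 0.9), incl. the boundary
    failing = [
        ("MYH9", 1, 2),
        ("RACGAP1", 2, 3),
        ("KIF23", 3, 4),
        ("ECT2", 1, 3),
        ("PLK1", 2, 5),
        ("CIT", 1, 4),
        ("SEPT9", 2, 4),
        ("PRC1", 3, 5),
        ("CEP55", 1, 2),
        ("CHMP4B", 1, 5),
        ("SPAST", 1, 6),
        ("VPS4A", 2, 6),
        ("AURKA", 3, 6),
        ("INCENP", 2, 7),
        ("CDCA8", 1, 7),
        ("BIRC5", 9, 10),  # exactly 0.9: filtered out
        ("NUSAP1", 4, 5),
        ("TPX2", 1, 8),
        ("KIF4A", 2, 8),
        ("MKLP1", 3, 7),
    ]
    for gene, nf, nu in failing:
        add(gene, nf, nu)
    # background genes with no flagged term (not candidates)
    for i, gene in enumerate(["GAPDH", "ACTB", "TNNT2", "MYH7", "RYR2"]):
        add(gene, 0, 3 + i % 3)
    return GOAnnotationTable(pd.DataFrame(rows))


def simulate_embedding_blobs(
    n_blobs: int = 3,
    n_per_blob: int = 200,
    dim: int = 10,
    sigma: float = 0.02,
    separation: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian blobs in embedding space, with truth labels."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_blobs, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation
    coords = np.vstack(
        [c + rng.normal(scale=sigma, size=(n_per_blob, dim)) for c in centers]
    )
    labels = np.repeat(np.arange(n_blobs), n_per_blob)
    return coords, labels


def simulate_low_rank(
    n_cells: int = 500,
    n_genes: int = 100,
    rank: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Cells x genes data of intrinsic rank ``rank`` plus Gaussian noise.

    Used to benchmark reconstruction fidelity: PCA with ``rank``
    components recovers everything but the noise floor.
    """
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n_cells, rank)) * np.array(
        [2.0 / (1 + i) for i in range(rank)]
    )
    loadings = rng.normal(size=(rank, n_genes))
    return scores @ loadings + rng.normal(scale=noise_sd, size=(n_cells, n_genes))


def write_fixture(
    directory,
    raw: RawCountMatrix,
    truth: pd.DataFrame | None = None,
    marker_blocks: dict[str, list[str]] | None = None,
) -> None:
    """Write the MTX triplet plus sidecar truth/metadata and marker TSVs."""
    from pathlib import Path

    directory = Path(directory)
    write_mtx(raw, directory)
    if truth is not None:
        truth.to_csv(directory / "truth.tsv", sep="\t")
        meta_cols = [c for c in ("sample", "group", "timepoint") if c in truth.columns]
        if meta_cols:
            truth[meta_cols].to_csv(directory / "metadata.tsv", sep="\t")
    if marker_blocks is not None:
        with open(directory / "markers.tsv", "w") as fh:
            for name, genes in marker_blocks.items():
                fh.write(name + "\t" + "\t".join(genes) + "\n")
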