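"""Chained pipeline runner with YAML config, manifest, and seed fan-out.

A run config names the stages to execute (any subset of the fixed DAG
order simulate -> qc -> embed -> cluster -> cytokinesis -> trajectory ->
demux) plus one parameter block per stage. A single global seed fans out
to per-stage seeds by stable hashing so an individual stage rerun is
reproducible in isolation. Every run emits a manifest recording the tool
version, a config hash, per-output checksums and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from scregenai.io_qc import (
    QCThresholds,
    ValidationError,
    load_counts,
    load_metadata,
    normalize_log,
    qc_filter_cells,
    select_embedding_genes,
)
from scregenai.autoencoder import AutoencoderConfig, embed, train_autoencoder
from scregenai.clustering import annotate_clusters, cluster_cells, composition
from scregenai.cytokinesis import (
    GOAnnotationTable,
    count_cytokinetic_cells,
    derive_specific_genes,
)
from scregenai.species import call_cluster_species, per_cell_ratio_report
from scregenai.trajectory import TrajectoryConfig, infer_trajectory, trajectory_summary

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "qc",
    "embed",
    "cluster",
    "cytokinesis",
    "trajectory",
    "demux",
)

_TOP_LEVEL_KEYS = {"seed", "outdir", "input", "stages"} | set(STAGE_ORDER)

_STAGE_KEYS: dict[str, set[str]] = {
    "simulate": {"preset", "n_cells_per_population", "n_genes", "n_populations", "seed"},
    "qc": {"min_genes", "min_umi", "max_umi", "max_mito", "min_total_umi"},
    "embed": {"dim", "l2", "rho", "beta", "epochs", "learning_rate", "seed"},
    "cluster": {"method", "eps", "minpts", "k", "knn", "resolution", "seed", "umap"},
    "cytokinesis": {"annotations", "ratio", "min_genes", "expr_threshold"},
    "trajectory": {"origin", "positive", "negative", "tau", "C", "max_iter"},
    "demux": {"fold", "gray_band"},
}


class ConfigError(ValueError):
    """Raised before any stage runs when the config violates the schema."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("scregenai_run")
    input: Path | None = None
    stages: list[str] = field(default_factory=lambda: ["simulate", "qc", "embed", "cluster"])
    blocks: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(data) - _TOP_LEVEL_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        stages = list(data.get("stages", ["simulate", "qc", "embed", "cluster"]))
        for stage in stages:
            if stage not in STAGE_ORDER:
                raise ConfigError(f"unknown stage {stage!r}")
        blocks = {}
        for stage in STAGE_ORDER:
            block = data.get(stage, {}) or {}
            if not isinstance(block, dict):
                raise ConfigError(f"stage block {stage!r} must be a mapping")
            bad = set(block) - _STAGE_KEYS[stage]
            if bad:
                raise ConfigError(f"unknown keys in {stage!r} block: {sorted(bad)}")
            blocks[stage] = block
        return cls(
            seed=int(data.get("seed", 0)),
            outdir=Path(data.get("outdir", "scregenai_run")),
            input=Path(data["input"]) if data.get("input") else None,
            stages=sorted(stages, key=STAGE_ORDER.index),
            blocks=blocks,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "outputs": self.outputs,
                    "timings_sec": {k: round(v, 3) for k, v in self.timings.items()},
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in DAG order and write the manifest."""
    from scregenai import __version__

    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(
            {"seed": config.seed, "stages": config.stages, "blocks": config.blocks},
            sort_keys=True,
        ).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, config_hash=config_hash, seed=config.seed)

    state: dict = {}
    for stage in config.stages:
        start = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, outdir)
        except Exception as exc:
            raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
        manifest.timings[stage] = time.perf_counter() - start
        logger.info("stage %s done in %.2fs", stage, manifest.timings[stage])

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.outputs[str(path.relative_to(outdir))] = _sha256(path)
    manifest.write(outdir / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> None:
    from scregenai import simulate as sim

    block = config.blocks["simulate"]
    preset = block.get("preset", "two-lineage")
    seed = int(block.get("seed", stage_seed(config.seed, "simulate")))
    if preset == "two-lineage":
        n_cells = int(block.get("n_cells_per_population", 150))
        n_pops = int(block.get("n_populations", 2))
        spec = sim.SimulationSpec(
            populations=[
                sim.PopulationSpec(name=f"pop{i + 1}", n_cells=n_cells)
                for i in range(n_pops)
            ],
            n_genes=int(block.get("n_genes", 600)),
            seed=seed,
        )
        raw, truth, markers = sim.simulate_counts(spec)
        sim.write_fixture(outdir / "simulated", raw, truth, markers)
        state.update(raw=raw, truth=truth, markers=markers)
    elif preset == "trajectory":
        raw, truth = sim.simulate_trajectory_data(sim.TrajectorySpec(seed=seed))
        sim.write_fixture(outdir / "simulated", raw, truth)
        state.update(raw=raw, truth=truth)
    elif preset == "dual-species":
        counts, truth, clusters = sim.simulate_dual_species(seed=seed)
        truth.to_csv(outdir / "dual_species_truth.tsv", sep="\t")
        state.update(dual_counts=counts, truth=truth, clusters=clusters)
    else:
        raise ConfigError(f"unknown simulate preset {preset!r}")


def _stage_qc(config: RunConfig, state: dict, outdir: Path) -> None:
    block = config.blocks["qc"]
    if "raw" not in state:
        if config.input is None:
            raise ConfigError("qc stage needs a simulate stage or an input path")
        state["raw"] = load_counts(config.input)
        meta_path = config.input / "metadata.tsv" if config.input.is_dir() else None
        if meta_path is not None and meta_path.exists():
            state["truth"] = load_metadata(meta_path)
    thresholds = QCThresholds(
        min_genes_per_cell=int(block.get("min_genes", 200)),
        min_umi=int(block.get("min_umi", 500)),
        max_umi=int(block.get("max_umi", 30000)),
        max_mito_fraction=float(block.get("max_mito", 0.25)),
    )
    filtered = qc_filter_cells(state["raw"], thresholds)
    state["filtered"] = filtered
    state["norm"] = normalize_log(filtered)
    state["embedding_genes"] = select_embedding_genes(
        filtered, min_total_umi=int(block.get("min_total_umi", 1000))
    )
    pd.DataFrame({"cell_id": filtered.cell_ids}).to_csv(
        outdir / "qc_cells.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene_id": state["embedding_genes"]}).to_csv(
        outdir / "embedding_genes.tsv", sep="\t", index=False
    )


def _stage_embed(config: RunConfig, state: dict, outdir: Path) -> None:
    block = config.blocks["embed"]
    if "norm" not in state:
        raise ConfigError("embed stage requires the qc stage")
    ae_config = AutoencoderConfig(
        embedding_dim=int(block.get("dim", 10)),
        l2_weight=float(block.get("l2", 0.001)),
        sparsity_target=float(block.get("rho", 0.05)),
        sparsity_weight=float(block.get("beta", 1.0)),
        epochs=int(block.get("epochs", 200)),
        learning_rate=float(block.get("learning_rate", 1e-3)),
        seed=int(block.get("seed", stage_seed(config.seed, "embed"))),
    )
    model = train_autoencoder(state["norm"], ae_config, gene_ids=state["embedding_genes"])
    result = embed(model, state["norm"].subset_genes(state["embedding_genes"]))
    state["model"] = model
    state["embedding"] = result
    model.save(outdir / "autoencoder.h5")
    emb_df = pd.DataFrame(
        result.coordinates,
        index=pd.Index(result.cell_ids, name="cell_id"),
        columns=[f"dim{i + 1}" for i in range(result.coordinates.shape[1])],
    )
    emb_df.to_csv(outdir / "embedding.tsv", sep="\t")


def _stage_cluster(config: RunConfig, state: dict, outdir: Path) -> None:
    block = config.blocks["cluster"]
    if "embedding" not in state:
        raise ConfigError("cluster stage requires the embed stage")
    method = block.get("method", "kmeans")
    seed = int(block.get("seed", stage_seed(config.seed, "cluster")))
    params: dict = {}
    if method == "dbscan":
        params = {"eps": float(block.get("eps", 0.2)), "minpts": int(block.get("minpts", 50))}
    elif method == "kmeans":
        params = {"k": int(block.get("k", 7)), "seed": seed}
    elif method == "louvain":
        params = {
            "knn_k": int(block.get("knn", 30)),
            "resolution": float(block.get("resolution", 1.0)),
            "seed": seed,
        }
    assignment = cluster_cells(state["embedding"], method=method, **params)
    state["clusters"] = assignment
    assignment.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    if state.get("markers"):
        annotations = annotate_clusters(state["norm"], assignment, state["markers"])
        state["annotations"] = annotations
        pd.Series(annotations, name="cell_type").rename_axis("cluster").to_csv(
            outdir / "cluster_annotations.tsv", sep="\t"
        )
    truth = state.get("truth")
    if truth is not None and "sample" in getattr(truth, "columns", []):
        comp = composition(assignment, truth, by="sample")
        comp.counts.to_csv(outdir / "composition_counts.tsv", sep="\t")
        comp.proportions.to_csv(outdir / "composition_proportions.tsv", sep="\t")


def _stage_cytokinesis(config: RunConfig, state: dict, outdir: Path) -> None:
    from scregenai import simulate as sim

    block = config.blocks["cytokinesis"]
    if block.get("annotations"):
        table = GOAnnotationTable.from_tsv(block["annotations"])
    else:
        table = sim.simulate_go_annotations()
    panel = derive_specific_genes(table, ratio_threshold=float(block.get("ratio", 0.9)))
    with open(outdir / "cytokinesis_panel.txt", "w") as fh:
        fh.writelines(f"{g}\n" for g in panel.genes)
    state["panel"] = panel
    expr = state.get("filtered") or state.get("raw")
    if expr is not None:
        present = sum(g in set(expr.gene_ids) for g in panel.genes)
        if present >= int(block.get("min_genes", 3)):
            _, summary = count_cytokinetic_cells(
                expr,
                panel,
                min_genes=int(block.get("min_genes", 3)),
                expr_threshold=float(block.get("expr_threshold", 0.0)),
            )
            summary.to_csv(outdir / "cytokinesis_counts.tsv", sep="\t")


def _stage_trajectory(config: RunConfig, state: dict, outdir: Path) -> None:
    block = config.blocks["trajectory"]
    truth = state.get("truth")
    norm = state.get("norm")
    if norm is None or truth is None or "role" not in getattr(truth, "columns", []):
        raise ConfigError("trajectory stage requires the trajectory simulate preset + qc")
    roles = truth.loc[norm.cell_ids, "role"]
    origin = list(norm.cell_ids[(roles == "origin").to_numpy()])
    positive = list(norm.cell_ids[(roles == "positive").to_numpy()])
    negative = list(norm.cell_ids[(roles == "negative").to_numpy()])
    t_config = TrajectoryConfig(
        assign_threshold=float(block.get("tau", 0.1)),
        C=float(block.get("C", 1.0)),
        max_iterations=int(block.get("max_iter", 100)),
    )
    assignment = infer_trajectory(norm, origin, positive, negative, t_config)
    state["trajectory"] = assignment
    assignment.to_frame().to_csv(outdir / "trajectory.tsv", sep="\t")
    with open(outdir / "trajectory_history.jsonl", "w") as fh:
        for record in assignment.history:
            fh.write(json.dumps(record) + "\n")
    with open(outdir / "trajectory_summary.json", "w") as fh:
        json.dump(trajectory_summary(assignment), fh, indent=2)


def _stage_demux(config: RunConfig, state: dict, outdir: Path) -> None:
    block = config.blocks["demux"]
    counts = state.get("dual_counts")
    clusters = state.get("clusters")
    if counts is None:
        raise ConfigError("demux stage requires the dual-species simulate preset")
    if clusters is None:
        clusters = state.get("clusters") or state.get("truth_clusters")
    if clusters is None:
        raise ConfigError("demux stage requires cluster labels")
    call = call_cluster_species(
        counts,
        clusters,
        fold=float(block.get("fold", 10.0)),
        gray_band=float(block.get("gray_band", 3.0)),
    )
    call.cell_species.to_csv(outdir / "species_calls.tsv", sep="\t")
    call.diagnostics.to_csv(outdir / "species_diagnostics.tsv", sep="\t", index=False)
    per_cell_ratio_report(counts, clusters).to_csv(outdir / "species_ratios.tsv", sep="\t")
    state["species"] = call


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "embed": _stage_embed,
    "cluster": _stage_cluster,
    "cytokinesis": _stage_cytokinesis,
    "trajectory": _stage_trajectory,
    "demux": _stage_demux,
}
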