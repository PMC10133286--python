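"""Three-layer sparse autoencoder for cell embedding, plus PCA baselines.

The network is deliberately shallow: input genes -> one hidden (embedded)
layer of ``embedding_dim`` logistic units -> linear synthetic output of
the same dimensionality as the input. Training minimises

    E = (1/N) sum_i ||x_i - y_i||^2  +  l2_weight * ||W||^2  +  beta * Q

where x_i is a cell's (per-gene min-max scaled) expression vector, y_i its
reconstruction, ||W||^2 the squared Frobenius norm of both weight
matrices, and Q a KL-divergence sparsity penalty pulling the mean hidden
activation of each embedded unit toward a small target rho. The embedded
layer after training is the low-dimensional representation used for
clustering; reconstruction fidelity is summarised by the mean squared
per-cell reconstruction error S, which is also used to compare the
autoencoder against PCA with all or only the top-k components.

Inputs are min-max scaled per gene to [0, 1] before entering the
logistic encoder; the linear decoder maps straight back to the original
expression scale, so the reconstruction term of the training loss is the
same quantity S reports. Implementation is pure NumPy with analytic
gradients and Adam; at these problem sizes (thousands of cells, a
10-unit hidden layer) a framework adds nothing but a dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from scregenai.io_qc import NormalizedExpression, ValidationError


@dataclass
class AutoencoderConfig:
    """Training hyperparameters; every random choice flows from ``seed``."""

    embedding_dim: int = 10
    l2_weight: float = 0.001
    sparsity_target: float = 0.05
    sparsity_weight: float = 1.0
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None: full batch up to 5000 cells, else 256
    init: str = "pca"  # encoder init: principal directions or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValidationError("embedding_dim must be >= 1")
        if self.l2_weight < 0:
            raise ValidationError("l2_weight must be >= 0")
        if not 0 < self.sparsity_target < 1:
            raise ValidationError("sparsity_target must be in (0, 1)")
        if self.init not in ("pca", "random"):
            raise ValidationError("init must be 'pca' or 'random'")


#: training recipe used when benchmarking raw reconstruction capacity
#: against PCA: both regularisers off (they deliberately trade fidelity
#: for small weights / sparse codes) and enough full-batch epochs to
#: converge at desk scale.
FIDELITY_BENCHMARK = dict(
    l2_weight=0.0, sparsity_weight=0.0, epochs=500, learning_rate=1e-2
)


@dataclass
class AutoencoderModel:
    """Trained weights, the loss trace, and per-gene input scaling."""

    encoder_weights: np.ndarray  # genes x embedding_dim
    encoder_bias: np.ndarray
    decoder_weights: np.ndarray  # embedding_dim x genes
    decoder_bias: np.ndarray
    gene_ids: np.ndarray
    scale_min: np.ndarray  # per-gene minimum of the training data
    scale_range: np.ndarray  # per-gene max - min (zero-range genes -> 1)
    loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    config: AutoencoderConfig = field(default_factory=AutoencoderConfig)

    @property
    def embedding_dim(self) -> int:
        return self.encoder_weights.shape[1]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            for name in (
                "encoder_weights",
                "encoder_bias",
                "decoder_weights",
                "decoder_bias",
                "scale_min",
                "scale_range",
                "loss_trace",
            ):
                fh.create_dataset(name, data=getattr(self, name))
            fh.create_dataset(
                "gene_ids", data=np.array([str(g) for g in self.gene_ids], dtype="S")
            )
            cfg = fh.create_group("config")
            for key, value in vars(self.config).items():
                cfg.attrs[key] = -1 if value is None else value

    @classmethod
    def load(cls, path: str | Path) -> "AutoencoderModel":
        with h5py.File(path, "r") as fh:
            kwargs = {
                name: fh[name][()]
                for name in (
                    "encoder_weights",
                    "encoder_bias",
                    "decoder_weights",
                    "decoder_bias",
                    "scale_min",
                    "scale_range",
                    "loss_trace",
                )
            }
            gene_ids = np.array([g.decode() for g in fh["gene_ids"][()]], dtype=object)
            attrs = dict(fh["config"].attrs)
            batch = int(attrs.get("batch_size", -1))
            config = AutoencoderConfig(
                embedding_dim=int(attrs["embedding_dim"]),
                l2_weight=float(attrs["l2_weight"]),
                sparsity_target=float(attrs["sparsity_target"]),
                sparsity_weight=float(attrs["sparsity_weight"]),
                epochs=int(attrs["epochs"]),
                learning_rate=float(attrs["learning_rate"]),
                batch_size=None if batch < 0 else batch,
                seed=int(attrs["seed"]),
            )
        return cls(gene_ids=gene_ids, config=config, **kwargs)


@dataclass
class EmbeddingResult:
    """Embedded coordinates (cells x d) and reconstructions (cells x genes)."""

    coordinates: np.ndarray
    reconstruction: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != self.reconstruction.shape[0]:
            raise ValidationError("coordinates/reconstruction row mismatch")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("non-finite embedding coordinates")


@dataclass
class ReconstructionScore:
    """Mean squared per-cell reconstruction error S with a method label."""

    S: float
    method: str = "autoencoder"

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValidationError("S must be >= 0")


def _cells_by_genes(X, gene_ids=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept NormalizedExpression (genes x cells) or ndarray (cells x genes)."""
    if isinstance(X, NormalizedExpression):
        if gene_ids is not None:
            X = X.subset_genes(list(gene_ids))
        return X.values.T.copy(), np.asarray(X.gene_ids), np.asarray(X.cell_ids)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expression must be 2-D")
    genes = (
        np.asarray(gene_ids, dtype=object)
        if gene_ids is not None
        else np.array([f"g{i}" for i in range(arr.shape[1])], dtype=object)
    )
    cells = np.array([f"cell{i}" for i in range(arr.shape[0])], dtype=object)
    return arr.copy(), genes, cells


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_autoencoder(
    X,
    config: AutoencoderConfig | None = None,
    gene_ids: Sequence[str] | None = None,
) -> AutoencoderModel:
    """Train the three-layer sparse autoencoder.

    Parameters
    ----------
    X
        :class:`NormalizedExpression` (optionally restricted via
        ``gene_ids``, typically the output of
        :func:`scregenai.io_qc.select_embedding_genes`) or a cells x genes
        array.
    config
        :class:`AutoencoderConfig`; the defaults give a 10-D embedding.

    Returns
    -------
    AutoencoderModel with a per-epoch loss trace; reruns with the same
    config and data are bit-identical.
    """
    config = config or AutoencoderConfig()
    data, genes, _ = _cells_by_genes(X, gene_ids)
    n_cells, n_genes = data.shape
    if n_cells < 2:
        raise ValidationError("need at least 2 cells to train")
    if not np.isfinite(data).all():
        raise ValidationError("training data must be finite")
    if config.embedding_dim >= n_genes:
        raise ValidationError("embedding_dim must be < number of input genes")

    # per-gene min-max scaling to [0, 1]; constant genes map to 0
    x_min = data.min(axis=0)
    x_range = data.max(axis=0) - x_min
    x_range = np.where(x_range > 0, x_range, 1.0)
    Xs = (data - x_min) / x_range

    rng = np.random.default_rng(config.seed)
    d = config.embedding_dim

    # encoder init: principal directions of the scaled data (default) keep
    # the hidden units in the near-linear sigmoid regime from the start;
    # "random" falls back to a Glorot-uniform draw.
    if config.init == "pca":
        centered = Xs - Xs.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        W1 = np.zeros((n_genes, d))
        n_avail = min(d, vt.shape[0])
        W1[:, :n_avail] = vt[:n_avail].T
        if n_avail < d:
            limit = np.sqrt(6.0 / (n_genes + d))
            W1[:, n_avail:] = rng.uniform(-limit, limit, size=(n_genes, d - n_avail))
    else:
        limit = np.sqrt(6.0 / (n_genes + d))
        W1 = rng.uniform(-limit, limit, size=(n_genes, d))
    b1 = -Xs.mean(axis=0) @ W1
    W2 = np.zeros((d, n_genes))
    b2 = data.mean(axis=0)

    if config.batch_size is not None:
        batch_size = config.batch_size
    else:
        batch_size = n_cells if n_cells <= 5000 else 256

    rho = config.sparsity_target
    beta = config.sparsity_weight
    lam = config.l2_weight
    lr = config.learning_rate
    m = [np.zeros_like(W1), np.zeros_like(b1)]
    v = [np.zeros_like(W1), np.zeros_like(b1)]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    trace = np.empty(config.epochs)
    eye = np.eye(d)

    for epoch in range(config.epochs):
        order = rng.permutation(n_cells) if batch_size < n_cells else np.arange(n_cells)
        for start in range(0, n_cells, batch_size):
            rows = order[start : start + batch_size]
            batch = Xs[rows]
            target = data[rows]
            B = batch.shape[0]
            H = _sigmoid(batch @ W1 + b1)

            # decoder subproblem is quadratic in (W2, b2): solve the ridge
            # normal equations exactly instead of descending them
            h_mean = H.mean(axis=0)
            t_mean = target.mean(axis=0)
            Hc = H - h_mean
            W2 = np.linalg.solve(
                Hc.T @ Hc / B + (lam + 1e-10) * eye, Hc.T @ (target - t_mean) / B
            )
            b2 = t_mean - h_mean @ W2
            Y = H @ W2 + b2
            rho_hat = np.clip(h_mean, 1e-6, 1 - 1e-6)

            # encoder gradient: d recon / dY = (2/B)(Y - x), plus the
            # KL-sparsity pull on the mean activations and l2 on W1
            dY = (2.0 / B) * (Y - target)
            dH = dY @ W2.T
            dKL = beta * (-rho / rho_hat + (1 - rho) / (1 - rho_hat)) / B
            dH = dH + dKL[None, :]
            dZ1 = dH * H * (1 - H)
            gW1 = batch.T @ dZ1 + 2.0 * lam * W1
            gb1 = dZ1.sum(axis=0)

            step += 1
            for p, g, mi, vi in zip([W1, b1], [gW1, gb1], m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**step)
                vhat = vi / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + eps_adam)

        H = _sigmoid(Xs @ W1 + b1)
        Y = H @ W2 + b2
        rho_hat = np.clip(H.mean(axis=0), 1e-6, 1 - 1e-6)
        recon = float(np.mean(np.sum((Y - data) ** 2, axis=1)))
        kl = float(
            np.sum(
                rho * np.log(rho / rho_hat)
                + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
            )
        )
        loss = recon + lam * (float(np.sum(W1**2)) + float(np.sum(W2**2))) + beta * kl
        if not np.isfinite(loss):
            raise ValidationError(
                f"non-finite loss at epoch {epoch}; reduce learning_rate="
                f"{config.learning_rate}"
            )
        trace[epoch] = loss

    return AutoencoderModel(
        encoder_weights=W1,
        encoder_bias=b1,
        decoder_weights=W2,
        decoder_bias=b2,
        gene_ids=genes,
        scale_min=x_min,
        scale_range=x_range,
        loss_trace=trace,
        config=config,
    )


def embed(model: AutoencoderModel, X, gene_ids: Sequence[str] | None = None) -> EmbeddingResult:
    """Encode cells with a trained model; reconstructions are inverse-scaled.

    The gene list of ``X`` must match the model's training gene list.
    """
    data, genes, cells = _cells_by_genes(X, gene_ids)
    if list(genes) != list(model.gene_ids):
        missing = sorted(set(model.gene_ids) - set(genes))
        raise ValidationError(
            f"gene list mismatch with model (missing {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''})"
        )
    Xs = (data - model.scale_min) / model.scale_range
    H = _sigmoid(Xs @ model.encoder_weights + model.encoder_bias)
    reconstruction = H @ model.decoder_weights + model.decoder_bias
    return EmbeddingResult(coordinates=H, reconstruction=reconstruction, cell_ids=cells)


def reconstruction_similarity(X, X_hat, method: str = "autoencoder") -> ReconstructionScore:
    """S = (1/N) * sum over cells of the squared reconstruction error.

    ``X`` and ``X_hat`` are cells x genes arrays (or NormalizedExpression);
    lower S means the low-dimensional representation preserves more of the
    original data.
    """
    a, _, _ = _cells_by_genes(X)
    b, _, _ = _cells_by_genes(X_hat)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    s = float(np.mean(np.sum((a - b) ** 2, axis=1)))
    return ReconstructionScore(S=s, method=method)


def pca_reconstruct(X, k: int | None = None) -> np.ndarray:
    """Project onto principal components and invert the projection.

    ``k=None`` uses all feasible components (exact reconstruction up to
    numerical noise); an integer ``k`` keeps only the top-k components, the
    baseline against which the autoencoder's S score is compared.
    """
    from sklearn.decomposition import PCA

    data, _, _ = _cells_by_genes(X)
    n_cells, n_genes = data.shape
    max_k = min(n_cells, n_genes)
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ValidationError(f"k={k} outside feasible range [1, {max_k}]")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(data)
    return pca.inverse_transform(scores)
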