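"""Entity relation network: reconstruction-trained entity embeddings.

Each row entity of a fused binary adjacency matrix gets a fixed-length real
embedding: row i of a projection matrix ``W_emb`` (the one-hot product is
realized as a row lookup, never materialized).  A two-layer head maps the
embedding to a probability for every column,

    P_i = sigmoid( sigmoid( relu(v_i) @ W1 ) @ W2 ),

and training minimizes the squared reconstruction error between ``P`` and the
binary association profiles.  The network is deliberately driven to overfit:
a near-exact reconstruction forces entities with similar association profiles
close together in embedding space, which is the signal the downstream pair
classifier consumes.  The embedding length is independent of the number of
columns, so new association sources widen the reconstruction target without
growing the representation.

A *general embedder* ``F_m`` is fitted afterwards: a feedforward inverse map
from an association profile to an embedding, so entities outside the training
vocabulary can be embedded directly from their profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._optim import Adam, DivergenceError, relu, sigmoid, uniform_fan_in
from .data import AdjacencyMatrix, EntityVocabulary

__all__ = [
    "ERNConfig",
    "ERNModel",
    "EmbeddingMatrix",
    "GeneralEmbedder",
    "init_ern",
    "ern_forward",
    "ern_loss",
    "train_ern",
    "get_embeddings",
    "fit_general_embedder",
    "embed_profile",
]


@dataclass(frozen=True)
class ERNConfig:
    """Hyperparameters of the embedding network.

    ``stop_loss`` is the mean squared error *per matrix entry* below which
    training stops early; the reconstruction objective has no regularization
    because overfitting is intended.
    """

    embedding_dim: int = 128
    hidden_dim: int = 256
    epochs: int = 2000
    learning_rate: float = 1e-3
    seed: int = 0
    use_bias: bool = False
    stop_loss: float = 1e-4

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.hidden_dim < 1:
            raise ValueError("embedding_dim and hidden_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.stop_loss < 0:
            raise ValueError("stop_loss must be non-negative")


@dataclass
class ERNModel:
    """Projection matrix plus two-layer reconstruction head."""

    embedding_weights: np.ndarray  # (n_entities, embedding_dim)
    head_weights_1: np.ndarray     # (embedding_dim, hidden_dim)
    head_weights_2: np.ndarray     # (hidden_dim, n_columns)
    config: ERNConfig
    head_bias_1: np.ndarray | None = None
    head_bias_2: np.ndarray | None = None

    @property
    def n_entities(self) -> int:
        return self.embedding_weights.shape[0]

    @property
    def n_columns(self) -> int:
        return self.head_weights_2.shape[1]

    def _params(self) -> list[np.ndarray]:
        params = [self.embedding_weights, self.head_weights_1, self.head_weights_2]
        if self.config.use_bias:
            params += [self.head_bias_1, self.head_bias_2]
        return params


@dataclass(frozen=True)
class EmbeddingMatrix:
    """One fixed-length embedding vector per vocabulary entry."""

    row_vocab: EntityVocabulary
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.row_vocab):
            raise ValueError("one vector per vocabulary entry required")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector_of(self, name: str) -> np.ndarray:
        return self.vectors[self.row_vocab.index_of(name)]


def init_ern(config: ERNConfig, n_entities: int, n_columns: int) -> ERNModel:
    """Seeded initialization; two calls with equal arguments are bitwise identical."""
    if n_entities < 1 or n_columns < 1:
        raise ValueError("n_entities and n_columns must be >= 1")
    rng = np.random.default_rng(config.seed)
    # rows are looked up, not summed over, so the embedding scale follows
    # the embedding width rather than the entity count
    emb_bound = 1.0 / np.sqrt(config.embedding_dim)
    model = ERNModel(
        embedding_weights=rng.uniform(
            -emb_bound, emb_bound, size=(n_entities, config.embedding_dim)
        ),
        head_weights_1=uniform_fan_in(rng, config.embedding_dim, config.hidden_dim),
        head_weights_2=uniform_fan_in(rng, config.hidden_dim, n_columns),
        config=config,
    )
    if config.use_bias:
        model.head_bias_1 = np.zeros(config.hidden_dim)
        model.head_bias_2 = np.zeros(n_columns)
    return model


def _forward_all(model: ERNModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reconstruction probabilities for every entity; returns (R, H, P)."""
    r = relu(model.embedding_weights)
    z1 = r @ model.head_weights_1
    if model.head_bias_1 is not None:
        z1 = z1 + model.head_bias_1
    h = sigmoid(z1)
    z2 = h @ model.head_weights_2
    if model.head_bias_2 is not None:
        z2 = z2 + model.head_bias_2
    return r, h, sigmoid(z2)


def ern_forward(model: ERNModel, entity_index: int) -> np.ndarray:
    """Probability vector over all columns for one entity (row lookup, Eqs. as-printed head)."""
    if not 0 <= entity_index < model.n_entities:
        raise IndexError(
            f"entity index {entity_index} out of range [0, {model.n_entities})"
        )
    v = model.embedding_weights[entity_index]
    z1 = relu(v) @ model.head_weights_1
    if model.head_bias_1 is not None:
        z1 = z1 + model.head_bias_1
    z2 = sigmoid(z1) @ model.head_weights_2
    if model.head_bias_2 is not None:
        z2 = z2 + model.head_bias_2
    return sigmoid(z2)


def ern_loss(predictions: np.ndarray, adjacency: AdjacencyMatrix | np.ndarray) -> float:
    """Total squared reconstruction error (sum over all entries).

    The optimizer minimizes the mean per entry -- the same objective up to a
    constant factor -- so that the learning rate does not depend on matrix
    size; this function reports the plain sum.
    """
    target = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
    predictions = np.asarray(predictions)
    if predictions.shape != target.shape:
        raise ValueError(f"shape mismatch: {predictions.shape} vs {target.shape}")
    return float(np.sum((predictions - target.astype(float)) ** 2))


def train_ern(
    adjacency: AdjacencyMatrix | np.ndarray, config: ERNConfig
) -> tuple[ERNModel, np.ndarray]:
    """Full-batch training of the reconstruction objective.

    Returns the trained model and the per-epoch trace of mean squared error
    per entry.  Runs for ``config.epochs`` epochs or until the trace falls
    below ``config.stop_loss``, whichever comes first.
    """
    target = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
    if target.size == 0:
        raise ValueError("adjacency is empty")
    a = target.astype(float)
    n, j = a.shape
    model = init_ern(config, n, j)
    opt = Adam(model._params(), lr=config.learning_rate)
    trace: list[float] = []
    inv = 1.0 / (n * j)
    for _ in range(config.epochs):
        r, h, p = _forward_all(model)
        loss = float(np.mean((p - a) ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite reconstruction loss at epoch {len(trace)}")
        trace.append(loss)
        if loss < config.stop_loss:
            break
        dz2 = 2.0 * inv * (p - a) * p * (1.0 - p)
        g_w2 = h.T @ dz2
        dz1 = (dz2 @ model.head_weights_2.T) * h * (1.0 - h)
        g_w1 = r.T @ dz1
        g_emb = (dz1 @ model.head_weights_1.T) * (model.embedding_weights > 0)
        grads = [g_emb, g_w1, g_w2]
        if config.use_bias:
            grads += [dz1.sum(axis=0), dz2.sum(axis=0)]
        opt.step(grads)
    return model, np.asarray(trace)


def get_embeddings(model: ERNModel, vocab: EntityVocabulary) -> EmbeddingMatrix:
    """Embedding of entity i is row i of the projection matrix (one-hot selection)."""
    if len(vocab) != model.n_entities:
        raise ValueError(
            f"vocabulary size {len(vocab)} != model entity count {model.n_entities}"
        )
    return EmbeddingMatrix(row_vocab=vocab, vectors=model.embedding_weights.copy())


@dataclass
class GeneralEmbedder:
    """Fitted inverse map F_m: association profile -> embedding vector.

    Lets out-of-vocabulary entities be embedded from their association
    profiles alone, without retraining the projection matrix.
    """

    w1: np.ndarray  # (n_columns, hidden_dim)
    b1: np.ndarray
    w2: np.ndarray  # (hidden_dim, embedding_dim)
    b2: np.ndarray
    fit_mse: float = float("nan")
    fit_max_error: float = float("nan")

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def output_dim(self) -> int:
        return self.w2.shape[1]


def embed_profile(embedder: GeneralEmbedder, profile: np.ndarray) -> np.ndarray:
    """Embed a (possibly unseen) entity directly from its binary association profile."""
    profile = np.asarray(profile, dtype=float)
    squeeze = profile.ndim == 1
    profile = np.atleast_2d(profile)
    if profile.shape[1] != embedder.input_dim:
        raise ValueError(
            f"profile length {profile.shape[1]} != embedder input length {embedder.input_dim}"
        )
    out = relu(profile @ embedder.w1 + embedder.b1) @ embedder.w2 + embedder.b2
    return out[0] if squeeze else out


def fit_general_embedder(
    model: ERNModel,
    adjacency: AdjacencyMatrix | np.ndarray,
    config: ERNConfig | None = None,
    *,
    target_mse: float = 1e-5,
) -> GeneralEmbedder:
    """Fit F_m on (profile, embedding) pairs from the trained model.

    One hidden rectifier layer of ``hidden_dim`` units, linear output,
    squared-error objective; runs until the mean squared fit error drops
    below ``target_mse`` or the epoch budget is exhausted.
    """
    config = config or model.config
    x = (adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)).astype(float)
    y = model.embedding_weights
    if x.shape[0] != y.shape[0]:
        raise ValueError("adjacency row count must match model entity count")
    n = x.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    emb = GeneralEmbedder(
        w1=uniform_fan_in(rng, x.shape[1], config.hidden_dim),
        b1=np.zeros(config.hidden_dim),
        w2=uniform_fan_in(rng, config.hidden_dim, y.shape[1]),
        b2=np.zeros(y.shape[1]),
    )
    opt = Adam([emb.w1, emb.b1, emb.w2, emb.b2], lr=config.learning_rate * 10)
    inv = 1.0 / y.size
    for _ in range(config.epochs):
        z1 = x @ emb.w1 + emb.b1
        h = relu(z1)
        pred = h @ emb.w2 + emb.b2
        err = pred - y
        mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise DivergenceError("non-finite fit error in general-embedder training")
        if mse < target_mse:
            break
        d = 2.0 * inv * err
        g_w2 = h.T @ d
        g_b2 = d.sum(axis=0)
        dh = (d @ emb.w2.T) * (z1 > 0)
        g_w1 = x.T @ dh
        g_b1 = dh.sum(axis=0)
        opt.step([g_w1, g_b1, g_w2, g_b2])
    pred = embed_profile(emb, x)
    emb.fit_mse = float(np.mean((pred - y) ** 2))
    emb.fit_max_error = float(np.max(np.abs(pred - y))) if n else float("nan")
    return emb


def save_ern(model: ERNModel, vocab: EntityVocabulary, column_names: tuple[str, ...], path: str | Path) -> None:
    """Checkpoint archive: weights, config, row and column names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    np.savez_compressed(
        path,
        embedding_weights=model.embedding_weights,
        head_weights_1=model.head_weights_1,
        head_weights_2=model.head_weights_2,
        head_bias_1=model.head_bias_1 if model.head_bias_1 is not None else np.zeros(0),
        head_bias_2=model.head_bias_2 if model.head_bias_2 is not None else np.zeros(0),
        config=np.asarray(
            [cfg.embedding_dim, cfg.hidden_dim, cfg.epochs, cfg.learning_rate,
             cfg.seed, int(cfg.use_bias), cfg.stop_loss]
        ),
        row_role=np.asarray(vocab.role),
        row_names=np.asarray(vocab.names, dtype=object),
        column_names=np.asarray(column_names, dtype=object),
    )


def load_ern(path: str | Path) -> tuple[ERNModel, EntityVocabulary, tuple[str, ...]]:
    with np.load(path, allow_pickle=True) as npz:
        c = npz["config"]
        cfg = ERNConfig(
            embedding_dim=int(c[0]), hidden_dim=int(c[1]), epochs=int(c[2]),
            learning_rate=float(c[3]), seed=int(c[4]), use_bias=bool(int(c[5])),
            stop_loss=float(c[6]),
        )
        model = ERNModel(
            embedding_weights=npz["embedding_weights"],
            head_weights_1=npz["head_weights_1"],
            head_weights_2=npz["head_weights_2"],
            config=cfg,
            head_bias_1=npz["head_bias_1"] if npz["head_bias_1"].size else None,
            head_bias_2=npz["head_bias_2"] if npz["head_bias_2"].size else None,
        )
        vocab = EntityVocabulary(role=str(npz["row_role"]), names=tuple(npz["row_names"]))
        return model, vocab, tuple(npz["column_names"])


def write_embeddings_tsv(embeddings: EmbeddingMatrix, path: str | Path) -> None:
    """Delimited-text export: entity name followed by its coordinates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for name, vec in zip(embeddings.row_vocab.names, embeddings.vectors):
            coords = "\t".join(format(x, ".10g") for x in vec)
            fh.write(f"{name}\t{coords}\n")
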