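"""Pseudo-siamese pair classifier over disease and circRNA embeddings.

The two inputs live in different semantic spaces (a disease embedding trained
on gene/miRNA/lncRNA/drug links, a circRNA embedding trained on disease/miRNA
links), so the two branches share the architecture but **not** the weights:

    u = Extractor_disease(v_disease),   v = Extractor_circ(v_circ)
    P = sigmoid( head([u; v; u - v; u ⊙ v]) )

The fusion vector augments the raw features with their difference and
element-wise product so the head can read local agreement between the two
branches directly.  Training is binary cross-entropy on labeled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._optim import Adam, DivergenceError, relu, sigmoid, uniform_fan_in
from .ern import EmbeddingMatrix

__all__ = [
    "PSNConfig",
    "PSNModel",
    "fuse",
    "init_psn",
    "psn_forward",
    "train_psn",
    "predict_pairs",
]


@dataclass(frozen=True)
class PSNConfig:
    feature_dim: int = 64
    extractor_hidden_dim: int = 64
    head_hidden_dim: int = 64
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    threshold: float = 0.5
    validation_fraction: float = 0.1
    patience: int = 20

    def __post_init__(self) -> None:
        if min(self.feature_dim, self.extractor_hidden_dim, self.head_hidden_dim,
               self.batch_size, self.epochs) < 1:
            raise ValueError("all dimensions, batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class PSNModel:
    """Two independent feature extractors plus a fusion head ending in a logistic unit."""

    extractor_disease: dict[str, np.ndarray]
    extractor_circ: dict[str, np.ndarray]
    fusion_head: dict[str, np.ndarray]
    config: PSNConfig

    def _params(self) -> list[np.ndarray]:
        return (
            [self.extractor_disease[k] for k in ("w1", "b1", "w2", "b2")]
            + [self.extractor_circ[k] for k in ("w1", "b1", "w2", "b2")]
            + [self.fusion_head[k] for k in ("w1", "b1", "w2", "b2")]
        )


def fuse(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Fusion vector [u; v; u−v; u⊙v]; works on single vectors or batches."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"feature shapes differ: {u.shape} vs {v.shape}")
    return np.concatenate([u, v, u - v, u * v], axis=-1)


def _make_layer_pair(rng, d_in: int, d_hidden: int, d_out: int) -> dict[str, np.ndarray]:
    return {
        "w1": uniform_fan_in(rng, d_in, d_hidden),
        "b1": np.zeros(d_hidden),
        "w2": uniform_fan_in(rng, d_hidden, d_out),
        "b2": np.zeros(d_out),
    }


def init_psn(config: PSNConfig, disease_dim: int, circ_dim: int) -> PSNModel:
    """Seeded init; the two extractors draw independent weights (no sharing)."""
    if disease_dim < 1 or circ_dim < 1:
        raise ValueError("embedding dimensions must be >= 1")
    rng = np.random.default_rng(config.seed)
    return PSNModel(
        extractor_disease=_make_layer_pair(rng, disease_dim, config.extractor_hidden_dim, config.feature_dim),
        extractor_circ=_make_layer_pair(rng, circ_dim, config.extractor_hidden_dim, config.feature_dim),
        fusion_head=_make_layer_pair(rng, 4 * config.feature_dim, config.head_hidden_dim, 1),
        config=config,
    )


def _extract(layers: dict[str, np.ndarray], x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z1 = x @ layers["w1"] + layers["b1"]
    h = relu(z1)
    return z1, h, h @ layers["w2"] + layers["b2"]


def _forward_batch(model: PSNModel, xd: np.ndarray, xc: np.ndarray) -> np.ndarray:
    _, _, u = _extract(model.extractor_disease, xd)
    _, _, v = _extract(model.extractor_circ, xc)
    fz = fuse(u, v)
    _, h, z = _extract(model.fusion_head, fz)
    return sigmoid(z[:, 0])


def psn_forward(model: PSNModel, disease_embedding: np.ndarray, circ_embedding: np.ndarray) -> float:
    """Association probability for a single (disease, circRNA) embedding pair."""
    xd = np.atleast_2d(np.asarray(disease_embedding, dtype=float))
    xc = np.atleast_2d(np.asarray(circ_embedding, dtype=float))
    if xd.shape[1] != model.extractor_disease["w1"].shape[0]:
        raise ValueError(
            f"disease embedding length {xd.shape[1]} != extractor input "
            f"{model.extractor_disease['w1'].shape[0]}"
        )
    if xc.shape[1] != model.extractor_circ["w1"].shape[0]:
        raise ValueError(
            f"circRNA embedding length {xc.shape[1]} != extractor input "
            f"{model.extractor_circ['w1'].shape[0]}"
        )
    return float(_forward_batch(model, xd, xc)[0])


def _lookup(
    disease_embeddings: EmbeddingMatrix,
    circ_embeddings: EmbeddingMatrix,
    pairs: Sequence[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs are (circRNA name, disease name); returns (X_disease, X_circ)."""
    ci = [circ_embeddings.row_vocab.index_of(c) for c, _ in pairs]
    di = [disease_embeddings.row_vocab.index_of(d) for _, d in pairs]
    return disease_embeddings.vectors[di], circ_embeddings.vectors[ci]


def train_psn(
    model: PSNModel,
    disease_embeddings: EmbeddingMatrix,
    circ_embeddings: EmbeddingMatrix,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
    config: PSNConfig | None = None,
) -> tuple[PSNModel, np.ndarray]:
    """Mini-batch cross-entropy training; deterministic under the config seed.

    ``pairs`` are (circRNA name, disease name); ``labels`` in {0, 1}.
    Returns the trained model (modified in place) and the per-epoch mean
    training loss.

    When ``validation_fraction`` is positive and the pair set is large enough
    for a stratified split, that fraction is held out and training stops once
    the validation cross-entropy has not improved for ``patience`` epochs; the
    best-validation weights are restored.  The pair labels include presumed
    negatives (and, on noisy data, mislabeled pairs), so training to full
    convergence memorizes label noise that early stopping avoids.
    """
    config = config or model.config
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    y = np.asarray(labels, dtype=float)
    if len(pairs) != y.size:
        raise ValueError("pairs and labels length mismatch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    xd_all, xc_all = _lookup(disease_embeddings, circ_embeddings, pairs)
    f = config.feature_dim
    rng = np.random.default_rng(config.seed + 1)

    # stratified validation split for early stopping
    n_total = y.size
    n_val = int(round(config.validation_fraction * n_total))
    val_idx = np.zeros(0, dtype=int)
    if n_val >= 2:
        pos = rng.permutation(np.flatnonzero(y == 1.0))
        neg = rng.permutation(np.flatnonzero(y == 0.0))
        n_val_pos = int(round(n_val * pos.size / n_total))
        n_val_neg = n_val - n_val_pos
        if 0 < n_val_pos < pos.size and 0 < n_val_neg < neg.size:
            val_idx = np.concatenate([pos[:n_val_pos], neg[:n_val_neg]])
    train_idx = np.setdiff1d(np.arange(n_total), val_idx)
    xd_val, xc_val, y_val = xd_all[val_idx], xc_all[val_idx], y[val_idx]
    xd_all, xc_all, y = xd_all[train_idx], xc_all[train_idx], y[train_idx]
    n = y.size

    opt = Adam(model._params(), lr=config.learning_rate)
    trace: list[float] = []
    eps = 1e-12
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    stale = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xd, xc, yb = xd_all[idx], xc_all[idx], y[idx]
            b = idx.size
            zd1, hd, u = _extract(model.extractor_disease, xd)
            zc1, hc, v = _extract(model.extractor_circ, xc)
            fz = fuse(u, v)
            zh1, hh, zout = _extract(model.fusion_head, fz)
            p = sigmoid(zout[:, 0])
            loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
            if not np.isfinite(loss):
                raise DivergenceError("non-finite classifier loss")
            epoch_loss += loss * b
            # logistic + cross-entropy: d(loss)/d(zout) = (p - y)/B
            dz = ((p - yb) / b)[:, None]
            g_hw2 = hh.T @ dz
            g_hb2 = dz.sum(axis=0)
            dhh = (dz @ model.fusion_head["w2"].T) * (zh1 > 0)
            g_hw1 = fz.T @ dhh
            g_hb1 = dhh.sum(axis=0)
            dfz = dhh @ model.fusion_head["w1"].T
            du = dfz[:, :f] + dfz[:, 2 * f : 3 * f] + dfz[:, 3 * f :] * v
            dv = dfz[:, f : 2 * f] - dfz[:, 2 * f : 3 * f] + dfz[:, 3 * f :] * u
            g_dw2 = hd.T @ du
            g_db2 = du.sum(axis=0)
            dhd = (du @ model.extractor_disease["w2"].T) * (zd1 > 0)
            g_dw1 = xd.T @ dhd
            g_db1 = dhd.sum(axis=0)
            g_cw2 = hc.T @ dv
            g_cb2 = dv.sum(axis=0)
            dhc = (dv @ model.extractor_circ["w2"].T) * (zc1 > 0)
            g_cw1 = xc.T @ dhc
            g_cb1 = dhc.sum(axis=0)
            opt.step([
                g_dw1, g_db1, g_dw2, g_db2,
                g_cw1, g_cb1, g_cw2, g_cb2,
                g_hw1, g_hb1, g_hw2, g_hb2,
            ])
        trace.append(epoch_loss / n)
        if val_idx.size:
            p_val = _forward_batch(model, xd_val, xc_val)
            val_loss = -np.mean(
                y_val * np.log(p_val + eps) + (1 - y_val) * np.log(1 - p_val + eps)
            )
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = [p.copy() for p in model._params()]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_params is not None:
        for p, best in zip(model._params(), best_params):
            p[...] = best
    return model, np.asarray(trace)


def predict_pairs(
    model: PSNModel,
    disease_embeddings: EmbeddingMatrix,
    circ_embeddings: EmbeddingMatrix,
    pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Association probability per (circRNA, disease) pair, order-preserving.

    Duplicate pairs are scored once and share bitwise-identical output.
    """
    if len(pairs) == 0:
        return np.zeros(0)
    unique: dict[tuple[str, str], int] = {}
    for pair in pairs:
        unique.setdefault(tuple(pair), len(unique))
    xd, xc = _lookup(disease_embeddings, circ_embeddings, list(unique))
    probs = _forward_batch(model, xd, xc)
    return probs[[unique[tuple(pair)] for pair in pairs]]


def save_psn(model: PSNModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    arrays = {}
    for branch, layers in (
        ("disease", model.extractor_disease),
        ("circ", model.extractor_circ),
        ("head", model.fusion_head),
    ):
        for key, arr in layers.items():
            arrays[f"{branch}_{key}"] = arr
    arrays["config"] = np.asarray([
        cfg.feature_dim, cfg.extractor_hidden_dim, cfg.head_hidden_dim,
        cfg.learning_rate, cfg.epochs, cfg.batch_size, cfg.seed, cfg.threshold,
    ])
    np.savez_compressed(path, **arrays)


def load_psn(path: str | Path) -> PSNModel:
    with np.load(path) as npz:
        c = npz["config"]
        cfg = PSNConfig(
            feature_dim=int(c[0]), extractor_hidden_dim=int(c[1]),
            head_hidden_dim=int(c[2]), learning_rate=float(c[3]),
            epochs=int(c[4]), batch_size=int(c[5]), seed=int(c[6]),
            threshold=float(c[7]),
        )
        def branch(name: str) -> dict[str, np.ndarray]:
            return {k: npz[f"{name}_{k}"] for k in ("w1", "b1", "w2", "b2")}
        return PSNModel(
            extractor_disease=branch("disease"),
            extractor_circ=branch("circ"),
            fusion_head=branch("head"),
            config=cfg,
        )
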