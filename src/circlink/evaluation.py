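"""Benchmarking: negative sampling, stratified k-fold CV, metrics, ranking.

Observed circRNA-disease associations are the positives; the same number of
unobserved pairs is drawn uniformly from the complement of the grid as
presumed negatives.  Stratified k-fold cross-validation trains the embedding
networks and the pair classifier on k-1 folds and scores the held-out fold;
accuracy, sensitivity, precision, F1 and AUC are reported per fold and as
mean ± sample standard deviation.

Because the circRNA adjacency fuses the circRNA-disease links themselves,
naively training embeddings on the full adjacency would let the test labels
leak into the features.  A leakage guard (default on) masks the held-out
positive links from the adjacency used for embedding training in each fold;
``leakage_guard=False`` reproduces the naive protocol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .data import (
    AdjacencyMatrix,
    AssociationTable,
    EntityVocabulary,
    build_adjacency,
    build_vocabulary,
    merge_vocabularies,
)
from .ern import (
    EmbeddingMatrix,
    ERNConfig,
    GeneralEmbedder,
    embed_profile,
    fit_general_embedder,
    get_embeddings,
    train_ern,
)
from .psn import PSNConfig, PSNModel, init_psn, predict_pairs, train_psn

logger = logging.getLogger(__name__)

# canonical relation keys used across the pipeline
REL_CIRC_DISEASE = "circRNA-disease"
REL_CIRC_MIRNA = "circRNA-miRNA"
REL_DISEASE_GENE = "disease-gene"
REL_DISEASE_MIRNA = "disease-miRNA"
REL_DISEASE_LNCRNA = "disease-lncRNA"
REL_DISEASE_DRUG = "disease-drug"
DISEASE_RELATIONS = (REL_DISEASE_GENE, REL_DISEASE_MIRNA, REL_DISEASE_LNCRNA, REL_DISEASE_DRUG)
METRIC_NAMES = ("accuracy", "sensitivity", "precision", "f1", "auc")


class CapacityError(ValueError):
    """Requested more negatives than the complement of the positive set holds."""


@dataclass(frozen=True)
class LabeledPairSet:
    """Balanced labeled (circRNA, disease) pairs with sampling provenance."""

    pairs: tuple[tuple[str, str], ...]
    labels: tuple[int, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must have equal length")
        seen: dict[tuple[str, str], int] = {}
        for pair, label in zip(self.pairs, self.labels):
            if label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {label!r}")
            if pair in seen:
                raise ValueError(
                    f"pair {pair!r} appears more than once"
                    + ("" if seen[pair] == label else " with both labels")
                )
            seen[pair] = label

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels_array(self) -> np.ndarray:
        return np.asarray(self.labels)


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: tuple[int, ...]
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) != fold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics plus AUC; degenerate denominators give NaN, listed in ``degenerate``."""

    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    auc: float
    counts: ConfusionCounts
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class SummaryRow:
    """Per-fold metric values with mean and sample (n-1) standard deviation."""

    per_fold: dict[str, tuple[float, ...]]
    mean: dict[str, float]
    sd: dict[str, float]


def sample_negatives(
    positives: Sequence[tuple[str, str]],
    circ_vocab: EntityVocabulary,
    disease_vocab: EntityVocabulary,
    n: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Draw n distinct unobserved pairs uniformly from the complement grid.

    The complement is the circRNA x disease grid minus the positive set;
    sampling is without replacement and reproducible under the seed.
    """
    n_c, n_d = len(circ_vocab), len(disease_vocab)
    pos_ids = {
        circ_vocab.index_of(c) * n_d + disease_vocab.index_of(d) for c, d in positives
    }
    capacity = n_c * n_d - len(pos_ids)
    if n > capacity:
        raise CapacityError(
            f"requested {n} negatives but the complement holds only {capacity} pairs"
        )
    rng = np.random.default_rng(seed)
    total = n_c * n_d
    if total <= 5_000_000:
        complement = np.setdiff1d(
            np.arange(total), np.fromiter(pos_ids, dtype=np.int64, count=len(pos_ids))
        )
        chosen = rng.choice(complement, size=n, replace=False)
    else:
        # huge grid: rejection sampling against the (sparse) positive set
        chosen_set: set[int] = set()
        while len(chosen_set) < n:
            draw = rng.integers(0, total, size=2 * (n - len(chosen_set)))
            for flat in draw:
                flat = int(flat)
                if flat not in pos_ids and flat not in chosen_set:
                    chosen_set.add(flat)
                    if len(chosen_set) == n:
                        break
        chosen = np.fromiter(chosen_set, dtype=np.int64, count=n)
        chosen.sort()
    return [
        (circ_vocab.names[flat // n_d], disease_vocab.names[flat % n_d])
        for flat in np.asarray(chosen, dtype=np.int64)
    ]


def make_folds(pair_set: LabeledPairSet, k: int, seed: int) -> FoldAssignment:
    """Stratified partition into k folds: class counts balanced within ±1 per fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pair_set) < k:
        raise ValueError(f"cannot split {len(pair_set)} pairs into {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(pair_set), dtype=int)
    y = pair_set.labels_array
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(pair_set)), y)):
        fold_of[test_idx] = fold
    return FoldAssignment(k=k, fold_of=tuple(int(f) for f in fold_of), seed=seed)


def confusion_at_threshold(
    probs: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Tally confusion counts; a probability equal to the threshold calls positive."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probs and labels length mismatch")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def compute_metrics(counts: ConfusionCounts, auc: float = float("nan")) -> MetricsReport:
    """Accuracy, sensitivity, precision, F1 from confusion counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN).
    Degenerate denominators yield NaN and are flagged rather than coerced to 0.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    degenerate: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return float("nan")
        return num / den

    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    report = MetricsReport(
        accuracy=(tp + tn) / counts.total,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        precision=ratio(tp, tp + fp, "precision"),
        f1=ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        auc=auc,
        counts=counts,
        degenerate=tuple(degenerate),
    )
    return report


def compute_auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the midrank (tie-safe) statistic.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, ties counted one half; identical to the
    trapezoidal area under the ROC curve.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    n1 = int(np.sum(y == 1))
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(p)  # average (mid) ranks
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(probs: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold)."""
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(probs, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def compute_auc_trapezoid(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal area under the ROC curve; must agree with compute_auc."""
    pts = roc_points(probs, labels)
    return float(np.trapezoid(pts["tpr"], pts["fpr"]))


def summarize_table(per_fold: Mapping[str, Sequence[float]]) -> SummaryRow:
    """Mean and sample (n-1) SD per metric; NaN sentinels are excluded."""
    per = {name: tuple(float(v) for v in values) for name, values in per_fold.items()}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name, values in per.items():
        arr = np.asarray(values, dtype=float)
        valid = arr[np.isfinite(arr)]
        if valid.size < 2:
            raise ValueError(f"{name}: need >= 2 finite values for mean/SD, got {valid.size}")
        mean[name] = float(valid.mean())
        sd[name] = float(valid.std(ddof=1))
    return SummaryRow(per_fold=per, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# pipeline assembly


def _mask_pairs(
    table: AssociationTable, masked: set[tuple[str, str]]
) -> AssociationTable:
    if not masked:
        return table
    kept = tuple(p for p in table.pairs if p not in masked)
    return AssociationTable(relation=table.relation, pairs=kept)


def build_entity_vocabularies(
    tables: Mapping[str, AssociationTable]
) -> tuple[EntityVocabulary, EntityVocabulary]:
    """(circRNA vocab, disease vocab) drawn from every table that mentions them."""
    if REL_CIRC_DISEASE not in tables:
        raise ValueError(f"the {REL_CIRC_DISEASE!r} table is required")
    circ_tables = [tables[REL_CIRC_DISEASE]]
    if REL_CIRC_MIRNA in tables:
        circ_tables.append(tables[REL_CIRC_MIRNA])
    circ_vocab = build_vocabulary(circ_tables, side="left", role="circRNA")
    disease_vocabs = [
        build_vocabulary([tables[REL_CIRC_DISEASE]], side="right", role="disease")
    ]
    for rel in DISEASE_RELATIONS:
        if rel in tables:
            disease_vocabs.append(build_vocabulary([tables[rel]], side="left", role="disease"))
    disease_vocab = merge_vocabularies("disease", *disease_vocabs)
    return circ_vocab, disease_vocab


def build_fused_adjacencies(
    tables: Mapping[str, AssociationTable],
    circ_vocab: EntityVocabulary,
    disease_vocab: EntityVocabulary,
    masked_positives: set[tuple[str, str]],
) -> tuple[AdjacencyMatrix, AdjacencyMatrix]:
    """Circ and disease adjacencies for one fold, with held-out links masked.

    The circRNA adjacency fuses the (masked) circRNA-disease block with the
    circRNA-miRNA block.  The disease adjacency fuses whatever disease-side
    relations are available; when none are, it falls back to the transposed
    (masked) circRNA-disease table so diseases still have a profile.
    """
    cd = _mask_pairs(tables[REL_CIRC_DISEASE], masked_positives)
    circ_tables = [cd]
    circ_col_vocabs = [disease_vocab]
    if REL_CIRC_MIRNA in tables:
        circ_tables.append(tables[REL_CIRC_MIRNA])
        circ_col_vocabs.append(
            build_vocabulary([tables[REL_CIRC_MIRNA]], side="right", role="miRNA")
        )
    circ_adj = build_adjacency(circ_vocab, circ_tables, circ_col_vocabs)

    disease_tables = [tables[rel] for rel in DISEASE_RELATIONS if rel in tables]
    if disease_tables:
        disease_col_vocabs = [
            build_vocabulary([t], side="right", role=t.relation.split("-", 1)[1])
            for t in disease_tables
        ]
    else:
        flipped = AssociationTable(
            relation="disease-circRNA", pairs=tuple((d, c) for c, d in cd.pairs)
        )
        disease_tables = [flipped]
        disease_col_vocabs = [circ_vocab]
    disease_adj = build_adjacency(disease_vocab, disease_tables, disease_col_vocabs)
    return circ_adj, disease_adj


@dataclass
class TrainedPipeline:
    """Everything needed to score new (circRNA, disease) pairs."""

    circ_adj: AdjacencyMatrix
    disease_adj: AdjacencyMatrix
    circ_embeddings: EmbeddingMatrix
    disease_embeddings: EmbeddingMatrix
    psn_model: PSNModel
    circ_embedder: GeneralEmbedder
    disease_embedder: GeneralEmbedder
    pair_set: LabeledPairSet


def _train_fold_models(
    tables: Mapping[str, AssociationTable],
    circ_vocab: EntityVocabulary,
    disease_vocab: EntityVocabulary,
    train_pairs: Sequence[tuple[str, str]],
    train_labels: Sequence[int],
    masked_positives: set[tuple[str, str]],
    ern_config: ERNConfig,
    psn_config: PSNConfig,
    n_classifiers: int = 1,
) -> tuple[AdjacencyMatrix, AdjacencyMatrix, EmbeddingMatrix, EmbeddingMatrix, list[PSNModel]]:
    circ_adj, disease_adj = build_fused_adjacencies(
        tables, circ_vocab, disease_vocab, masked_positives
    )
    circ_model, _ = train_ern(circ_adj, ern_config)
    disease_model, _ = train_ern(disease_adj, replace(ern_config, seed=ern_config.seed + 1))
    circ_emb = get_embeddings(circ_model, circ_vocab)
    disease_emb = get_embeddings(disease_model, disease_vocab)
    models: list[PSNModel] = []
    for member in range(n_classifiers):
        member_config = replace(psn_config, seed=psn_config.seed + 13 * member)
        psn_model = init_psn(member_config, disease_emb.dim, circ_emb.dim)
        train_psn(psn_model, disease_emb, circ_emb, train_pairs, train_labels, member_config)
        models.append(psn_model)
    return circ_adj, disease_adj, circ_emb, disease_emb, models


@dataclass
class CVResult:
    per_fold: list[MetricsReport]
    summary: SummaryRow
    roc: list[pd.DataFrame]
    folds: FoldAssignment
    pair_set: LabeledPairSet
    probabilities: np.ndarray  # held-out probability for every labeled pair


def cross_validate(
    tables: Mapping[str, AssociationTable],
    ern_config: ERNConfig | None = None,
    psn_config: PSNConfig | None = None,
    k: int = 5,
    seed: int = 0,
    *,
    pair_set: LabeledPairSet | None = None,
    leakage_guard: bool = True,
    threshold: float = 0.5,
    n_classifiers: int = 5,
) -> CVResult:
    """Stratified k-fold evaluation of the full embedding + classifier pipeline.

    Negatives are sampled once on the full pair set before folding (pass a
    prebuilt ``pair_set`` to control this).  With ``leakage_guard`` on, each
    fold's held-out positive links are masked out of the adjacency used to
    train embeddings for that fold.  Per fold, ``n_classifiers``
    independently initialized classifiers are trained and their predicted
    probabilities averaged; the small ensemble damps initialization variance
    at negligible cost next to embedding training.
    """
    ern_config = ern_config or ERNConfig(seed=seed)
    psn_config = psn_config or PSNConfig(seed=seed)
    circ_vocab, disease_vocab = build_entity_vocabularies(tables)
    if pair_set is None:
        positives = list(tables[REL_CIRC_DISEASE].pairs)
        negatives = sample_negatives(
            positives, circ_vocab, disease_vocab, len(positives), seed
        )
        pair_set = LabeledPairSet(
            pairs=tuple(positives) + tuple(negatives),
            labels=(1,) * len(positives) + (0,) * len(negatives),
            provenance={"positive_source": REL_CIRC_DISEASE, "negative_seed": seed},
        )
    folds = make_folds(pair_set, k, seed + 1)
    labels = pair_set.labels_array
    per_fold: list[MetricsReport] = []
    roc: list[pd.DataFrame] = []
    probabilities = np.full(len(pair_set), np.nan)
    for fold in range(k):
        test_idx = folds.test_indices(fold)
        train_idx = folds.train_indices(fold)
        train_pairs = [pair_set.pairs[i] for i in train_idx]
        test_pairs = [pair_set.pairs[i] for i in test_idx]
        masked = (
            {pair_set.pairs[i] for i in test_idx if labels[i] == 1}
            if leakage_guard
            else set()
        )
        fold_ern = replace(ern_config, seed=ern_config.seed + 101 * fold)
        fold_psn = replace(psn_config, seed=psn_config.seed + 101 * fold)
        _, _, circ_emb, disease_emb, psn_models = _train_fold_models(
            tables, circ_vocab, disease_vocab,
            train_pairs, labels[train_idx], masked, fold_ern, fold_psn,
            n_classifiers=n_classifiers,
        )
        probs = np.mean(
            [predict_pairs(m, disease_emb, circ_emb, test_pairs) for m in psn_models],
            axis=0,
        )
        probabilities[test_idx] = probs
        counts = confusion_at_threshold(probs, labels[test_idx], threshold)
        report = compute_metrics(counts, auc=compute_auc(probs, labels[test_idx]))
        per_fold.append(report)
        roc.append(roc_points(probs, labels[test_idx]))
        logger.info(
            "fold %d: acc=%.4f sen=%.4f prec=%.4f f1=%.4f auc=%.4f",
            fold, report.accuracy, report.sensitivity, report.precision,
            report.f1, report.auc,
        )
    summary = summarize_table(
        {name: [r.as_dict()[name] for r in per_fold] for name in METRIC_NAMES}
    )
    return CVResult(
        per_fold=per_fold, summary=summary, roc=roc, folds=folds,
        pair_set=pair_set, probabilities=probabilities,
    )


def fit_pipeline(
    tables: Mapping[str, AssociationTable],
    ern_config: ERNConfig | None = None,
    psn_config: PSNConfig | None = None,
    seed: int = 0,
    *,
    pair_set: LabeledPairSet | None = None,
) -> TrainedPipeline:
    """Train embeddings, general embedders and the classifier on all labeled pairs."""
    ern_config = ern_config or ERNConfig(seed=seed)
    psn_config = psn_config or PSNConfig(seed=seed)
    circ_vocab, disease_vocab = build_entity_vocabularies(tables)
    if pair_set is None:
        positives = list(tables[REL_CIRC_DISEASE].pairs)
        negatives = sample_negatives(
            positives, circ_vocab, disease_vocab, len(positives), seed
        )
        pair_set = LabeledPairSet(
            pairs=tuple(positives) + tuple(negatives),
            labels=(1,) * len(positives) + (0,) * len(negatives),
            provenance={"positive_source": REL_CIRC_DISEASE, "negative_seed": seed},
        )
    circ_adj, disease_adj = build_fused_adjacencies(
        tables, circ_vocab, disease_vocab, set()
    )
    circ_model, _ = train_ern(circ_adj, ern_config)
    disease_model, _ = train_ern(disease_adj, replace(ern_config, seed=ern_config.seed + 1))
    circ_emb = get_embeddings(circ_model, circ_vocab)
    disease_emb = get_embeddings(disease_model, disease_vocab)
    psn_model = init_psn(psn_config, disease_emb.dim, circ_emb.dim)
    train_psn(
        psn_model, disease_emb, circ_emb, list(pair_set.pairs),
        pair_set.labels_array, psn_config,
    )
    return TrainedPipeline(
        circ_adj=circ_adj,
        disease_adj=disease_adj,
        circ_embeddings=circ_emb,
        disease_embeddings=disease_emb,
        psn_model=psn_model,
        circ_embedder=fit_general_embedder(circ_model, circ_adj, ern_config),
        disease_embedder=fit_general_embedder(
            disease_model, disease_adj, replace(ern_config, seed=ern_config.seed + 1)
        ),
        pair_set=pair_set,
    )


def rank_candidates(
    pipeline: TrainedPipeline,
    disease: str,
    candidates: Sequence[str] | None = None,
    *,
    known_positives: Sequence[str] | None = None,
    recall_threshold: float = 0.9,
    disease_profile: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Rank candidate circRNAs for one disease by predicted probability.

    If the disease is outside the training vocabulary, a binary association
    profile over the disease adjacency's columns must be supplied; it is
    embedded with the fitted general embedder.  Equal probabilities are
    broken lexicographically by circRNA name.  The second return value is
    recall@threshold: the fraction of known positive circRNAs scoring
    strictly above ``recall_threshold`` (NaN if none are given).
    """
    if candidates is None:
        candidates = list(pipeline.circ_embeddings.row_vocab.names)
    if disease in pipeline.disease_embeddings.row_vocab:
        d_vec = pipeline.disease_embeddings.vector_of(disease)
    elif disease_profile is not None:
        d_vec = embed_profile(pipeline.disease_embedder, disease_profile)
    else:
        raise ValueError(
            f"disease {disease!r} is outside the vocabulary and no association "
            "profile was supplied"
        )
    from .psn import psn_forward  # local alias for clarity

    probs = np.array([
        psn_forward(pipeline.psn_model, d_vec, pipeline.circ_embeddings.vector_of(c))
        for c in candidates
    ])
    table = (
        pd.DataFrame({"circRNA": list(candidates), "probability": probs})
        .sort_values(["probability", "circRNA"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if known_positives:
        scores = dict(zip(table["circRNA"], table["probability"]))
        hits = sum(1 for c in known_positives if scores.get(c, 0.0) > recall_threshold)
        recall = hits / len(known_positives)
    else:
        logger.warning("recall@%.2f undefined: no known positives supplied", recall_threshold)
        recall = float("nan")
    return table, recall


# ---------------------------------------------------------------------------
# report writers (2-decimal display CSVs + full-precision JSON sidecar)


def write_reports(result: CVResult, out_dir: str | Path) -> dict[str, Path]:
    """Fold-metric, summary and ROC CSVs plus a full-precision JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fold_rows = []
    for fold, report in enumerate(result.per_fold):
        row = {"fold": fold}
        row.update({name: round(100 * value, 2) for name, value in report.as_dict().items()})
        fold_rows.append(row)
    paths["fold_metrics"] = out_dir / "fold_metrics.csv"
    pd.DataFrame(fold_rows).to_csv(paths["fold_metrics"], index=False)

    summary_rows = [
        {
            "metric": name,
            "mean": round(100 * result.summary.mean[name], 2),
            "sd": round(100 * result.summary.sd[name], 2),
        }
        for name in METRIC_NAMES
    ]
    paths["summary"] = out_dir / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(paths["summary"], index=False)

    roc_frames = []
    for fold, pts in enumerate(result.roc):
        frame = pts.copy()
        frame.insert(0, "fold", fold)
        roc_frames.append(frame)
    paths["roc"] = out_dir / "roc_points.csv"
    pd.concat(roc_frames, ignore_index=True).to_csv(paths["roc"], index=False)

    paths["sidecar"] = out_dir / "metrics_full.json"
    sidecar = {
        "per_fold": [
            {**r.as_dict(), "counts": vars(r.counts), "degenerate": list(r.degenerate)}
            for r in result.per_fold
        ],
        "summary": {"mean": result.summary.mean, "sd": result.summary.sd},
        "folds": {"k": result.folds.k, "seed": result.folds.seed},
        "provenance": result.pair_set.provenance,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, allow_nan=True))
    return paths


def write_ranked_csv(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out["probability"] = out["probability"].round(4)
    out.to_csv(path, index=False)
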