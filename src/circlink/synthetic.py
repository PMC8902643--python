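"""Planted-partition generator for heterogeneous association networks.

Every entity (circRNA, disease, miRNA, gene, lncRNA, drug) is assigned one of
K latent groups; each candidate pair across each relation type is linked
independently with probability ``p_in`` when the two entities share a group
and ``p_out`` otherwise.  Entities in the same group therefore share
association profiles across *all* relation types — exactly the multi-source
signal the embedding network is supposed to pick up — and the ground-truth
group labels make recovery measurable: a classifier scoring (circRNA,
disease) pairs should separate same-group from cross-group pairs, with the
task getting harder as ``p_in − p_out`` shrinks and becoming impossible at
``p_in == p_out``.

Group labels are assigned by shuffling a balanced label vector (each group
receives ``n // K`` or ``n // K + 1`` members), so no group is ever empty and
the deterministic ``p_in=1, p_out=0`` fixture always contains entities with
duplicate profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .data import AssociationTable, EntityVocabulary, write_association_table
from .evaluation import (
    DISEASE_RELATIONS,
    REL_CIRC_DISEASE,
    REL_CIRC_MIRNA,
    LabeledPairSet,
    sample_negatives,
)

__all__ = ["PlantedBlockConfig", "PlantedData", "generate_planted", "make_benchmark"]

AUX_ROLES = ("miRNA", "gene", "lncRNA", "drug")
DEFAULT_AUX_SIZES = {"miRNA": 60, "gene": 60, "lncRNA": 30, "drug": 30}


@dataclass(frozen=True)
class PlantedBlockConfig:
    """Defaults define the standard benchmark condition used throughout the tests."""

    n_circ: int = 40
    n_disease: int = 20
    aux_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_AUX_SIZES))
    n_groups: int = 4
    p_in: float = 0.9
    p_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        counts = [self.n_circ, self.n_disease, *self.aux_sizes.values()]
        if any(c < self.n_groups for c in counts):
            raise ValueError("every entity count must be >= n_groups")
        if set(self.aux_sizes) != set(AUX_ROLES):
            raise ValueError(f"aux_sizes must have exactly the keys {AUX_ROLES}")


@dataclass(frozen=True)
class PlantedData:
    tables: dict[str, AssociationTable]
    groups: dict[str, int]  # entity name -> planted group
    config: PlantedBlockConfig


def _balanced_groups(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(1, n + 1)]


def _sample_relation(
    rng: np.random.Generator,
    left_names: list[str],
    left_groups: np.ndarray,
    right_names: list[str],
    right_groups: np.ndarray,
    p_in: float,
    p_out: float,
    relation: str,
) -> AssociationTable:
    same = left_groups[:, None] == right_groups[None, :]
    p = np.where(same, p_in, p_out)
    linked = rng.random(p.shape) < p
    rows, cols = np.nonzero(linked)
    pairs = tuple((left_names[i], right_names[j]) for i, j in zip(rows, cols))
    return AssociationTable(relation=relation, pairs=pairs)


def generate_planted(config: PlantedBlockConfig) -> PlantedData:
    """Draw the six relation tables plus ground-truth group assignments."""
    rng = np.random.default_rng(config.seed)
    circ = _names("circ", config.n_circ)
    disease = _names("dis", config.n_disease)
    aux = {role: _names(role.lower(), n) for role, n in config.aux_sizes.items()}

    g_circ = _balanced_groups(rng, config.n_circ, config.n_groups)
    g_dis = _balanced_groups(rng, config.n_disease, config.n_groups)
    g_aux = {
        role: _balanced_groups(rng, config.aux_sizes[role], config.n_groups)
        for role in AUX_ROLES
    }

    def rel(left, gl, right, gr, name):
        return _sample_relation(rng, left, gl, right, gr, config.p_in, config.p_out, name)

    tables = {
        REL_CIRC_DISEASE: rel(circ, g_circ, disease, g_dis, REL_CIRC_DISEASE),
        REL_CIRC_MIRNA: rel(circ, g_circ, aux["miRNA"], g_aux["miRNA"], REL_CIRC_MIRNA),
    }
    for relation, role in zip(DISEASE_RELATIONS, ("gene", "miRNA", "lncRNA", "drug")):
        tables[relation] = rel(disease, g_dis, aux[role], g_aux[role], relation)

    groups: dict[str, int] = {}
    for names, labels in [
        (circ, g_circ), (disease, g_dis),
        *[(aux[r], g_aux[r]) for r in AUX_ROLES],
    ]:
        groups.update({n: int(g) for n, g in zip(names, labels)})
    return PlantedData(tables=tables, groups=groups, config=config)


def make_benchmark(
    config: PlantedBlockConfig, sampling_seed: int | None = None
) -> tuple[LabeledPairSet, PlantedData]:
    """Planted tables packaged with a balanced labeled pair set for cross-validation.

    Positives are the generated circRNA-disease edges; an equal number of
    negatives is drawn from the complement of the grid.
    """
    data = generate_planted(config)
    positives = list(data.tables[REL_CIRC_DISEASE].pairs)
    if not positives:
        raise ValueError("generator produced no circRNA-disease edges; raise p_in/p_out")
    circ_vocab = EntityVocabulary(role="circRNA", names=tuple(_names("circ", config.n_circ)))
    disease_vocab = EntityVocabulary(role="disease", names=tuple(_names("dis", config.n_disease)))
    seed = config.seed + 10_007 if sampling_seed is None else sampling_seed
    negatives = sample_negatives(positives, circ_vocab, disease_vocab, len(positives), seed)
    pair_set = LabeledPairSet(
        pairs=tuple(positives) + tuple(negatives),
        labels=(1,) * len(positives) + (0,) * len(negatives),
        provenance={"positive_source": "planted", "negative_seed": seed},
    )
    return pair_set, data


def write_edge_lists(data: PlantedData, out_dir: str | Path) -> dict[str, Path]:
    """One two-column TSV per relation plus a JSON sidecar of ground-truth groups."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for relation, table in data.tables.items():
        fname = relation.replace("-", "_").lower() + ".tsv"
        paths[relation] = out_dir / fname
        write_association_table(table, paths[relation])
    paths["groups"] = out_dir / "groups.json"
    paths["groups"].write_text(json.dumps(data.groups, indent=0, sort_keys=True))
    return paths
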