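"""Association edge lists, entity vocabularies, and fused binary adjacency matrices.

Heterogeneous association data (circRNA-disease, circRNA-miRNA, disease-gene,
disease-miRNA, disease-lncRNA, disease-drug) is represented uniformly: an edge
list per relation type, and per entity class a binary adjacency matrix whose
rows are entities of that class and whose columns are the concatenation of one
block per relation type.  Entry (i, j) is 1 exactly when the corresponding
pair was observed.  The i-th row of such a matrix is the entity's *association
profile* -- the reconstruction target of the embedding network.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical form of an entity name: strip, case-fold, collapse whitespace runs."""
    return _WS_RUN.sub(" ", name.strip()).casefold()


class VocabularyError(ValueError):
    """Raised for empty vocabularies or unknown entity lookups."""


class EdgeListParseError(ValueError):
    """Raised when an edge-list row cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class EntityVocabulary:
    """Ordered set of normalized entity names for one entity class (role)."""

    role: str
    names: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise VocabularyError(f"empty vocabulary for role {self.role!r}")
        index = {name: k for k, name in enumerate(self.names)}
        if len(index) != len(self.names):
            raise VocabularyError(f"duplicate names in vocabulary for role {self.role!r}")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._index

    def index_of(self, name: str) -> int:
        key = normalize_name(name)
        try:
            return self._index[key]
        except KeyError:
            raise VocabularyError(f"unknown {self.role} entity: {name!r}") from None


@dataclass(frozen=True)
class AssociationTable:
    """Deduplicated, normalized (entity_a, entity_b) pairs for one relation type."""

    relation: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError(f"{self.relation}: pair with empty name: {(a, b)!r}")
            if (a, b) in seen:
                raise ValueError(f"{self.relation}: duplicate pair {(a, b)!r}")
            seen.add((a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_pairs(cls, relation: str, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        """Normalize and deduplicate raw pairs, preserving first-appearance order."""
        out: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for a, b in pairs:
            key = (normalize_name(a), normalize_name(b))
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
        return cls(relation=relation, pairs=tuple(out))


def read_association_table(path: str | Path, relation: str, *, delimiter: str | None = None) -> AssociationTable:
    """Read a two-column edge list (one header line) into an AssociationTable.

    The delimiter is auto-detected per file (tab if the header contains one,
    else comma) unless given.  Rows with fewer than two fields raise
    EdgeListParseError with the offending line number.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"edge list not found: {path}")
    raw_pairs: list[tuple[str, str]] = []
    n_read = 0
    with path.open() as fh:
        header = fh.readline()
        if delimiter is None:
            delimiter = "\t" if "\t" in header else ","
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 non-empty fields, got {line.rstrip()!r}"
                )
            n_read += 1
            raw_pairs.append((fields[0], fields[1]))
    table = AssociationTable.from_pairs(relation, raw_pairs)
    if n_read == 0:
        logger.warning("%s: edge list %s contains no data rows", relation, path)
    else:
        logger.info("%s: read %d rows, kept %d unique pairs", relation, n_read, len(table))
    return table


def write_association_table(table: AssociationTable, path: str | Path, *, delimiter: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"entity_a{delimiter}entity_b\n")
        for a, b in table.pairs:
            fh.write(f"{a}{delimiter}{b}\n")


def build_vocabulary(
    tables: Sequence[AssociationTable], side: str, role: str
) -> EntityVocabulary:
    """Collect every distinct normalized name on one side of the given tables.

    ``side`` is ``"left"`` (entity_a) or ``"right"`` (entity_b); names keep
    first-appearance order across the table sequence.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not tables:
        raise ValueError("at least one table is required")
    pos = 0 if side == "left" else 1
    names: list[str] = []
    seen: set[str] = set()
    for table in tables:
        for pair in table.pairs:
            name = pair[pos]
            if name not in seen:
                seen.add(name)
                names.append(name)
    if not names:
        raise VocabularyError(f"no {role} names found on side {side!r}")
    return EntityVocabulary(role=role, names=tuple(names))


def merge_vocabularies(role: str, *vocabs: EntityVocabulary) -> EntityVocabulary:
    """Union of vocabularies under one role, first-appearance order preserved."""
    names: list[str] = []
    seen: set[str] = set()
    for vocab in vocabs:
        for name in vocab.names:
            if name not in seen:
                seen.add(name)
                names.append(name)
    return EntityVocabulary(role=role, names=tuple(names))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary entity x fused-feature matrix with named column blocks.

    ``values`` is dense uint8 of shape ``|row_vocab| x sum(len(v) for v in
    block vocabularies)``; ``block_offsets[k]`` is the first column of block k.
    """

    row_vocab: EntityVocabulary
    column_blocks: tuple[tuple[str, EntityVocabulary], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n_cols = sum(len(v) for _, v in self.column_blocks)
        if self.values.shape != (len(self.row_vocab), n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.row_vocab)}, {n_cols})"
            )
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def block_offsets(self) -> tuple[int, ...]:
        offsets = []
        off = 0
        for _, vocab in self.column_blocks:
            offsets.append(off)
            off += len(vocab)
        return tuple(offsets)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for relation, vocab in self.column_blocks:
            names.extend(f"{relation}:{name}" for name in vocab.names)
        return tuple(names)


def build_adjacency(
    row_vocab: EntityVocabulary,
    tables: Sequence[AssociationTable],
    column_vocabs: Sequence[EntityVocabulary],
    *,
    prune_empty_columns: bool = True,
    on_unknown_column: str = "drop",
) -> AdjacencyMatrix:
    """Assemble the fused binary adjacency from one table per column block.

    Pairs whose left name is not in ``row_vocab`` are dropped with a logged
    count (the source relations cover different entity sets).  Pairs whose
    right name is missing from the block vocabulary are dropped or raise,
    per ``on_unknown_column`` ("drop" | "fail").  All-zero columns (entities
    never linked to any row entity) are pruned by default.
    """
    if len(tables) != len(column_vocabs):
        raise ValueError(
            f"{len(tables)} tables but {len(column_vocabs)} column vocabularies"
        )
    if on_unknown_column not in ("drop", "fail"):
        raise ValueError(f"on_unknown_column must be 'drop' or 'fail', got {on_unknown_column!r}")

    blocks: list[np.ndarray] = []
    kept_blocks: list[tuple[str, EntityVocabulary]] = []
    for table, col_vocab in zip(tables, column_vocabs):
        block = np.zeros((len(row_vocab), len(col_vocab)), dtype=np.uint8)
        n_dropped_row = n_dropped_col = 0
        for a, b in table.pairs:
            if a not in row_vocab:
                n_dropped_row += 1
                continue
            if b not in col_vocab:
                if on_unknown_column == "fail":
                    raise VocabularyError(
                        f"{table.relation}: column entity {b!r} missing from "
                        f"{col_vocab.role} vocabulary"
                    )
                n_dropped_col += 1
                continue
            block[row_vocab.index_of(a), col_vocab.index_of(b)] = 1
        if n_dropped_row or n_dropped_col:
            logger.warning(
                "%s: dropped %d pairs with unknown row entity, %d with unknown column entity",
                table.relation, n_dropped_row, n_dropped_col,
            )
        if prune_empty_columns:
            keep = block.any(axis=0)
            if not keep.any():
                # every column empty: the whole block vanishes under pruning
                logger.info("%s: pruned entire all-zero block", table.relation)
                continue
            if not keep.all():
                logger.info(
                    "%s: pruned %d all-zero columns", table.relation, int((~keep).sum())
                )
                block = block[:, keep]
                col_vocab = EntityVocabulary(
                    role=col_vocab.role,
                    names=tuple(n for n, k in zip(col_vocab.names, keep) if k),
                )
        blocks.append(block)
        kept_blocks.append((table.relation, col_vocab))
    values = np.hstack(blocks) if blocks else np.zeros((len(row_vocab), 0), dtype=np.uint8)
    return AdjacencyMatrix(
        row_vocab=row_vocab, column_blocks=tuple(kept_blocks), values=values
    )


def row_profile(adj: AdjacencyMatrix, entity: str) -> np.ndarray:
    """The association profile of one row entity: the i-th binary row."""
    return adj.values[adj.row_vocab.index_of(entity)].copy()


def adjacency_to_tables(adj: AdjacencyMatrix) -> list[AssociationTable]:
    """Export each column block back to an edge list (round-trip inverse of build_adjacency)."""
    tables = []
    offsets = adj.block_offsets
    for (relation, vocab), off in zip(adj.column_blocks, offsets):
        block = adj.values[:, off : off + len(vocab)]
        rows, cols = np.nonzero(block)
        pairs = tuple(
            (adj.row_vocab.names[i], vocab.names[j]) for i, j in zip(rows, cols)
        )
        tables.append(AssociationTable(relation=relation, pairs=pairs))
    return tables


def save_adjacency(adj: AdjacencyMatrix, path: str | Path) -> None:
    """Persist as a NumPy archive keyed by values / row names / block names / offsets."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        values=adj.values,
        row_role=np.asarray(adj.row_vocab.role),
        row_names=np.asarray(adj.row_vocab.names, dtype=object),
        block_relations=np.asarray([r for r, _ in adj.column_blocks], dtype=object),
        block_roles=np.asarray([v.role for _, v in adj.column_blocks], dtype=object),
        block_sizes=np.asarray([len(v) for _, v in adj.column_blocks]),
        block_names=np.asarray(
            [name for _, v in adj.column_blocks for name in v.names], dtype=object
        ),
    )


def save_adjacency_mtx(adj: AdjacencyMatrix, prefix: str | Path) -> dict[str, Path]:
    """Export as MatrixMarket plus two name lists (<prefix>.mtx, .rows.txt, .cols.txt)."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_suffix(".mtx"),
        "rows": prefix.with_suffix(".rows.txt"),
        "cols": prefix.with_suffix(".cols.txt"),
    }
    mmwrite(paths["matrix"], csr_matrix(adj.values))
    paths["rows"].write_text("\n".join(adj.row_vocab.names) + "\n")
    paths["cols"].write_text("\n".join(adj.column_names) + "\n")
    return paths


def load_adjacency(path: str | Path) -> AdjacencyMatrix:
    with np.load(path, allow_pickle=True) as npz:
        row_vocab = EntityVocabulary(
            role=str(npz["row_role"]), names=tuple(npz["row_names"])
        )
        blocks = []
        pos = 0
        for relation, role, size in zip(
            npz["block_relations"], npz["block_roles"], npz["block_sizes"]
        ):
            names = tuple(npz["block_names"][pos : pos + int(size)])
            pos += int(size)
            blocks.append((str(relation), EntityVocabulary(role=str(role), names=names)))
        return AdjacencyMatrix(
            row_vocab=row_vocab,
            column_blocks=tuple(blocks),
            values=npz["values"].astype(np.uint8),
        )
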