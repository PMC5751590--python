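"""Readers and writers for the heterogeneous network layers.

Four tab-separated text formats are supported:

* gene-disease association lists (binary links),
* weighted similarity networks (gene-gene functional net, disease-disease
  similarity),
* ortholog-disease incidence profiles (human gene vs. nonhuman-species
  disease, with optional species tag),
* ranked prediction tables.

Lines starting with ``#`` are comments; files are UTF-8. Identifiers are
mapped to dense 0-based indices in sorted order so index assignment is
deterministic across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetworkFormatError",
    "IndexMap",
    "AssociationMatrix",
    "SimilarityMatrix",
    "OrthologProfileSet",
    "load_association_list",
    "load_similarity_network",
    "load_ortholog_profiles",
    "load_ranked_predictions",
    "write_association_list",
    "write_similarity_network",
    "write_ortholog_profiles",
    "write_ranked_predictions",
]


class NetworkFormatError(ValueError):
    """Raised when an edge-list file violates the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexMap:
    """Bijective mapping between identifier strings and dense 0-based indices.

    Identifiers are kept in sorted order, so loading the same set of ids
    always produces the same index assignment.
    """

    entity_ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {eid: k for k, eid in enumerate(self.entity_ids)}
        if len(index) != len(self.entity_ids):
            raise ValueError("duplicate identifiers in IndexMap")
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "IndexMap":
        return cls(tuple(sorted(set(ids))))

    def index_of(self, entity_id: str) -> int:
        return self._index[entity_id]

    def __len__(self) -> int:
        return len(self.entity_ids)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.entity_ids)


@dataclass
class AssociationMatrix:
    """Sparse binary gene x disease link matrix; absence means unlabeled."""

    genes: IndexMap
    diseases: IndexMap
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.int8)
        self.matrix.sum_duplicates()
        if self.matrix.shape != (len(self.genes), len(self.diseases)):
            raise ValueError("matrix shape does not match index maps")
        if self.matrix.nnz and not np.all(self.matrix.data == 1):
            self.matrix.data[:] = 1

    @classmethod
    def from_id_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        pairs = list(pairs)
        genes = IndexMap.from_ids(g for g, _ in pairs)
        diseases = IndexMap.from_ids(d for _, d in pairs)
        idx = {(genes.index_of(g), diseases.index_of(d)) for g, d in pairs}
        return cls.from_index_pairs(genes, diseases, idx)

    @classmethod
    def from_index_pairs(
        cls,
        genes: IndexMap,
        diseases: IndexMap,
        pairs: Iterable[tuple[int, int]],
    ) -> "AssociationMatrix":
        pairs = sorted(set((int(i), int(j)) for i, j in pairs))
        if pairs:
            rows, cols = zip(*pairs)
        else:
            rows, cols = (), ()
        mat = sp.csr_matrix(
            (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
            shape=(len(genes), len(diseases)),
        )
        return cls(genes, diseases, mat)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_entries(self) -> int:
        return int(self.matrix.nnz)

    def entry_list(self) -> list[tuple[int, int]]:
        coo = self.matrix.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def id_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.genes.entity_ids[i], self.diseases.entity_ids[j])
            for i, j in self.entry_list()
        ]

    def has_entry(self, i: int, j: int) -> bool:
        return bool(self.matrix[i, j])

    def without(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given index pairs removed (index maps preserved)."""
        drop = set((int(i), int(j)) for i, j in pairs)
        keep = [p for p in self.entry_list() if p not in drop]
        return AssociationMatrix.from_index_pairs(self.genes, self.diseases, keep)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative similarity matrix over one entity universe."""

    entities: IndexMap
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.float64)
        n = len(self.entities)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match index map")
        asym = abs(self.matrix - self.matrix.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("similarity matrix is not symmetric")

    @classmethod
    def from_dense(cls, entities: IndexMap, values: np.ndarray) -> "SimilarityMatrix":
        return cls(entities, sp.csr_matrix(np.asarray(values, dtype=np.float64)))

    @classmethod
    def empty(cls, entities: IndexMap) -> "SimilarityMatrix":
        n = len(entities)
        return cls(entities, sp.csr_matrix((n, n), dtype=np.float64))

    @property
    def n(self) -> int:
        return len(self.entities)

    def value(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class OrthologProfileSet:
    """Binary incidence of human genes vs. nonhuman-species diseases.

    ``profile(i)`` is the support of row ``i``; ``mean(i)`` is the row mean
    over every nonhuman disease column.
    """

    genes: IndexMap
    nonhuman_diseases: IndexMap
    incidence: sp.csr_matrix

    def __post_init__(self) -> None:
        self.incidence = sp.csr_matrix(self.incidence, dtype=np.int8)
        shape = (len(self.genes), len(self.nonhuman_diseases))
        if self.incidence.shape != shape:
            raise ValueError("incidence shape does not match index maps")
        if self.incidence.nnz and not np.all(self.incidence.data == 1):
            self.incidence.data[:] = 1

    @classmethod
    def from_id_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        genes: IndexMap | None = None,
    ) -> "OrthologProfileSet":
        pairs = list(pairs)
        if genes is None:
            genes = IndexMap.from_ids(g for g, _ in pairs)
        diseases = IndexMap.from_ids(d for _, d in pairs)
        idx = {(genes.index_of(g), diseases.index_of(d)) for g, d in pairs}
        if idx:
            rows, cols = zip(*sorted(idx))
        else:
            rows, cols = (), ()
        inc = sp.csr_matrix(
            (np.ones(len(idx), dtype=np.int8), (rows, cols)),
            shape=(len(genes), len(diseases)),
        )
        return cls(genes, diseases, inc)

    def profile(self, i: int) -> frozenset[int]:
        row = self.incidence.getrow(i)
        return frozenset(row.indices.tolist())

    def profile_size(self, i: int) -> int:
        return int(self.incidence.getrow(i).nnz)

    def profile_sizes(self) -> np.ndarray:
        return np.asarray(self.incidence.sum(axis=1)).ravel()

    def mean(self, i: int) -> float:
        n = len(self.nonhuman_diseases)
        return self.profile_size(i) / n if n else 0.0

    def id_pairs(self) -> list[tuple[str, str]]:
        coo = self.incidence.tocoo()
        return sorted(
            (self.genes.entity_ids[i], self.nonhuman_diseases.entity_ids[j])
            for i, j in zip(coo.row.tolist(), coo.col.tolist())
        )


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _iter_records(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _require_fields(
    path: str | Path, lineno: int, fields: Sequence[str], minimum: int
) -> None:
    if len(fields) < minimum:
        raise NetworkFormatError(
            f"{path}: line {lineno}: expected at least {minimum} "
            f"tab-separated fields, got {len(fields)}"
        )


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_association_list(
    path: str | Path, column_spec: tuple[int, int] = (0, 1)
) -> AssociationMatrix:
    """Load a binary gene-disease association list.

    Duplicate (gene, disease) lines collapse to a single entry. An empty
    file (no records) is an error.
    """
    gcol, dcol = column_spec
    need = max(gcol, dcol) + 1
    pairs: list[tuple[str, str]] = []
    for lineno, fields in _iter_records(path):
        _require_fields(path, lineno, fields, need)
        pairs.append((fields[gcol], fields[dcol]))
    if not pairs:
        raise NetworkFormatError(f"{path}: no association records found")
    return AssociationMatrix.from_id_pairs(pairs)


def load_similarity_network(path: str | Path) -> SimilarityMatrix:
    """Load a weighted undirected network as a symmetric similarity matrix.

    When both directions of an edge are listed with different weights the
    maximum is kept. Self-similarities are dropped (their endpoints are
    still indexed).
    """
    ids: set[str] = set()
    weights: dict[tuple[str, str], float] = {}
    for lineno, fields in _iter_records(path):
        _require_fields(path, lineno, fields, 3)
        a, b, raw = fields[0], fields[1], fields[2]
        try:
            w = float(raw)
        except ValueError:
            raise NetworkFormatError(
                f"{path}: line {lineno}: non-numeric weight {raw!r}"
            ) from None
        if not math.isfinite(w) or w < 0:
            raise NetworkFormatError(
                f"{path}: line {lineno}: weight must be a finite real >= 0, got {raw}"
            )
        ids.update((a, b))
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        weights[key] = max(w, weights.get(key, 0.0))
    entities = IndexMap.from_ids(ids)
    n = len(entities)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for (a, b), w in weights.items():
        if w == 0.0:
            continue
        ia, ib = entities.index_of(a), entities.index_of(b)
        rows.extend((ia, ib))
        cols.extend((ib, ia))
        vals.extend((w, w))
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return SimilarityMatrix(entities, mat)


def load_ortholog_profiles(
    path: str | Path, genes: IndexMap | None = None
) -> OrthologProfileSet:
    """Load ortholog-disease incidence profiles.

    Records are (gene, nonhuman disease[, species]); when a species tag is
    present it is prepended to the disease id as ``species:disease`` so the
    vocabularies of different species never collide. ``genes`` may supply a
    wider gene universe so genes with empty profiles stay indexed.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, fields in _iter_records(path):
        _require_fields(path, lineno, fields, 2)
        disease = fields[1]
        if len(fields) >= 3 and fields[2]:
            disease = f"{fields[2]}:{disease}"
        pairs.append((fields[0], disease))
    if not pairs:
        raise NetworkFormatError(f"{path}: no ortholog records found")
    return OrthologProfileSet.from_id_pairs(pairs, genes=genes)


def load_ranked_predictions(
    path: str | Path,
) -> dict[str, list[tuple[str, float, int]]]:
    """Read a ranked-prediction table back into per-disease blocks."""
    out: dict[str, list[tuple[str, float, int]]] = {}
    first = True
    for lineno, fields in _iter_records(path):
        if first and fields[:1] == ["disease_id"]:
            first = False
            continue
        first = False
        _require_fields(path, lineno, fields, 4)
        disease, gene, score, rank = fields[:4]
        out.setdefault(disease, []).append((gene, float(score), int(rank)))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def write_association_list(path: str | Path, assoc: AssociationMatrix) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene, disease in assoc.id_pairs():
            handle.write(f"{gene}\t{disease}\n")


def write_similarity_network(path: str | Path, sim: SimilarityMatrix) -> None:
    coo = sp.triu(sim.matrix, k=1).tocoo()
    edges = sorted(
        (sim.entities.entity_ids[i], sim.entities.entity_ids[j], w)
        for i, j, w in zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist())
        if w != 0.0
    )
    with open(path, "w", encoding="utf-8") as handle:
        for a, b, w in edges:
            handle.write(f"{a}\t{b}\t{_fmt(w)}\n")


def write_ortholog_profiles(path: str | Path, profiles: OrthologProfileSet) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene, disease in profiles.id_pairs():
            handle.write(f"{gene}\t{disease}\n")


def write_ranked_predictions(
    path: str | Path,
    rankings: Mapping[str, Sequence[tuple[str, float]]],
) -> None:
    """Write per-disease ranked gene predictions.

    Within each disease block genes are ordered by descending score; ties
    are broken by gene identifier. Ranks are 1-based.
    """
    for disease, block in rankings.items():
        for gene, score in block:
            if not math.isfinite(score):
                raise ValueError(
                    f"non-finite score for ({gene}, {disease}): {score}"
                )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("disease_id\tgene_id\tscore\trank\n")
        for disease in sorted(rankings):
            block = sorted(rankings[disease], key=lambda gs: (-gs[1], gs[0]))
            for rank, (gene, score) in enumerate(block, start=1):
                handle.write(f"{disease}\t{gene}\t{_fmt(score)}\t{rank}\n")
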