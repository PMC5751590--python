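"""Gene-gene similarity from ortholog-disease profiles.

Two metrics over binary incidence profiles are provided: cosine (vector
space) similarity and a Pearson correlation mapped into [0, 1] by
``(x + 1) / 2``. Both are then scaled by the relative profile size
``|I(i)| / max_j |I(j)|`` of the query gene, which down-weights genes with
sparse ortholog evidence.

The profile-derived layer is combined with a functional gene network as
``S = S' + omega * minmax(S'')`` with ``omega > 1``, then bounded back into
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .network_io import IndexMap, OrthologProfileSet, SimilarityMatrix

__all__ = [
    "SimilarityConfig",
    "NeighborSets",
    "vss_similarity",
    "pcc_similarity",
    "profile_similarity_matrix",
    "combine_gene_similarity",
    "build_neighbor_sets",
]

Denominator = Literal["full_profile", "intersection"]


@dataclass(frozen=True)
class SimilarityConfig:
    metric: Literal["vss", "pcc"] = "vss"
    omega: float = 2.0
    neighbor_count: int = 5
    denominator: Denominator = "full_profile"

    def __post_init__(self) -> None:
        if self.metric not in ("vss", "pcc"):
            raise ValueError(f"unknown similarity metric {self.metric!r}")
        if not self.omega > 1:
            raise ValueError("omega must be larger than 1")
        if self.neighbor_count < 1:
            raise ValueError("neighbor_count must be >= 1")
        if self.denominator not in ("full_profile", "intersection"):
            raise ValueError(f"unknown denominator policy {self.denominator!r}")


@dataclass
class NeighborSets:
    """Top-k similarity neighbors per gene and per disease.

    Maps an entity index to an ordered tuple of (neighbor index, similarity)
    pairs, descending by similarity with index tie-break. Entities with no
    positive-similarity neighbor are absent.
    """

    gene_neighbors: dict[int, tuple[tuple[int, float], ...]] = field(
        default_factory=dict
    )
    disease_neighbors: dict[int, tuple[tuple[int, float], ...]] = field(
        default_factory=dict
    )


# ---------------------------------------------------------------------------
# Pairwise metrics
# ---------------------------------------------------------------------------


def _degree_scale(profiles: OrthologProfileSet, i: int) -> float:
    sizes = profiles.profile_sizes()
    max_size = sizes.max(initial=0)
    return float(sizes[i] / max_size) if max_size else 0.0


def vss_similarity(
    profiles: OrthologProfileSet,
    i: int,
    g: int,
    denominator: Denominator = "full_profile",
) -> float:
    """Degree-scaled cosine similarity of two binary ortholog profiles.

    Returns 0 when the profiles do not intersect or either is empty. The
    ``intersection`` denominator restricts the norm sums to shared diseases
    (on binary data this is degenerate and kept only for fidelity checks).
    """
    pi, pg = profiles.profile(i), profiles.profile(g)
    inter = len(pi & pg)
    if inter == 0:
        return 0.0
    if denominator == "full_profile":
        raw = min(inter / (np.sqrt(len(pi)) * np.sqrt(len(pg))), 1.0)
    else:
        raw = inter / inter  # sqrt(inter)^2; identically 1 on binary data
    return _degree_scale(profiles, i) * float(raw)


def pcc_similarity(
    profiles: OrthologProfileSet,
    i: int,
    g: int,
    denominator: Denominator = "full_profile",
) -> float:
    """Degree-scaled, [0,1]-mapped Pearson correlation of two profiles.

    The correlation uses each gene's mean incidence over the full
    nonhuman-disease vocabulary. Zero-variance profiles get raw correlation
    0 (mapped to 0.5) before scaling.
    """
    x = profiles.incidence.getrow(i).toarray().ravel().astype(np.float64)
    y = profiles.incidence.getrow(g).toarray().ravel().astype(np.float64)
    mx, my = x.mean() if x.size else 0.0, y.mean() if y.size else 0.0
    xc, yc = x - mx, y - my
    if denominator == "full_profile":
        denom = float(np.linalg.norm(xc) * np.linalg.norm(yc))
        raw = float(xc @ yc / denom) if denom > 0 else 0.0
    else:
        mask = (x > 0) & (y > 0)
        num = float(xc[mask] @ yc[mask])
        denom = float(
            np.sqrt(np.sum(xc[mask] ** 2)) * np.sqrt(np.sum(yc[mask] ** 2))
        )
        raw = num / denom if denom > 0 else 0.0
    raw = float(np.clip(raw, -1.0, 1.0))
    return _degree_scale(profiles, i) * (raw + 1.0) / 2.0


# ---------------------------------------------------------------------------
# Matrix-level construction
# ---------------------------------------------------------------------------


def profile_similarity_matrix(
    profiles: OrthologProfileSet,
    config: SimilarityConfig = SimilarityConfig(),
) -> SimilarityMatrix:
    """All-pairs profile similarity as a symmetric matrix.

    The degree scale ``|I(i)| / max|I|`` is direction-dependent; the matrix
    entry keeps the larger of the two directed values so the result stays
    symmetric (the pairwise functions expose the directed values).
    """
    R = profiles.incidence.toarray().astype(np.float64)
    m, q = R.shape
    sizes = R.sum(axis=1)
    max_size = sizes.max(initial=0.0)
    if max_size == 0 or q == 0:
        return SimilarityMatrix.empty(profiles.genes)

    if config.denominator == "full_profile":
        if config.metric == "vss":
            inter = R @ R.T
            norms = np.sqrt(sizes)
            denom = np.outer(norms, norms)
            with np.errstate(divide="ignore", invalid="ignore"):
                base = np.where((denom > 0) & (inter > 0), inter / denom, 0.0)
            base = np.clip(base, 0.0, 1.0)
        else:
            centered = R - (sizes / q)[:, None]
            sd = np.linalg.norm(centered, axis=1)
            cov = centered @ centered.T
            denom = np.outer(sd, sd)
            with np.errstate(divide="ignore", invalid="ignore"):
                raw = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
            base = (np.clip(raw, -1.0, 1.0) + 1.0) / 2.0
    else:
        fn = vss_similarity if config.metric == "vss" else pcc_similarity
        scale = np.where(max_size > 0, sizes / max_size, 0.0)
        base = np.zeros((m, m))
        for i in range(m):
            for g in range(i + 1, m):
                directed = fn(profiles, i, g, denominator="intersection")
                # undo the directed scale to recover the raw metric value
                base[i, g] = base[g, i] = directed / scale[i] if scale[i] else 0.0

    scale = sizes / max_size
    values = base * np.maximum.outer(scale, scale)
    np.fill_diagonal(values, 0.0)
    return SimilarityMatrix.from_dense(profiles.genes, values)


def combine_gene_similarity(
    s_prime: SimilarityMatrix,
    s_doubleprime: SimilarityMatrix,
    omega: float = 2.0,
) -> SimilarityMatrix:
    """Combine profile-derived and functional-network gene similarities.

    The functional layer's nonzero weights are min-max normalized to [0, 1]
    and added with weight ``omega``; if the combined maximum exceeds 1 the
    result is rescaled by that maximum so every entry stays in [0, 1].
    """
    if s_prime.entities != s_doubleprime.entities:
        raise ValueError("gene index maps of the two layers differ")
    if not omega > 1:
        raise ValueError("omega must be larger than 1")
    func = s_doubleprime.matrix.tocoo()
    if func.nnz == 0:
        return SimilarityMatrix(s_prime.entities, s_prime.matrix.copy())
    w = func.data
    lo, hi = w.min(), w.max()
    norm = np.ones_like(w) if hi == lo else (w - lo) / (hi - lo)
    normalized = sp.csr_matrix(
        (norm, (func.row, func.col)), shape=func.shape
    )
    combined = (s_prime.matrix + omega * normalized).tocsr()
    peak = combined.max() if combined.nnz else 0.0
    if peak > 1.0:
        combined = combined / peak
    return SimilarityMatrix(s_prime.entities, combined)


def build_neighbor_sets(
    gene_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    neighbor_count: int = 5,
) -> NeighborSets:
    """Top-k positive-similarity neighbors for every gene and disease."""
    if neighbor_count < 1:
        raise ValueError("neighbor_count must be >= 1")
    return NeighborSets(
        gene_neighbors=_top_neighbors(gene_sim, neighbor_count),
        disease_neighbors=_top_neighbors(disease_sim, neighbor_count),
    )


def _top_neighbors(
    sim: SimilarityMatrix, k: int
) -> dict[int, tuple[tuple[int, float], ...]]:
    out: dict[int, tuple[tuple[int, float], ...]] = {}
    mat = sim.matrix.tocsr()
    for i in range(sim.n):
        row = mat.getrow(i)
        cols, vals = row.indices, row.data
        keep = (cols != i) & (vals > 0)
        cols, vals = cols[keep], vals[keep]
        if cols.size == 0:
            continue
        order = np.lexsort((cols, -vals))[:k]
        out[i] = tuple((int(cols[t]), float(vals[t])) for t in order)
    return out
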