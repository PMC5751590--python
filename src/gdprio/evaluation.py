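"""Cross-validated top-k retrieval evaluation.

Known positives are split into seeded folds; each fold in turn is hidden
from training and the model is asked to rank, for every disease with a
hidden link, all genes that are not among that disease's training
positives. Diseases are stratified by the number of training-visible
positives: none remaining ("single") versus at least one ("many").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import factor_model as fm
from .negative_sampling import SamplingConfig, select_negatives, walk_propensity
from .network_io import AssociationMatrix, SimilarityMatrix
from .similarity import NeighborSets, build_neighbor_sets

__all__ = [
    "EvaluationProtocol",
    "RetrievalCurve",
    "threefold_split",
    "stratify_diseases",
    "topk_curve",
    "curve_from_ranks",
    "cross_validate",
    "parameter_grid",
]

STRATA = ("single", "many")


@dataclass(frozen=True)
class EvaluationProtocol:
    n_folds: int = 3
    k_grid: tuple[int, ...] = tuple(range(1, 101))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        grid = tuple(int(k) for k in self.k_grid)
        if not grid:
            raise ValueError("k_grid must be non-empty")
        if any(b <= a for a, b in zip(grid, grid[1:])) or grid[0] < 1:
            raise ValueError("k_grid must be strictly increasing positive cutoffs")
        object.__setattr__(self, "k_grid", grid)


@dataclass
class RetrievalCurve:
    """Probability that a held-out true gene appears in the top k."""

    points: list[tuple[int, float]]
    stratum: str = "all"
    model: str = ""

    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.points])

    def probability_at(self, k: int) -> float:
        for kk, p in self.points:
            if kk == k:
                return p
        raise KeyError(f"no point at k={k}")


def threefold_split(
    assoc: AssociationMatrix, seed: int = 0, n_folds: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Partition positive pairs into near-equal seeded folds.

    Returns (pairs, fold_of) where ``pairs`` is an (N, 2) index array in
    deterministic order and ``fold_of[t]`` is the fold of ``pairs[t]``.
    Fold sizes differ by at most one.
    """
    pairs = np.array(assoc.entry_list(), dtype=np.int64).reshape(-1, 2)
    n_pos = len(pairs)
    if n_pos < n_folds:
        raise ValueError(f"{n_pos} positives cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pos)
    fold_of = np.empty(n_pos, dtype=np.int64)
    fold_of[perm] = np.arange(n_pos) % n_folds
    return pairs, fold_of


def stratify_diseases(
    assoc: AssociationMatrix, test_pairs: Iterable[tuple[int, int]]
) -> dict[str, set[int]]:
    """Partition diseases by training-visible positive count.

    Diseases with no links at all are excluded. A disease whose every link
    is held out falls in the "single" (no known genes) stratum; otherwise
    it has "many" known genes.
    """
    total = np.asarray(assoc.matrix.sum(axis=0)).ravel()
    held = np.zeros_like(total)
    for _, j in test_pairs:
        held[j] += 1
    remaining = total - held
    out: dict[str, set[int]] = {"single": set(), "many": set()}
    for j in np.flatnonzero(total > 0):
        out["single" if remaining[j] == 0 else "many"].add(int(j))
    return out


def curve_from_ranks(
    ranks: Sequence[int],
    k_grid: Sequence[int],
    stratum: str = "all",
    model: str = "",
) -> RetrievalCurve:
    ranks_arr = np.asarray(ranks)
    if ranks_arr.size == 0:
        raise ValueError("no held-out pairs to evaluate")
    points = [(int(k), float(np.mean(ranks_arr <= k))) for k in k_grid]
    return RetrievalCurve(points=points, stratum=stratum, model=model)


def topk_curve(
    rankings: Mapping[int, Sequence[int]],
    truth: Iterable[tuple[int, int]],
    k_grid: Sequence[int],
    stratum: str = "all",
    model: str = "",
) -> RetrievalCurve:
    """Fraction of held-out (gene, disease) pairs retrieved in the top k.

    ``rankings[j]`` is the ordered candidate gene list for disease j and
    must cover every truth pair's disease.
    """
    position: dict[int, dict[int, int]] = {
        j: {g: r for r, g in enumerate(genes, start=1)}
        for j, genes in rankings.items()
    }
    ranks = []
    for i, j in truth:
        if j not in position or i not in position[j]:
            raise ValueError(f"truth pair ({i}, {j}) missing from rankings")
        ranks.append(position[j][i])
    return curve_from_ranks(ranks, k_grid, stratum=stratum, model=model)


# ---------------------------------------------------------------------------
# Cross-validated model evaluation
# ---------------------------------------------------------------------------


def _heldout_ranks(
    scores: np.ndarray,
    train_assoc: AssociationMatrix,
    test_pairs: np.ndarray,
) -> list[tuple[int, int, int]]:
    """1-based rank of each held-out gene among its disease's candidates.

    Candidates are all genes minus the disease's training positives; ties
    break by gene index (== sorted identifier order).
    """
    train_cols = train_assoc.matrix.tocsc()
    out = []
    by_disease: dict[int, list[int]] = {}
    for i, j in test_pairs:
        by_disease.setdefault(int(j), []).append(int(i))
    for j, genes in by_disease.items():
        col = scores[:, j].copy()
        excluded = train_cols.getcol(j).indices
        col[excluded] = -np.inf
        for i in genes:
            s = col[i]
            higher = int(np.sum(col > s))
            tied_before = int(np.sum((col == s) & (np.arange(len(col)) < i)))
            out.append((i, j, higher + tied_before + 1))
    return out


def cross_validate(
    assoc: AssociationMatrix,
    gene_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    *,
    protocol: EvaluationProtocol = EvaluationProtocol(),
    train_cfg: fm.TrainConfig = fm.TrainConfig(),
    sampling_cfg: SamplingConfig = SamplingConfig(),
    neighbor_count: int = 5,
    model_label: str | None = None,
) -> pd.DataFrame:
    """Run the full CV protocol and return a long-format results table.

    Columns: model, stratum, alpha, beta, D, k, probability, n_pairs.
    Strata are "single", "many", and the pooled "all"; held-out ranks are
    pooled across folds before the curve is computed.
    """
    label = model_label or train_cfg.variant
    pairs, fold_of = threefold_split(assoc, protocol.seed, protocol.n_folds)
    neighbors = build_neighbor_sets(gene_sim, disease_sim, neighbor_count)

    stratum_ranks: dict[str, list[int]] = {"single": [], "many": [], "all": []}
    for fold in range(protocol.n_folds):
        test = pairs[fold_of == fold]
        train_pairs = pairs[fold_of != fold]
        train_assoc = AssociationMatrix.from_index_pairs(
            assoc.genes, assoc.diseases, map(tuple, train_pairs)
        )
        propensity = walk_propensity(
            gene_sim, train_assoc, disease_sim, norm=sampling_cfg.norm
        )
        labeled = select_negatives(
            propensity,
            train_assoc,
            replace(sampling_cfg, seed=sampling_cfg.seed + fold),
        )
        model, _ = fm.train(
            labeled,
            assoc.shape,
            replace(train_cfg, seed=train_cfg.seed + fold),
            neighbors,
        )
        strata = stratify_diseases(assoc, map(tuple, test))
        scores = model.score_matrix()
        for i, j, rank in _heldout_ranks(scores, train_assoc, test):
            stratum = "single" if j in strata["single"] else "many"
            stratum_ranks[stratum].append(rank)
            stratum_ranks["all"].append(rank)

    rows = []
    for stratum, ranks in stratum_ranks.items():
        if not ranks:
            continue
        curve = curve_from_ranks(ranks, protocol.k_grid, stratum, label)
        for k, prob in curve.points:
            rows.append(
                {
                    "model": label,
                    "stratum": stratum,
                    "alpha": train_cfg.alpha,
                    "beta": train_cfg.beta,
                    "D": train_cfg.latent_dim,
                    "k": k,
                    "probability": prob,
                    "n_pairs": len(ranks),
                }
            )
    return pd.DataFrame(rows)


def parameter_grid(
    alphas: Sequence[float],
    betas: Sequence[float],
    assoc: AssociationMatrix,
    gene_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    *,
    protocol: EvaluationProtocol = EvaluationProtocol(),
    train_cfg: fm.TrainConfig = fm.TrainConfig(variant="pairwise"),
    sampling_cfg: SamplingConfig = SamplingConfig(),
    neighbor_count: int = 5,
) -> pd.DataFrame:
    """One full CV evaluation per (alpha, beta) grid cell, both strata."""
    if not len(alphas) or not len(betas):
        raise ValueError("alpha and beta grids must be non-empty")
    frames = []
    for alpha in alphas:
        for beta in betas:
            cfg = replace(train_cfg, alpha=float(alpha), beta=float(beta))
            frames.append(
                cross_validate(
                    assoc,
                    gene_sim,
                    disease_sim,
                    protocol=protocol,
                    train_cfg=cfg,
                    sampling_cfg=sampling_cfg,
                    neighbor_count=neighbor_count,
                )
            )
    return pd.concat(frames, ignore_index=True)
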