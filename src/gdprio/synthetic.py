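"""Synthetic heterogeneous gene-disease datasets with planted structure.

Genes and diseases are placed around shared cluster centers in a latent
space; link probabilities follow the model's own generative map
``p = exp(-(||U_i - V_j||^2 / 2 + vartheta))``, globally rescaled so the
mean link probability hits a target density. Similarity layers derive from
planted-factor distances (not from the sampled links), so neighborhood
regularization carries information about held-out links. Ortholog profiles
are cluster-coherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .evaluation import curve_from_ranks, RetrievalCurve
from .factor_model import FactorModel
from .network_io import (
    AssociationMatrix,
    IndexMap,
    OrthologProfileSet,
    SimilarityMatrix,
    write_association_list,
    write_ortholog_profiles,
    write_similarity_network,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "recovery_report",
           "write_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 300
    n_diseases: int = 150
    latent_dim: int = 5
    n_clusters: int = 6
    cluster_spread: float = 0.4
    n_nonhuman_diseases: int = 60
    similarity_noise: float = 0.05
    density_target: float = 0.02
    vartheta: float = 1e-4
    seed: int = 0
    # ortholog link rates inside / outside a gene's own cluster
    profile_rate_within: float = 0.6
    profile_rate_between: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_diseases, self.latent_dim, self.n_clusters) < 1:
            raise ValueError("counts and dimensions must be >= 1")
        if not (0.0 < self.density_target < 1.0):
            raise ValueError("density_target must lie in (0, 1)")
        if not self.cluster_spread > 0:
            raise ValueError("cluster_spread must be positive")
        if self.similarity_noise < 0:
            raise ValueError("similarity_noise must be >= 0")
        if not self.vartheta > 0:
            raise ValueError("vartheta must be positive")


@dataclass
class SyntheticDataset:
    assoc: AssociationMatrix
    gene_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    ortholog: OrthologProfileSet
    truth: np.ndarray
    gene_factors: np.ndarray
    disease_factors: np.ndarray
    gene_clusters: np.ndarray
    disease_clusters: np.ndarray
    config: GeneratorConfig


def _ids(prefix: str, count: int) -> IndexMap:
    width = len(str(max(count - 1, 0)))
    return IndexMap(tuple(f"{prefix}{k:0{width}d}" for k in range(count)))


def _mean_density(d2: np.ndarray, scale: float, vartheta: float) -> float:
    return float(np.exp(-(scale**2 * d2 / 2.0 + vartheta)).mean())


def _solve_scale(d2: np.ndarray, target: float, vartheta: float) -> float:
    """Bisection for the global factor scale hitting the mean density."""
    if target >= _mean_density(d2, 0.0, vartheta):
        raise ValueError(
            f"density_target {target} unreachable: ceiling is exp(-vartheta)"
        )
    hi = 1.0
    while _mean_density(d2, hi, vartheta) > target:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("density_target unreachable for this geometry")
    lo = 0.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _mean_density(d2, mid, vartheta) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _similarity_from_factors(
    factors: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    d2 = cdist(factors, factors, "sqeuclidean")
    values = np.exp(-d2)
    if noise > 0:
        upper = np.triu(rng.normal(0.0, noise, size=values.shape), k=1)
        values = values + upper + upper.T
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 0.0)
    return values


def generate(cfg: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Draw a fully reproducible synthetic dataset for the given config."""
    rng = np.random.default_rng(cfg.seed)
    centers = rng.normal(0.0, 1.0, size=(cfg.n_clusters, cfg.latent_dim))
    gene_clusters = rng.permutation(np.arange(cfg.n_genes) % cfg.n_clusters)
    disease_clusters = rng.permutation(np.arange(cfg.n_diseases) % cfg.n_clusters)
    U = centers[gene_clusters] + rng.normal(
        0.0, cfg.cluster_spread, size=(cfg.n_genes, cfg.latent_dim)
    )
    V = centers[disease_clusters] + rng.normal(
        0.0, cfg.cluster_spread, size=(cfg.n_diseases, cfg.latent_dim)
    )
    d2 = cdist(U, V, "sqeuclidean")
    scale = _solve_scale(d2, cfg.density_target, cfg.vartheta)
    U *= scale
    V *= scale
    truth = np.exp(-(cdist(U, V, "sqeuclidean") / 2.0 + cfg.vartheta))

    genes = _ids("g", cfg.n_genes)
    diseases = _ids("d", cfg.n_diseases)
    links = rng.random(truth.shape) < truth
    assoc = AssociationMatrix.from_index_pairs(
        genes, diseases, zip(*np.nonzero(links))
    )

    gene_sim = SimilarityMatrix.from_dense(
        genes, _similarity_from_factors(U, cfg.similarity_noise, rng)
    )
    disease_sim = SimilarityMatrix.from_dense(
        diseases, _similarity_from_factors(V, cfg.similarity_noise, rng)
    )

    nonhuman = _ids("sp:nd", cfg.n_nonhuman_diseases)
    nd_clusters = np.arange(cfg.n_nonhuman_diseases) % cfg.n_clusters
    same = gene_clusters[:, None] == nd_clusters[None, :]
    rate = np.where(same, cfg.profile_rate_within, cfg.profile_rate_between)
    incidence = rng.random(rate.shape) < rate
    ortholog = OrthologProfileSet(
        genes,
        nonhuman,
        np.asarray(incidence, dtype=np.int8),
    )

    return SyntheticDataset(
        assoc=assoc,
        gene_sim=gene_sim,
        disease_sim=disease_sim,
        ortholog=ortholog,
        truth=truth,
        gene_factors=U,
        disease_factors=V,
        gene_clusters=gene_clusters,
        disease_clusters=disease_clusters,
        config=cfg,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the four network layers plus the generative truth as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "gene_disease.tsv",
        "gene_network": outdir / "gene_network.tsv",
        "disease_similarity": outdir / "disease_similarity.tsv",
        "ortholog_profiles": outdir / "ortholog_profiles.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_association_list(paths["associations"], dataset.assoc)
    write_similarity_network(paths["gene_network"], dataset.gene_sim)
    write_similarity_network(paths["disease_similarity"], dataset.disease_sim)
    write_ortholog_profiles(paths["ortholog_profiles"], dataset.ortholog)
    genes = dataset.assoc.genes.entity_ids
    diseases = dataset.assoc.diseases.entity_ids
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        handle.write("gene_id\tdisease_id\tprobability\n")
        for i, gene in enumerate(genes):
            for j, disease in enumerate(diseases):
                handle.write(f"{gene}\t{disease}\t{dataset.truth[i, j]!r}\n")
    return paths


def recovery_report(
    dataset: SyntheticDataset,
    model: FactorModel,
    heldout: Sequence[tuple[int, int]],
    *,
    seed: int = 0,
    k_grid: Sequence[int] = tuple(range(1, 51)),
) -> dict:
    """Measure how well a trained model recovers the planted structure.

    Reports the Spearman correlation between predicted and generative link
    probabilities over unlabeled pairs, the AUC of held-out positives
    against an equal number of sampled unlabeled pairs, and the top-k
    retrieval curve with its random-ranker expectation.
    """
    scores = model.score_matrix()
    assoc_mask = dataset.assoc.toarray().astype(bool)
    heldout = [(int(i), int(j)) for i, j in heldout]
    unlabeled = ~assoc_mask
    corr = float(spearmanr(scores[unlabeled], dataset.truth[unlabeled]).statistic)

    rng = np.random.default_rng(seed)
    flat_unlabeled = np.flatnonzero(unlabeled.ravel())
    n_cols = assoc_mask.shape[1]
    neg_flat = rng.choice(flat_unlabeled, size=len(heldout), replace=False)
    pos_scores = np.array([scores[i, j] for i, j in heldout])
    neg_scores = scores.ravel()[neg_flat]
    auc = float(
        roc_auc_score(
            np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))]),
            np.concatenate([pos_scores, neg_scores]),
        )
    )

    train_cols: dict[int, set[int]] = {}
    heldout_set = set(heldout)
    for i, j in dataset.assoc.entry_list():
        if (i, j) not in heldout_set:
            train_cols.setdefault(j, set()).add(i)
    m = assoc_mask.shape[0]
    ranks = []
    candidate_counts = []
    for i, j in heldout:
        col = scores[:, j].copy()
        excluded = sorted(train_cols.get(j, ()))
        col[excluded] = -np.inf
        higher = int(np.sum(col > col[i]))
        tied_before = int(np.sum((col == col[i]) & (np.arange(m) < i)))
        ranks.append(higher + tied_before + 1)
        candidate_counts.append(m - len(excluded))
    curve = curve_from_ranks(ranks, k_grid, stratum="all", model="recovery")
    mean_candidates = float(np.mean(candidate_counts))
    random_curve = [(int(k), min(1.0, k / mean_candidates)) for k in k_grid]

    return {
        "truth_rank_correlation": corr,
        "heldout_auc": auc,
        "curve": curve,
        "random_expectation": random_curve,
        "n_heldout": len(heldout),
    }
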