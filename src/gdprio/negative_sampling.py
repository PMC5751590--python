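"""Random-walk negative sampling for the positive-unlabeled link problem.

Unlabeled gene-disease pairs are scored by a one-step heterogeneous walk
propensity (similar genes -> known links -> similar diseases). Negatives
are drawn mostly from low-propensity pairs, with a small configurable share
from above the threshold to improve generalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .network_io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "SamplingConfig",
    "LabeledPairSet",
    "walk_propensity",
    "select_negatives",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingConfig:
    """Negative-sampling configuration.

    ``theta`` is the propensity threshold splitting the two negative
    strata; when None it is resolved as ``theta_percentile`` of the
    propensity over unlabeled pairs. ``n_negatives="auto"`` matches the
    positive count.
    """

    n_negatives: int | str = "auto"
    high_fraction: float = 0.1
    theta: float | None = None
    theta_percentile: float = 90.0
    seed: int = 0
    norm: Literal["stochastic", "frobenius"] = "stochastic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.high_fraction < 0.5):
            raise ValueError("high_fraction must lie in [0, 0.5)")
        if isinstance(self.n_negatives, str):
            if self.n_negatives != "auto":
                raise ValueError("n_negatives must be a positive int or 'auto'")
        elif self.n_negatives < 1:
            raise ValueError("n_negatives must be >= 1")
        if not (0.0 <= self.theta_percentile <= 100.0):
            raise ValueError("theta_percentile must lie in [0, 100]")
        if self.norm not in ("stochastic", "frobenius"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass(frozen=True)
class LabeledPairSet:
    """Supervised training triples (gene, disease, label in {0, 1})."""

    gene_idx: np.ndarray
    disease_idx: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.gene_idx) == len(self.disease_idx) == len(self.labels)):
            raise ValueError("triple arrays must have equal length")
        pairs = set(zip(self.gene_idx.tolist(), self.disease_idx.tolist()))
        if len(pairs) != len(self.gene_idx):
            raise ValueError("duplicate (gene, disease) pair in labeled set")

    def __len__(self) -> int:
        return len(self.labels)

    def triples(self) -> list[tuple[int, int, int]]:
        return list(
            zip(
                self.gene_idx.tolist(),
                self.disease_idx.tolist(),
                self.labels.tolist(),
            )
        )

    @classmethod
    def from_triples(cls, triples) -> "LabeledPairSet":
        triples = list(triples)
        gi = np.array([t[0] for t in triples], dtype=np.int64)
        dj = np.array([t[1] for t in triples], dtype=np.int64)
        y = np.array([t[2] for t in triples], dtype=np.int8)
        return cls(gi, dj, y)


def _as_dense(layer) -> np.ndarray:
    if isinstance(layer, (SimilarityMatrix,)):
        return layer.toarray()
    if isinstance(layer, AssociationMatrix):
        return layer.toarray().astype(np.float64)
    if sp.issparse(layer):
        return np.asarray(layer.todense(), dtype=np.float64)
    return np.asarray(layer, dtype=np.float64)


def walk_propensity(
    gene_sim,
    assoc,
    disease_sim,
    norm: Literal["stochastic", "frobenius"] = "stochastic",
) -> np.ndarray:
    """One-step walk propensity from every gene to every disease.

    With the default ``stochastic`` normalization the gene similarity rows
    and disease similarity columns are made stochastic (zero rows/columns
    stay zero) and the result is the probability of the walk
    gene -> known link -> disease. The ``frobenius`` variant divides the
    raw triple product by the two Frobenius norms instead.
    """
    S_g = _as_dense(gene_sim)
    Y = _as_dense(assoc)
    S_d = _as_dense(disease_sim)
    m, n = Y.shape
    if S_g.shape != (m, m) or S_d.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: gene_sim {S_g.shape}, assoc {Y.shape}, "
            f"disease_sim {S_d.shape}"
        )
    if norm == "stochastic":
        row_sums = S_g.sum(axis=1, keepdims=True)
        col_sums = S_d.sum(axis=0, keepdims=True)
        Rn = np.divide(S_g, row_sums, out=np.zeros_like(S_g), where=row_sums > 0)
        Cn = np.divide(S_d, col_sums, out=np.zeros_like(S_d), where=col_sums > 0)
        return Rn @ Y @ Cn
    denom = np.linalg.norm(S_g) * np.linalg.norm(S_d)
    if denom == 0:
        return np.zeros((m, n))
    return S_g @ Y @ S_d / denom


def resolve_theta(
    propensity: np.ndarray, positives: AssociationMatrix, cfg: SamplingConfig
) -> float:
    """Threshold from config, or the configured percentile over unlabeled pairs."""
    if cfg.theta is not None:
        return float(cfg.theta)
    unlabeled = positives.toarray() == 0
    return float(np.percentile(propensity[unlabeled], cfg.theta_percentile))


def select_negatives(
    propensity: np.ndarray,
    positives: AssociationMatrix,
    cfg: SamplingConfig = SamplingConfig(),
) -> LabeledPairSet:
    """Positives (label 1) plus seeded stratified negative draws (label 0).

    ``ceil((1 - high_fraction) * n)`` negatives come from unlabeled pairs
    with propensity <= theta, the rest from above theta; if a stratum is
    too small the deficit is filled from the other one (logged).
    """
    pos_mask = positives.toarray().astype(bool)
    if propensity.shape != pos_mask.shape:
        raise ValueError("propensity and association shapes differ")
    unlabeled = ~pos_mask
    total_unlabeled = int(unlabeled.sum())
    n_pos = int(pos_mask.sum())
    n_neg = n_pos if cfg.n_negatives == "auto" else int(cfg.n_negatives)
    if n_neg > total_unlabeled:
        raise ValueError(
            f"requested {n_neg} negatives but only {total_unlabeled} "
            "unlabeled pairs exist"
        )
    theta = resolve_theta(propensity, positives, cfg)

    n_low = math.ceil((1.0 - cfg.high_fraction) * n_neg)
    n_high = n_neg - n_low
    low_pool = np.flatnonzero(unlabeled.ravel() & (propensity.ravel() <= theta))
    high_pool = np.flatnonzero(unlabeled.ravel() & (propensity.ravel() > theta))

    if n_low > low_pool.size:
        deficit = n_low - low_pool.size
        logger.warning(
            "low-propensity stratum short by %d pairs; filling from above theta",
            deficit,
        )
        n_low, n_high = low_pool.size, n_high + deficit
    if n_high > high_pool.size:
        deficit = n_high - high_pool.size
        logger.warning(
            "high-propensity stratum short by %d pairs; filling from below theta",
            deficit,
        )
        n_high, n_low = high_pool.size, n_low + deficit

    rng = np.random.default_rng(cfg.seed)
    chosen_low = rng.choice(low_pool, size=n_low, replace=False)
    chosen_high = rng.choice(high_pool, size=n_high, replace=False)
    chosen = np.sort(np.concatenate([chosen_low, chosen_high]))

    n_cols = pos_mask.shape[1]
    neg_i, neg_j = chosen // n_cols, chosen % n_cols
    pos_pairs = positives.entry_list()
    gi = np.concatenate([np.array([p[0] for p in pos_pairs], dtype=np.int64), neg_i])
    dj = np.concatenate([np.array([p[1] for p in pos_pairs], dtype=np.int64), neg_j])
    labels = np.concatenate(
        [np.ones(n_pos, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)]
    )
    return LabeledPairSet(gi, dj, labels)
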