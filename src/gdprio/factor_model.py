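"""Probability-based latent factor model for binary link prediction.

Genes and diseases live in one D-dimensional latent space. A pair's half
squared distance ``f = ||U_i - V_j||^2 / 2 + vartheta`` is converted into a
link probability ``P(Y=1) = exp(-f)``, and the Bernoulli log-likelihood is
maximized by stochastic gradient ascent.

Three variants are supported:

* ``basic`` — likelihood only;
* ``centroid`` — adds a penalty pulling each latent vector toward the
  similarity-weighted centroid of its network neighbors;
* ``pairwise`` — adds a similarity-weighted penalty on the pairwise
  distances to each neighbor, which also propagates information to
  entities with no positive training pairs (cold start).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .negative_sampling import LabeledPairSet
from .similarity import NeighborSets

__all__ = [
    "FactorModel",
    "TrainConfig",
    "ObjectiveValue",
    "VARIANTS",
    "pair_distance",
    "association_probability",
    "log_likelihood",
    "gradient_likelihood",
    "objective_value",
    "gradients",
    "train",
    "rank_genes",
    "save_checkpoint",
    "load_checkpoint",
]

Variant = Literal["basic", "centroid", "pairwise"]
VARIANTS: tuple[str, ...] = ("basic", "centroid", "pairwise")

#: accepted aliases for the graph-regularized variants
VARIANT_ALIASES = {"model1": "centroid", "model2": "pairwise"}


def canonical_variant(name: str) -> str:
    name = VARIANT_ALIASES.get(name, name)
    if name not in VARIANTS:
        raise ValueError(f"unknown model variant {name!r}")
    return name


@dataclass
class FactorModel:
    """Latent factors for genes (U, m x D) and diseases (V, n x D)."""

    U: np.ndarray
    V: np.ndarray
    vartheta: float = 1e-4

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must be 2-D with equal latent dimension")
        if not self.vartheta > 0:
            raise ValueError("vartheta must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.U.shape[0], self.V.shape[0])

    @property
    def latent_dim(self) -> int:
        return self.U.shape[1]

    def distance(self, i: int, j: int) -> float:
        return pair_distance(self.U[i], self.V[j], self.vartheta)

    def score(self, i: int, j: int) -> float:
        return float(math.exp(-self.distance(i, j)))

    def score_matrix(self) -> np.ndarray:
        """Link probability for every (gene, disease) pair."""
        f = 0.5 * cdist(self.U, self.V, "sqeuclidean") + self.vartheta
        return np.exp(-f)


@dataclass(frozen=True)
class TrainConfig:
    variant: str = "basic"
    latent_dim: int = 10
    alpha: float = 0.0
    beta: float = 0.0
    vartheta: float = 1e-4
    learning_rate: float = 0.05
    lr_decay: float = 0.95
    epochs: int = 200
    init_scale: float = 0.1
    seed: int = 0
    tolerance: float = 1e-6
    full_batch: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", canonical_variant(self.variant))
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.init_scale > 0:
            raise ValueError("init_scale must be positive")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if not self.vartheta > 0:
            raise ValueError("vartheta must be positive")


@dataclass(frozen=True)
class ObjectiveValue:
    """Objective decomposition; regularizer contributions are <= 0."""

    total: float
    likelihood_term: float
    gene_reg_term: float = 0.0
    disease_reg_term: float = 0.0


# ---------------------------------------------------------------------------
# Probability map and likelihood
# ---------------------------------------------------------------------------


def pair_distance(u: np.ndarray, v: np.ndarray, vartheta: float = 1e-4) -> float:
    """Half squared Euclidean distance plus the positive offset vartheta."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    d = u - v
    return float(0.5 * d @ d + vartheta)


def association_probability(f) -> tuple[np.ndarray, np.ndarray]:
    """(P(Y=1), P(Y=0)) = (exp(-f), 1 - exp(-f)); the two sum to 1 exactly."""
    f = np.asarray(f, dtype=np.float64)
    p1 = np.exp(-f)
    return p1, 1.0 - p1


def _pair_f(model: FactorModel, pairs: LabeledPairSet) -> np.ndarray:
    diff = model.U[pairs.gene_idx] - model.V[pairs.disease_idx]
    return 0.5 * np.einsum("td,td->t", diff, diff) + model.vartheta


def log_likelihood(model: FactorModel, pairs: LabeledPairSet) -> float:
    """Bernoulli log-likelihood of the labeled pairs; 0 for an empty set."""
    if len(pairs) == 0:
        return 0.0
    f = _pair_f(model, pairs)
    y = pairs.labels.astype(np.float64)
    # log(1 - e^-f) computed via expm1 for small f
    log_p0 = np.log(-np.expm1(-f))
    return float(np.sum((1.0 - y) * log_p0 - y * f))


def _pair_coefficients(f: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-pair scalar multiplying (V_j - U_i) in the likelihood gradient."""
    coef = np.ones_like(f)
    neg = y == 0
    p0 = -np.expm1(-f[neg])
    coef[neg] = 1.0 - 1.0 / p0
    return coef


def gradient_likelihood(
    model: FactorModel, pairs: LabeledPairSet
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the log-likelihood with respect to U and V."""
    dU = np.zeros_like(model.U)
    dV = np.zeros_like(model.V)
    if len(pairs) == 0:
        return dU, dV
    f = _pair_f(model, pairs)
    coef = _pair_coefficients(f, pairs.labels.astype(np.float64))
    diff = model.V[pairs.disease_idx] - model.U[pairs.gene_idx]
    contrib = coef[:, None] * diff
    np.add.at(dU, pairs.gene_idx, contrib)
    np.add.at(dV, pairs.disease_idx, -contrib)
    return dU, dV


# ---------------------------------------------------------------------------
# Graph regularizers
# ---------------------------------------------------------------------------


def _neighbor_arrays(
    nbrs: dict[int, tuple[tuple[int, float], ...]]
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    return {
        i: (
            np.array([g for g, _ in items], dtype=np.int64),
            np.array([s for _, s in items], dtype=np.float64),
        )
        for i, items in nbrs.items()
        if items
    }


def _centroid_penalty(
    X: np.ndarray,
    nbrs: dict[int, tuple[tuple[int, float], ...]],
    weight: float,
    want_grad: bool,
) -> tuple[float, np.ndarray | None]:
    """(weight/2) * sum_i ||X_i - weighted neighbor centroid||^2.

    Entities with no neighbors or zero similarity mass contribute nothing.
    The gradient accounts for X_i appearing both as a center and inside
    other entities' centroids.
    """
    value = 0.0
    grad = np.zeros_like(X) if want_grad else None
    if weight == 0.0:
        return value, grad
    for i, (idx, s) in _neighbor_arrays(nbrs).items():
        mass = s.sum()
        if mass <= 0:
            continue
        centroid = (s[:, None] * X[idx]).sum(axis=0) / mass
        d = X[i] - centroid
        value += 0.5 * weight * float(d @ d)
        if want_grad:
            grad[i] += weight * d
            grad[idx] -= weight * np.outer(s / mass, d)
    return value, grad


def _pairwise_penalty(
    X: np.ndarray,
    nbrs: dict[int, tuple[tuple[int, float], ...]],
    weight: float,
    want_grad: bool,
) -> tuple[float, np.ndarray | None]:
    """(weight/2) * sum_i sum_{g in N(i)} s_ig ||X_i - X_g||^2.

    The sum runs over directed neighbor pairs exactly as stored; the
    gradient therefore hits both endpoints of every directed term.
    """
    value = 0.0
    grad = np.zeros_like(X) if want_grad else None
    if weight == 0.0:
        return value, grad
    for i, (idx, s) in _neighbor_arrays(nbrs).items():
        diffs = X[i] - X[idx]
        value += 0.5 * weight * float(s @ np.einsum("gd,gd->g", diffs, diffs))
        if want_grad:
            weighted = weight * s[:, None] * diffs
            grad[i] += weighted.sum(axis=0)
            grad[idx] -= weighted
    return value, grad


_PENALTIES = {"centroid": _centroid_penalty, "pairwise": _pairwise_penalty}


def objective_value(
    model: FactorModel,
    pairs: LabeledPairSet,
    neighbors: NeighborSets | None = None,
    *,
    variant: str = "basic",
    alpha: float = 0.0,
    beta: float = 0.0,
) -> ObjectiveValue:
    """Full objective (likelihood minus regularization penalties)."""
    variant = canonical_variant(variant)
    lik = log_likelihood(model, pairs)
    if variant == "basic" or neighbors is None:
        return ObjectiveValue(total=lik, likelihood_term=lik)
    penalty = _PENALTIES[variant]
    gene_pen, _ = penalty(model.U, neighbors.gene_neighbors, alpha, False)
    dis_pen, _ = penalty(model.V, neighbors.disease_neighbors, beta, False)
    return ObjectiveValue(
        total=lik - gene_pen - dis_pen,
        likelihood_term=lik,
        gene_reg_term=-gene_pen,
        disease_reg_term=-dis_pen,
    )


def gradients(
    model: FactorModel,
    pairs: LabeledPairSet,
    neighbors: NeighborSets | None = None,
    *,
    variant: str = "basic",
    alpha: float = 0.0,
    beta: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic ascent gradient of :func:`objective_value`."""
    variant = canonical_variant(variant)
    dU, dV = gradient_likelihood(model, pairs)
    if variant != "basic" and neighbors is not None:
        penalty = _PENALTIES[variant]
        _, gU = penalty(model.U, neighbors.gene_neighbors, alpha, True)
        _, gV = penalty(model.V, neighbors.disease_neighbors, beta, True)
        dU -= gU
        dV -= gV
    return dU, dV


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(
    pairs: LabeledPairSet,
    shape: tuple[int, int],
    cfg: TrainConfig,
    neighbors: NeighborSets | None = None,
) -> tuple[FactorModel, list[ObjectiveValue]]:
    """Stochastic gradient ascent on the configured objective.

    Factors start from a seeded zero-mean normal. Each epoch visits all
    training pairs in a freshly shuffled order; per pair the touched rows
    (and, for the regularized variants, their neighbor rows) are updated
    with step ``learning_rate * lr_decay**epoch``. Training stops early
    when the full objective improves by less than ``tolerance``. A
    ``full_batch`` mode applies the complete gradient once per epoch and
    exists for ascent-property checks.

    Returns the model and a per-epoch objective trace.

    Raises ``FloatingPointError`` when the objective diverges; try a
    smaller ``learning_rate``.
    """
    m, n = shape
    variant = canonical_variant(cfg.variant)
    rng = np.random.default_rng(cfg.seed)
    model = FactorModel(
        U=rng.normal(0.0, cfg.init_scale, size=(m, cfg.latent_dim)),
        V=rng.normal(0.0, cfg.init_scale, size=(n, cfg.latent_dim)),
        vartheta=cfg.vartheta,
    )
    gnbr = (
        _neighbor_arrays(neighbors.gene_neighbors)
        if neighbors is not None and variant != "basic"
        else {}
    )
    dnbr = (
        _neighbor_arrays(neighbors.disease_neighbors)
        if neighbors is not None and variant != "basic"
        else {}
    )

    gi, dj = pairs.gene_idx, pairs.disease_idx
    y = pairs.labels
    U, V = model.U, model.V
    vartheta = model.vartheta
    alpha, beta = cfg.alpha, cfg.beta

    trace: list[ObjectiveValue] = []
    previous = -np.inf
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * cfg.lr_decay**epoch
        if cfg.full_batch:
            dU, dV = gradients(
                model, pairs, neighbors, variant=variant, alpha=alpha, beta=beta
            )
            U += lr * dU
            V += lr * dV
        else:
            for t in rng.permutation(len(pairs)):
                i, j = gi[t], dj[t]
                ui, vj = U[i], V[j]
                diff = vj - ui
                f = 0.5 * float(diff @ diff) + vartheta
                if y[t]:
                    coef = 1.0
                else:
                    coef = 1.0 - 1.0 / (-math.expm1(-f))
                step = lr * coef
                U[i] = ui + step * diff
                V[j] = vj - step * diff
                if variant == "pairwise":
                    if alpha and i in gnbr:
                        idx, s = gnbr[i]
                        diffs = U[i] - U[idx]
                        weighted = (lr * alpha) * s[:, None] * diffs
                        U[i] -= weighted.sum(axis=0)
                        U[idx] += weighted
                    if beta and j in dnbr:
                        idx, s = dnbr[j]
                        diffs = V[j] - V[idx]
                        weighted = (lr * beta) * s[:, None] * diffs
                        V[j] -= weighted.sum(axis=0)
                        V[idx] += weighted
                elif variant == "centroid":
                    if alpha and i in gnbr:
                        idx, s = gnbr[i]
                        mass = s.sum()
                        centroid = (s[:, None] * U[idx]).sum(axis=0) / mass
                        d = U[i] - centroid
                        U[i] -= lr * alpha * d
                        U[idx] += lr * alpha * np.outer(s / mass, d)
                    if beta and j in dnbr:
                        idx, s = dnbr[j]
                        mass = s.sum()
                        centroid = (s[:, None] * V[idx]).sum(axis=0) / mass
                        d = V[j] - centroid
                        V[j] -= lr * beta * d
                        V[idx] += lr * beta * np.outer(s / mass, d)

        obj = objective_value(
            model, pairs, neighbors, variant=variant, alpha=alpha, beta=beta
        )
        if not math.isfinite(obj.total):
            raise FloatingPointError(
                "objective diverged (NaN/inf); try a smaller learning_rate"
            )
        trace.append(obj)
        if epoch > 0 and obj.total - previous < cfg.tolerance:
            break
        previous = obj.total
    return model, trace


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def rank_genes(
    model: FactorModel,
    disease: int,
    candidates: Sequence[int],
    gene_ids: Sequence[str] | None = None,
) -> list[tuple[int | str, float]]:
    """Candidates ordered by descending link probability.

    Ties break on the gene identifier (or the index when no identifiers
    are supplied). Returns (gene, score) pairs.
    """
    cand = np.asarray(candidates, dtype=np.int64)
    diff = model.U[cand] - model.V[disease]
    f = 0.5 * np.einsum("td,td->t", diff, diff) + model.vartheta
    scores = np.exp(-f)
    keys = [gene_ids[c] for c in cand] if gene_ids is not None else cand.tolist()
    order = sorted(range(len(cand)), key=lambda t: (-scores[t], keys[t]))
    return [(keys[t], float(scores[t])) for t in order]


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    model: FactorModel,
    cfg: TrainConfig | None = None,
    gene_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> None:
    payload = {
        "U": model.U.tolist(),
        "V": model.V.tolist(),
        "vartheta": model.vartheta,
        "config": asdict(cfg) if cfg is not None else None,
        "gene_ids": list(gene_ids) if gene_ids is not None else None,
        "disease_ids": list(disease_ids) if disease_ids is not None else None,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_checkpoint(
    path: str | Path,
) -> tuple[FactorModel, TrainConfig | None, list[str] | None, list[str] | None]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    model = FactorModel(
        U=np.array(payload["U"], dtype=np.float64),
        V=np.array(payload["V"], dtype=np.float64),
        vartheta=payload["vartheta"],
    )
    cfg = TrainConfig(**payload["config"]) if payload["config"] else None
    return model, cfg, payload["gene_ids"], payload["disease_ids"]
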