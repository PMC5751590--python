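"""Truncated Katz scoring over the heterogeneous gene-disease network.

Scores count damped walks of length up to three from each gene to each
disease through the gene-gene, gene-disease, and disease-disease layers:
a length-L walk contributes ``beta**L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network_io import AssociationMatrix, SimilarityMatrix

__all__ = ["KatzConfig", "katz_scores"]


@dataclass(frozen=True)
class KatzConfig:
    """``beta`` damps long walks; small values emphasize short paths."""

    beta: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta < 1.0):
            raise ValueError("beta must lie in [0, 1)")


def _dense(layer) -> np.ndarray:
    if isinstance(layer, SimilarityMatrix):
        return layer.toarray()
    if isinstance(layer, AssociationMatrix):
        return layer.toarray().astype(np.float64)
    if sp.issparse(layer):
        return np.asarray(layer.todense(), dtype=np.float64)
    return np.asarray(layer, dtype=np.float64)


def katz_scores(
    gene_adj,
    gene_disease,
    disease_adj,
    config: KatzConfig = KatzConfig(),
) -> np.ndarray:
    """Damped count of heterogeneous walks of length <= 3, gene to disease.

    With G the gene-gene matrix, P the gene-disease matrix, and Q the
    disease-disease matrix::

        S = b*P + b^2*(G P + P Q) + b^3*(P P^T P + G^2 P + G P Q + P Q^2)

    which equals the gene-disease block of ``sum_L b^L A^L`` for the block
    adjacency ``A = [[G, P], [P^T, Q]]`` truncated at L = 3.
    """
    G = _dense(gene_adj)
    P = _dense(gene_disease)
    Q = _dense(disease_adj)
    m, n = P.shape
    if G.shape != (m, m) or Q.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: gene_adj {G.shape}, gene_disease {P.shape}, "
            f"disease_adj {Q.shape}"
        )
    b = config.beta
    GP = G @ P
    PQ = P @ Q
    return (
        b * P
        + b**2 * (GP + PQ)
        + b**3 * (P @ (P.T @ P) + G @ GP + GP @ Q + PQ @ Q)
    )
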