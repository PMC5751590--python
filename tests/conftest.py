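from __future__ import annotations

import numpy as np
import pytest

from gdprio.negative_sampling import LabeledPairSet
from gdprio.network_io import IndexMap, OrthologProfileSet
from gdprio.similarity import NeighborSets


@pytest.fixture
def tiny_profiles() -> OrthologProfileSet:
    """Three genes over three nonhuman diseases: {dA,dB}, {dA,dC}, {dC}."""
    return OrthologProfileSet.from_id_pairs(
        [
            ("g1", "dA"),
            ("g1", "dB"),
            ("g2", "dA"),
            ("g2", "dC"),
            ("g3", "dC"),
        ]
    )


def random_instance(seed: int, max_m: int = 6, max_n: int = 6, max_d: int = 4):
    """Small random model + labeled pairs + neighbor sets for gradient checks."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, max_m + 1))
    n = int(rng.integers(2, max_n + 1))
    d = int(rng.integers(1, max_d + 1))
    U = rng.normal(0, 0.7, size=(m, d))
    V = rng.normal(0, 0.7, size=(n, d))
    pair_idx = [(i, j) for i in range(m) for j in range(n)]
    keep = rng.random(len(pair_idx)) < 0.6
    triples = [
        (i, j, int(rng.random() < 0.4))
        for (i, j), kp in zip(pair_idx, keep)
        if kp
    ]
    if not triples:
        triples = [(0, 0, 1)]
    pairs = LabeledPairSet.from_triples(triples)

    def random_neighbors(count: int):
        out = {}
        for i in range(count):
            others = [g for g in range(count) if g != i]
            rng.shuffle(others)
            chosen = others[: int(rng.integers(0, min(3, len(others)) + 1))]
            if chosen:
                out[i] = tuple(
                    (g, float(rng.uniform(0.1, 1.0))) for g in sorted(chosen)
                )
        return out

    neighbors = NeighborSets(
        gene_neighbors=random_neighbors(m),
        disease_neighbors=random_neighbors(n),
    )
    return U, V, pairs, neighbors
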