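from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import numerical_gradient
from conftest import random_instance
from gdprio import factor_model as fm
from gdprio.negative_sampling import LabeledPairSet
from gdprio.similarity import NeighborSets

VARIANT_PARAMS = [("basic", 0.0, 0.0), ("centroid", 0.7, 0.4), ("pairwise", 0.7, 0.4)]


class TestPairDistance:
    def test_coincident_vectors_hit_floor(self):
        u = np.array([0.3, -0.2])
        assert fm.pair_distance(u, u) == pytest.approx(1e-4)

    def test_half_squared_distance(self):
        assert fm.pair_distance(
            np.array([1.0, 0.0]), np.array([0.0, 0.0]), vartheta=1e-12
        ) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        got = fm.pair_distance(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert got == pytest.approx(4.0001)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fm.pair_distance(np.zeros(2), np.zeros(3))


class TestAssociationProbability:
    def test_half_at_log_two(self):
        p1, p0 = fm.association_probability(math.log(2.0))
        assert p1 == pytest.approx(0.5)
        assert p0 == pytest.approx(0.5)

    def test_large_distance_is_nonlink(self):
        _, p0 = fm.association_probability(50.0)
        assert p0 == pytest.approx(1.0)

    @given(st.floats(min_value=1e-4, max_value=100.0))
    @settings(max_examples=200, deadline=None)
    def test_conservation_exact(self, f):
        p1, p0 = fm.association_probability(f)
        assert float(p1) + float(p0) == 1.0
        assert 0.0 < p1 <= math.exp(-1e-4)


class TestLogLikelihood:
    def test_single_positive_at_floor(self):
        model = fm.FactorModel(U=np.array([[0.5, 0.5]]), V=np.array([[0.5, 0.5]]))
        pairs = LabeledPairSet.from_triples([(0, 0, 1)])
        assert fm.log_likelihood(model, pairs) == pytest.approx(-1e-4)

    def test_single_negative_closed_form(self):
        # distance chosen so f = ln 2: ||u - v||^2 / 2 = ln 2 - vartheta
        gap = math.sqrt(2 * (math.log(2.0) - 1e-4))
        model = fm.FactorModel(U=np.array([[gap]]), V=np.array([[0.0]]))
        pairs = LabeledPairSet.from_triples([(0, 0, 0)])
        assert fm.log_likelihood(model, pairs) == pytest.approx(-math.log(2.0))

    def test_empty_set_is_zero(self):
        model = fm.FactorModel(U=np.zeros((2, 2)), V=np.zeros((2, 2)))
        pairs = LabeledPairSet.from_triples([])
        assert fm.log_likelihood(model, pairs) == 0.0

    def test_never_positive(self):
        for seed in range(10):
            U, V, pairs, _ = random_instance(seed)
            model = fm.FactorModel(U=U, V=V)
            assert fm.log_likelihood(model, pairs) <= 0.0


class TestGradientLikelihood:
    def test_coincident_positive_contributes_zero(self):
        model = fm.FactorModel(U=np.array([[1.0, 2.0]]), V=np.array([[1.0, 2.0]]))
        pairs = LabeledPairSet.from_triples([(0, 0, 1)])
        dU, dV = fm.gradient_likelihood(model, pairs)
        np.testing.assert_array_equal(dU, 0.0)
        np.testing.assert_array_equal(dV, 0.0)

    def test_distant_negative_contributes_nothing(self):
        model = fm.FactorModel(U=np.array([[100.0]]), V=np.array([[0.0]]))
        pairs = LabeledPairSet.from_triples([(0, 0, 0)])
        dU, dV = fm.gradient_likelihood(model, pairs)
        assert abs(dU).max() == pytest.approx(0.0, abs=1e-8)

    def test_finite_difference_agreement(self):
        U, V, pairs, _ = random_instance(7)
        model = fm.FactorModel(U=U.copy(), V=V.copy())
        dU, dV = fm.gradient_likelihood(model, pairs)
        numU = numerical_gradient(
            lambda X: fm.log_likelihood(fm.FactorModel(U=X, V=V), pairs), U.copy()
        )
        numV = numerical_gradient(
            lambda X: fm.log_likelihood(fm.FactorModel(U=U, V=X), pairs), V.copy()
        )
        np.testing.assert_allclose(dU, numU, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(dV, numV, rtol=1e-5, atol=1e-7)


class TestRegularizedObjectives:
    def test_identical_rows_nullify_both_regularizers(self):
        U = np.tile([0.4, -0.1], (3, 1))
        V = np.tile([0.2, 0.3], (2, 1))
        model = fm.FactorModel(U=U, V=V)
        pairs = LabeledPairSet.from_triples([(0, 0, 1), (1, 1, 0)])
        nbrs = NeighborSets(
            gene_neighbors={0: ((1, 0.5), (2, 0.8)), 1: ((0, 0.5),)},
            disease_neighbors={0: ((1, 1.0),)},
        )
        for variant in ("centroid", "pairwise"):
            obj = fm.objective_value(
                model, pairs, nbrs, variant=variant, alpha=1.0, beta=1.0
            )
            assert obj.gene_reg_term == 0.0
            assert obj.disease_reg_term == 0.0
            assert obj.total == pytest.approx(obj.likelihood_term)

    def test_centroid_hand_value(self):
        # one neighbor with s=1: centroid = neighbor; alpha/2 * ||(1,0)||^2
        U = np.array([[1.0, 0.0], [0.0, 0.0]])
        V = np.zeros((1, 2))
        model = fm.FactorModel(U=U, V=V)
        pairs = LabeledPairSet.from_triples([])
        nbrs = NeighborSets(gene_neighbors={0: ((1, 1.0),)})
        obj = fm.objective_value(
            model, pairs, nbrs, variant="centroid", alpha=2.0, beta=1.0
        )
        assert obj.gene_reg_term == pytest.approx(-1.0)

    def test_pairwise_hand_value(self):
        U = np.array([[2.0, 0.0], [0.0, 0.0]])
        V = np.zeros((1, 2))
        model = fm.FactorModel(U=U, V=V)
        pairs = LabeledPairSet.from_triples([])
        nbrs = NeighborSets(gene_neighbors={0: ((1, 0.5),)})
        obj = fm.objective_value(
            model, pairs, nbrs, variant="pairwise", alpha=1.0, beta=1.0
        )
        assert obj.gene_reg_term == pytest.approx(-(1.0 / 2.0) * 0.5 * 4.0)

    def test_empty_neighbors_reduce_to_likelihood(self):
        U, V, pairs, _ = random_instance(3)
        model = fm.FactorModel(U=U, V=V)
        empty = NeighborSets()
        for variant in ("centroid", "pairwise"):
            obj = fm.objective_value(
                model, pairs, empty, variant=variant, alpha=2.0, beta=2.0
            )
            assert obj.total == pytest.approx(fm.log_likelihood(model, pairs))
            dU, dV = fm.gradients(
                model, pairs, empty, variant=variant, alpha=2.0, beta=2.0
            )
            lU, lV = fm.gradient_likelihood(model, pairs)
            np.testing.assert_array_equal(dU, lU)
            np.testing.assert_array_equal(dV, lV)

    def test_objective_decomposition_sums(self):
        U, V, pairs, nbrs = random_instance(5)
        model = fm.FactorModel(U=U, V=V)
        obj = fm.objective_value(
            model, pairs, nbrs, variant="pairwise", alpha=0.3, beta=0.8
        )
        assert obj.total == pytest.approx(
            obj.likelihood_term + obj.gene_reg_term + obj.disease_reg_term
        )
        assert obj.gene_reg_term <= 0.0 and obj.disease_reg_term <= 0.0


@pytest.mark.parametrize("variant,alpha,beta", VARIANT_PARAMS)
class TestGradientFiniteDifferences:
    def test_agreement_on_random_instances(self, variant, alpha, beta):
        for seed in range(10):
            U, V, pairs, nbrs = random_instance(seed)
            model = fm.FactorModel(U=U.copy(), V=V.copy())
            dU, dV = fm.gradients(
                model, pairs, nbrs, variant=variant, alpha=alpha, beta=beta
            )

            def obj_u(X):
                return fm.objective_value(
                    fm.FactorModel(U=X, V=V), pairs, nbrs,
                    variant=variant, alpha=alpha, beta=beta,
                ).total

            def obj_v(X):
                return fm.objective_value(
                    fm.FactorModel(U=U, V=X), pairs, nbrs,
                    variant=variant, alpha=alpha, beta=beta,
                ).total

            np.testing.assert_allclose(
                dU, numerical_gradient(obj_u, U.copy()), rtol=1e-5, atol=1e-7
            )
            np.testing.assert_allclose(
                dV, numerical_gradient(obj_v, V.copy()), rtol=1e-5, atol=1e-7
            )


class TestTrain:
    def test_seeded_runs_bitwise_identical(self):
        _, _, pairs, nbrs = random_instance(11)
        m = int(pairs.gene_idx.max()) + 1
        n = int(pairs.disease_idx.max()) + 1
        cfg = fm.TrainConfig(variant="pairwise", latent_dim=3, alpha=0.3,
                             beta=0.3, epochs=20, seed=5)
        a, _ = fm.train(pairs, (m, n), cfg, nbrs)
        b, _ = fm.train(pairs, (m, n), cfg, nbrs)
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.V, b.V)

    def test_single_positive_pair_distance_shrinks(self):
        pairs = LabeledPairSet.from_triples([(0, 0, 1)])
        cfg = fm.TrainConfig(latent_dim=2, epochs=60, seed=2, learning_rate=0.2,
                             lr_decay=1.0, tolerance=1e-12)
        model, trace = fm.train(pairs, (1, 1), cfg)
        # gradient ascent on -f converges toward the floor vartheta
        assert model.distance(0, 0) < 0.01
        totals = [t.total for t in trace]
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    @pytest.mark.parametrize("variant,alpha,beta", VARIANT_PARAMS)
    def test_full_batch_small_step_is_monotone(self, variant, alpha, beta):
        _, _, pairs, nbrs = random_instance(23)
        m = int(pairs.gene_idx.max()) + 1
        n = int(pairs.disease_idx.max()) + 1
        cfg = fm.TrainConfig(
            variant=variant, latent_dim=3, alpha=alpha, beta=beta,
            epochs=50, seed=9, learning_rate=1e-3, lr_decay=1.0,
            full_batch=True, tolerance=1e-15,
        )
        _, trace = fm.train(pairs, (m, n), cfg, nbrs)
        totals = [t.total for t in trace]
        assert all(b >= a - 1e-10 for a, b in zip(totals, totals[1:]))

    def test_divergence_raises_helpful_error(self):
        pairs = LabeledPairSet.from_triples(
            [(0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 1)]
        )
        cfg = fm.TrainConfig(latent_dim=2, epochs=200, seed=0,
                             learning_rate=1e150, lr_decay=1.0)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="learning_rate"):
                fm.train(pairs, (2, 2), cfg)

    def test_early_stop_on_tolerance(self):
        _, _, pairs, _ = random_instance(31)
        m = int(pairs.gene_idx.max()) + 1
        n = int(pairs.disease_idx.max()) + 1
        cfg = fm.TrainConfig(latent_dim=2, epochs=500, seed=1, tolerance=1e-2)
        _, trace = fm.train(pairs, (m, n), cfg)
        assert len(trace) < 500

    def test_variant_aliases_accepted(self):
        cfg = fm.TrainConfig(variant="model2")
        assert cfg.variant == "pairwise"
        with pytest.raises(ValueError):
            fm.TrainConfig(variant="model3")


class TestColdStart:
    def test_unseen_disease_gets_finite_scores(self):
        pairs = LabeledPairSet.from_triples([(0, 0, 1), (1, 0, 0)])
        cfg = fm.TrainConfig(latent_dim=2, epochs=10, seed=0)
        model, _ = fm.train(pairs, (2, 3), cfg)  # diseases 1, 2 never trained
        scores = model.score_matrix()
        assert np.all(np.isfinite(scores))
        assert np.all(scores > 0)

    def test_pairwise_regularizer_pulls_cold_disease_to_neighbors(self):
        # disease 2 has no pairs; its neighbors 0 and 1 do
        pairs = LabeledPairSet.from_triples([(0, 0, 1), (1, 1, 1)])
        # symmetric neighborhood, as produced from a symmetric similarity
        nbrs = NeighborSets(
            disease_neighbors={
                2: ((0, 1.0), (1, 1.0)),
                0: ((2, 1.0),),
                1: ((2, 1.0),),
            },
        )
        cfg = fm.TrainConfig(
            variant="pairwise", latent_dim=2, alpha=0.0, beta=1.0,
            epochs=1, seed=4, learning_rate=0.05, tolerance=1e-15,
        )
        model1, _ = fm.train(pairs, (2, 3), cfg, nbrs)
        cfg30 = fm.TrainConfig(
            variant="pairwise", latent_dim=2, alpha=0.0, beta=1.0,
            epochs=30, seed=4, learning_rate=0.05, tolerance=1e-15,
        )
        model30, _ = fm.train(pairs, (2, 3), cfg30, nbrs)

        def dist_to_neighbor_mean(model):
            mean = model.V[[0, 1]].mean(axis=0)
            return np.linalg.norm(model.V[2] - mean)

        assert dist_to_neighbor_mean(model30) < dist_to_neighbor_mean(model1)


class TestRankGenes:
    def test_coincident_candidate_ranks_first(self):
        V = np.array([[0.0, 0.0]])
        U = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = fm.FactorModel(U=U, V=V)
        ranked = fm.rank_genes(model, 0, [0, 1])
        assert ranked[0][0] == 0
        assert ranked[0][1] == pytest.approx(math.exp(-1e-4))

    def test_order_follows_distance(self):
        U = np.array([[1.0, 0.0], [2.0, 0.0]])
        V = np.array([[0.0, 0.0]])
        model = fm.FactorModel(U=U, V=V)
        ranked = fm.rank_genes(model, 0, [1, 0])
        assert [g for g, _ in ranked] == [0, 1]

    def test_identifier_tie_break(self):
        U = np.array([[1.0, 0.0], [-1.0, 0.0]])
        V = np.array([[0.0, 0.0]])
        model = fm.FactorModel(U=U, V=V)
        ranked = fm.rank_genes(model, 0, [1, 0], gene_ids=["gB", "gA"])
        assert [g for g, _ in ranked] == ["gA", "gB"]


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        _, _, pairs, _ = random_instance(2)
        m = int(pairs.gene_idx.max()) + 1
        n = int(pairs.disease_idx.max()) + 1
        cfg = fm.TrainConfig(latent_dim=3, epochs=5, seed=8)
        model, _ = fm.train(pairs, (m, n), cfg)
        path = tmp_path / "model.json"
        fm.save_checkpoint(path, model, cfg, gene_ids=[f"g{i}" for i in range(m)],
                           disease_ids=[f"d{j}" for j in range(n)])
        loaded, loaded_cfg, gene_ids, disease_ids = fm.load_checkpoint(path)
        np.testing.assert_array_equal(loaded.U, model.U)
        np.testing.assert_array_equal(loaded.V, model.V)
        assert loaded_cfg == cfg
        assert gene_ids == [f"g{i}" for i in range(m)]
        assert disease_ids == [f"d{j}" for j in range(n)]
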