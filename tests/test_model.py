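"""NRLMF core: probabilities, neighborhoods, objective/gradients against
loop-based and finite-difference oracles, training descent/determinism,
and cold-start smoothing."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

import oracles
from conftest import random_interactions, random_similarity
from lpinrlmf import (
    Hyperparameters,
    InputError,
    InteractionMatrix,
    ModelError,
    SimilarityMatrix,
    build_neighborhood,
    fit,
    generate_planted_instance,
    gradients,
    init_factors,
    interaction_probability,
    objective,
    predict,
    smoothed_latent_vectors,
)


class TestInteractionProbability:
    def test_zero_logits_give_half(self):
        P = interaction_probability(np.zeros((3, 2)), np.zeros((4, 2)))
        assert np.allclose(P, 0.5)

    def test_scalar_logistic_value(self):
        P = interaction_probability(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]))
        assert P[0, 0] == pytest.approx(np.exp(2) / (1 + np.exp(2)), rel=1e-12)

    def test_large_logits_saturate_without_overflow(self):
        U = np.array([[1000.0]])
        V = np.array([[1.0], [-10.0]])
        P = interaction_probability(U, V)
        assert np.isfinite(P).all()
        assert 0 < P[0, 1] < P[0, 0] < 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            interaction_probability(np.zeros((3, 2)), np.zeros((4, 3)))


class TestNeighborhood:
    def test_tie_breaking_selects_lowest_index(self):
        eps = 0.3
        S = SimilarityMatrix(
            ids=["a", "b", "c"], values=np.eye(3) * (1 - eps) + eps
        )
        g = build_neighborhood(S, K=1)
        assert g.A[0, 1] == eps and g.A[0, 2] == 0
        assert g.A[1, 0] == eps and g.A[2, 0] == eps

    def test_row_support_and_weights(self, rng):
        S = random_similarity(8, rng)
        g = build_neighborhood(S, K=3)
        for i in range(8):
            nz = np.flatnonzero(g.A[i])
            assert len(nz) == 3 and i not in nz
            assert np.all(g.A[i, nz] == S.values[i, nz])

    def test_laplacian_quadratic_form_matches_double_sum(self, rng):
        S = random_similarity(8, rng)
        g = build_neighborhood(S, K=3)
        U = rng.normal(size=(8, 4))
        quad = float(np.trace(U.T @ g.L @ U))
        assert quad == pytest.approx(oracles.laplacian_quadratic_form(g.A, U), abs=1e-10)

    def test_laplacian_symmetric_psd(self, rng):
        S = random_similarity(10, rng)
        g = build_neighborhood(S, K=4)
        assert np.allclose(g.L, g.L.T)
        assert np.linalg.eigvalsh(g.L).min() >= -1e-10

    @pytest.mark.parametrize("K", [0, 3])
    def test_bad_K_rejected(self, K, rng):
        with pytest.raises(InputError):
            build_neighborhood(random_similarity(3, rng), K=K)


def _random_setup(rng, m=6, n=4, r=2, K1=2):
    Y = random_interactions(m, n, 0.3, rng)
    S_l, S_p = random_similarity(m, rng), random_similarity(n, rng)
    gl, gp = build_neighborhood(S_l, K1), build_neighborhood(S_p, K1)
    U = rng.normal(size=(m, r))
    V = rng.normal(size=(n, r))
    return Y, S_l, S_p, gl, gp, U, V


class TestObjective:
    def test_zero_factors_closed_form(self, rng):
        Y, _, _, gl, gp, U, V = _random_setup(rng)
        hp = Hyperparameters(r=2, c=5.0, K1=2)
        val = objective(np.zeros_like(U), np.zeros_like(V), Y, gl, gp, hp)
        expected = np.log(2.0) * (1 + (hp.c - 1) * Y.Y).sum()
        assert val == pytest.approx(expected, rel=1e-12)

    def test_reduces_to_plain_lmf_when_unregularized(self, rng):
        Y, _, _, gl, gp, U, V = _random_setup(rng)
        hp = Hyperparameters(r=2, c=1.0, lambda_l=0.3, lambda_p=0.7,
                             alpha=0.0, beta=0.0, K1=2)
        got = objective(U, V, Y, gl, gp, hp)
        want = oracles.plain_lmf_objective(U, V, Y.Y, hp.c, 0.3, 0.7)
        assert got == pytest.approx(want, abs=1e-9)

    def test_matches_literal_loop_transcription(self, rng):
        Y, _, _, gl, gp, U, V = _random_setup(rng)
        hp = Hyperparameters(r=2, c=4.0, lambda_l=0.2, lambda_p=0.4,
                             alpha=0.3, beta=0.6, K1=2)
        got = objective(U, V, Y, gl, gp, hp)
        want = oracles.full_objective_loops(
            U, V, Y.Y, gl.A, gp.A, hp.c, 0.2, 0.4, 0.3, 0.6
        )
        assert got == pytest.approx(want, rel=1e-10)


class TestGradients:
    def test_match_finite_differences(self, rng):
        for _ in range(3):
            Y, _, _, gl, gp, U, V = _random_setup(rng, m=8, n=5, r=3)
            hp = Hyperparameters(r=3, c=5.0, lambda_l=0.5, lambda_p=0.5,
                                 alpha=0.2, beta=0.3, K1=2)
            dU, dV = gradients(U, V, Y, gl, gp, hp)
            fU, fV = oracles.finite_difference_gradients(
                lambda Uc, Vc: objective(Uc, Vc, Y, gl, gp, hp), U, V
            )
            scale = max(np.abs(fU).max(), np.abs(fV).max())
            assert np.abs(dU - fU).max() / scale < 1e-5
            assert np.abs(dV - fV).max() / scale < 1e-5

    def test_zero_Y_reduction(self, rng):
        Y, _, _, gl, gp, U, V = _random_setup(rng)
        Y = InteractionMatrix(Y.lncrna_ids, Y.protein_ids, np.zeros(Y.shape))
        hp = Hyperparameters(r=2, c=5.0, lambda_l=0.5, alpha=0.0, beta=0.0, K1=2)
        dU, _ = gradients(U, V, Y, gl, gp, hp)
        from scipy.special import expit

        expected = expit(U @ V.T) @ V + 0.5 * U
        assert np.allclose(dU, expected, atol=1e-12)

    def test_matches_plain_lmf_gradient_oracle(self, rng):
        Y, _, _, gl, gp, U, V = _random_setup(rng)
        hp = Hyperparameters(r=2, c=1.0, lambda_l=0.3, lambda_p=0.7,
                             alpha=0.0, beta=0.0, K1=2)
        dU, dV = gradients(U, V, Y, gl, gp, hp)
        fU, fV = oracles.plain_lmf_gradients(U, V, Y.Y, hp.c, 0.3, 0.7)
        assert np.allclose(dU, fU, atol=1e-9)
        assert np.allclose(dV, fV, atol=1e-9)


class TestInitFactors:
    def test_deterministic(self):
        assert all(
            np.array_equal(a, b)
            for a, b in zip(init_factors(5, 4, 3, 42), init_factors(5, 4, 3, 42))
        )

    def test_variance_is_one_over_r(self):
        r = 10000
        U, V = init_factors(12, 8, r, seed=0)
        assert np.var(U) == pytest.approx(1.0 / r, rel=0.05)

    def test_invalid_r_rejected(self):
        with pytest.raises(InputError):
            init_factors(5, 4, 0, seed=0)


class TestFit:
    def test_objective_descends(self, small_instance, small_hp):
        model = fit(small_instance.Y, small_instance.S_l, small_instance.S_p, small_hp)
        h = np.array(model.training_history)
        assert len(h) == small_hp.max_iters + 1
        assert np.all(np.diff(h) <= 1e-12)
        assert h[-1] < h[0]

    def test_deterministic_given_seed(self, small_instance, small_hp):
        a = fit(small_instance.Y, small_instance.S_l, small_instance.S_p, small_hp)
        b = fit(small_instance.Y, small_instance.S_l, small_instance.S_p, small_hp)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_positives_outscore_negatives(self, small_instance, small_hp):
        model = fit(small_instance.Y, small_instance.S_l, small_instance.S_p, small_hp)
        P = interaction_probability(model.U, model.V)
        pos = P[small_instance.Y.Y == 1]
        neg = P[small_instance.Y.Y == 0]
        assert pos.mean() > neg.mean()

    def test_id_misalignment_rejected(self, small_instance, small_hp):
        S_bad = SimilarityMatrix(
            ids=[f"zz{i}" for i in range(small_instance.S_l.size)],
            values=small_instance.S_l.values,
        )
        with pytest.raises(InputError):
            fit(small_instance.Y, S_bad, small_instance.S_p, small_hp)

    def test_r_too_large_rejected(self, small_instance):
        hp = Hyperparameters(r=8, K1=2)
        with pytest.raises(InputError):
            fit(small_instance.Y, small_instance.S_l, small_instance.S_p, hp)


class TestSmoothingAndPredict:
    def test_no_cold_start_is_identity(self, small_instance, small_hp):
        inst = small_instance
        # ensure every entity has a positive so no smoothing is triggered
        Yv = inst.Y.Y.copy()
        for i in np.flatnonzero(Yv.sum(axis=1) == 0):
            Yv[i, i % Yv.shape[1]] = 1.0
        for j in np.flatnonzero(Yv.sum(axis=0) == 0):
            Yv[j % Yv.shape[0], j] = 1.0
        Y = InteractionMatrix(inst.Y.lncrna_ids, inst.Y.protein_ids, Yv)
        model = fit(Y, inst.S_l, inst.S_p, small_hp)
        U_s, V_s = smoothed_latent_vectors(model, Y)
        assert np.array_equal(U_s, model.U) and np.array_equal(V_s, model.V)
        P = predict(model, Y)
        assert np.array_equal(P.values, interaction_probability(model.U, model.V))

    def _cold_model(self, small_hp, rng, K2):
        m, n = 10, 6
        Y = random_interactions(m, n, 0.4, rng)
        Y.Y[0, :] = 0.0  # lncRNA 0 is cold-start
        S_l, S_p = random_similarity(m, rng), random_similarity(n, rng)
        hp = dataclasses.replace(small_hp, K2=K2)
        model = fit(Y, S_l, S_p, hp)
        return model, Y, S_l

    def test_single_neighbor_copies_vector(self, small_hp, rng):
        model, Y, S_l = self._cold_model(small_hp, rng, K2=1)
        U_s, _ = smoothed_latent_vectors(model, Y)
        positive = np.flatnonzero(Y.Y.sum(axis=1) > 0)
        nn = positive[np.argmax(S_l.values[0, positive])]
        assert np.allclose(U_s[0], model.U[nn])

    def test_equal_weights_give_arithmetic_mean(self, small_hp, rng):
        model, Y, S_l = self._cold_model(small_hp, rng, K2=2)
        positive = np.flatnonzero(Y.Y.sum(axis=1) > 0)
        # force the two nearest positive neighbors to be equally similar
        order = positive[np.argsort(-S_l.values[0, positive], kind="stable")]
        a, b = order[0], order[1]
        w = float(S_l.values[0, a])
        model.S_l.values[0, b] = model.S_l.values[b, 0] = w
        U_s, _ = smoothed_latent_vectors(model, Y)
        assert np.allclose(U_s[0], (model.U[a] + model.U[b]) / 2.0)

    def test_weighted_mean_formula(self, small_hp, rng):
        model, Y, S_l = self._cold_model(small_hp, rng, K2=3)
        positive = np.flatnonzero(Y.Y.sum(axis=1) > 0)
        order = positive[np.argsort(-S_l.values[0, positive], kind="stable")][:3]
        w = S_l.values[0, order]
        expected = (w[:, None] * model.U[order]).sum(axis=0) / w.sum()
        U_s, _ = smoothed_latent_vectors(model, Y)
        assert np.allclose(U_s[0], expected)

    def test_all_cold_is_model_error(self, small_hp, rng):
        m, n = 6, 4
        Y = random_interactions(m, n, 0.5, rng)
        model = fit(Y, random_similarity(m, rng), random_similarity(n, rng), small_hp)
        Y_empty = InteractionMatrix(Y.lncrna_ids, Y.protein_ids, np.zeros(Y.shape))
        with pytest.raises(ModelError):
            smoothed_latent_vectors(model, Y_empty)

    def test_masked_lncrna_recovers_planted_ranking(self, small_hp):
        rhos = []
        for seed in range(3):
            inst = generate_planted_instance(
                m=40, n=12, r=3, density_target=0.25, sim_noise=0.02, seed=seed
            )
            row = np.argmax(inst.Y.Y.sum(axis=1))
            Y = InteractionMatrix(
                inst.Y.lncrna_ids, inst.Y.protein_ids, inst.Y.Y.copy()
            )
            Y.Y[row, :] = 0.0
            hp = dataclasses.replace(small_hp, K2=5, max_iters=60)
            model = fit(Y, inst.S_l, inst.S_p, hp)
            P = predict(model, Y)
            rhos.append(spearmanr(P.values[row], inst.probabilities[row]).statistic)
        assert np.mean(rhos) > 0
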