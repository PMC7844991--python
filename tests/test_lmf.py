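"""Logistic matrix factorization: objective oracle, gradient checks,
optimizer contract, prediction and cold-start behavior."""

import numpy as np
import pytest
from scipy.special import expit

from siglmf.lmf import (LmfHyperParams, LmfModel, SimIc50Estimator, classify,
                        estimate_sim_ic50_new, fit_sim_ic50_estimator,
                        gradients, infer_new_cell_line, laplacian, load_model,
                        objective, predict_matrix, predict_prob, save_model,
                        train)
from siglmf.similarity import SimilarityMatrix, knn_adjacency


def _random_instance(rng, n=6, m=4, L=2, nonneg_sims=True):
    Q = rng.integers(0, 2, (n, m)).astype(float)
    lo = 0.0 if nonneg_sims else -1.0
    Sc = rng.uniform(lo, 1, (n, n)); Sc = (Sc + Sc.T) / 2; np.fill_diagonal(Sc, 1)
    Sd = rng.uniform(lo, 1, (m, m)); Sd = (Sd + Sd.T) / 2; np.fill_diagonal(Sd, 1)
    Hc = laplacian(knn_adjacency(SimilarityMatrix([f"c{i}" for i in range(n)], Sc),
                                 min(3, n - 1)))
    Hd = laplacian(knn_adjacency(SimilarityMatrix([f"d{i}" for i in range(m)], Sd),
                                 min(2, m - 1)))
    return Q, Hc, Hd


def _naive_objective(U, V, bc, bd, Q, Hc, Hd, hyper):
    """Independent double-loop re-implementation of the loss."""
    n, m = Q.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            z = float(U[i] @ V[j]) + bc[i] + bd[j]
            total += (1 + hyper.r * Q[i, j] - Q[i, j]) * np.log1p(np.exp(z)) \
                - hyper.r * Q[i, j] * z
    total += 0.5 * np.trace(U.T @ (hyper.lambda_c * np.eye(n) + hyper.alpha * Hc) @ U)
    total += 0.5 * np.trace(V.T @ (hyper.lambda_d * np.eye(m) + hyper.beta * Hd) @ V)
    return total


class TestObjective:
    def test_zero_model_gives_nm_log2(self):
        n, m = 5, 3
        Q = np.random.default_rng(0).integers(0, 2, (n, m)).astype(float)
        hyper = LmfHyperParams(L=2, lambda_c=0, lambda_d=0, alpha=0, beta=0)
        val = objective(np.zeros((n, 2)), np.zeros((m, 2)), np.zeros(n),
                        np.zeros(m), Q, np.zeros((n, n)), np.zeros((m, m)), hyper)
        assert val == pytest.approx(n * m * np.log(2))

    def test_reduces_to_bernoulli_nll_without_regularizers(self):
        rng = np.random.default_rng(1)
        Q, Hc, Hd = _random_instance(rng)
        U, V = rng.normal(size=(6, 2)), rng.normal(size=(4, 2))
        bc, bd = rng.normal(size=6), rng.normal(size=4)
        hyper = LmfHyperParams(L=2, lambda_c=0, lambda_d=0, alpha=0, beta=0)
        Z = U @ V.T + bc[:, None] + bd[None, :]
        nll = -(Q * np.log(expit(Z)) + (1 - Q) * np.log(expit(-Z))).sum()
        got = objective(U, V, bc, bd, Q, Hc, Hd, hyper)
        assert got == pytest.approx(nll, rel=1e-10)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        Q, Hc, Hd = _random_instance(rng)
        U, V = rng.normal(size=(6, 2)), rng.normal(size=(4, 2))
        bc, bd = rng.normal(size=6), rng.normal(size=4)
        hyper = LmfHyperParams(L=2)
        got = objective(U, V, bc, bd, Q, Hc, Hd, hyper)
        assert got == pytest.approx(_naive_objective(U, V, bc, bd, Q, Hc, Hd,
                                                     hyper), rel=1e-10)

    def test_stable_for_large_logits(self):
        Q = np.ones((1, 1))
        hyper = LmfHyperParams(L=1, lambda_c=0, lambda_d=0, alpha=0, beta=0)
        val = objective(np.array([[50.0]]), np.array([[10.0]]), np.zeros(1),
                        np.zeros(1), Q, np.zeros((1, 1)), np.zeros((1, 1)), hyper)
        assert np.isfinite(val)


class TestGradients:
    def test_matches_central_differences(self):
        rng = np.random.default_rng(3)
        Q, Hc, Hd = _random_instance(rng, n=6, m=4, L=2)
        U, V = rng.normal(size=(6, 2)), rng.normal(size=(4, 2))
        bc, bd = rng.normal(size=6), rng.normal(size=4)
        hyper = LmfHyperParams(L=2)
        gU, gV, gbc, gbd = gradients(U, V, bc, bd, Q, Hc, Hd, hyper)
        eps = 1e-6
        for arr, g in [(U, gU), (V, gV), (bc, gbc), (bd, gbd)]:
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                f1 = objective(U, V, bc, bd, Q, Hc, Hd, hyper)
                arr[idx] = orig - eps
                f0 = objective(U, V, bc, bd, Q, Hc, Hd, hyper)
                arr[idx] = orig
                num = (f1 - f0) / (2 * eps)
                assert abs(num - g[idx]) / max(abs(g[idx]), 1.0) <= 1e-4


class TestLaplacian:
    def test_symmetric_psd_on_random_nonnegative_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(4, 10))
            S = rng.uniform(0, 1, (n, n)); S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            H = laplacian(knn_adjacency(
                SimilarityMatrix([f"c{i}" for i in range(n)], S),
                int(rng.integers(1, n - 1))))
            assert np.allclose(H, H.T)
            assert np.linalg.eigvalsh(H).min() >= -1e-9

    def test_quadratic_form_is_weighted_gap_sum(self):
        rng = np.random.default_rng(5)
        S = rng.uniform(0, 1, (5, 5)); S = (S + S.T) / 2; np.fill_diagonal(S, 1)
        g = knn_adjacency(SimilarityMatrix([f"c{i}" for i in range(5)], S), 2)
        H = laplacian(g)
        x = rng.normal(size=5)
        W = g.W + g.W.T
        expected = 0.5 * sum(W[i, j] * (x[i] - x[j]) ** 2
                             for i in range(5) for j in range(5))
        assert x @ H @ x == pytest.approx(expected, rel=1e-9)


class TestTrain:
    def test_objective_decreases(self):
        rng = np.random.default_rng(6)
        Q, Hc, Hd = _random_instance(rng, n=12, m=6)
        model = train(Q, Hc, Hd, LmfHyperParams(L=3, n_iter=200, seed=0))
        traj = model.objective_trajectory
        assert traj[-1] < traj[0]

    def test_beats_bias_only_model_on_logistic_data(self):
        rng = np.random.default_rng(7)
        n, m, L = 40, 10, 3
        U0, V0 = rng.normal(size=(n, L)), rng.normal(size=(m, L))
        Q = (rng.random((n, m)) < expit(U0 @ V0.T)).astype(float)
        hyper = LmfHyperParams(L=L, alpha=0, beta=0, n_iter=500, seed=0)
        model = train(Q, np.zeros((n, n)), np.zeros((m, m)), hyper)
        probs = predict_matrix(model)
        ll_model = (Q * np.log(probs) + (1 - Q) * np.log(1 - probs)).mean()
        base = np.clip(Q.mean(axis=0), 1e-9, 1 - 1e-9)
        ll_bias = (Q * np.log(base) + (1 - Q) * np.log(1 - base)).mean()
        assert ll_model > ll_bias

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            train(np.array([[0.5]]), np.zeros((1, 1)), np.zeros((1, 1)),
                  LmfHyperParams(L=1))

    def test_roundtrip_serialization(self, tmp_path):
        rng = np.random.default_rng(8)
        Q, Hc, Hd = _random_instance(rng)
        model = train(Q, Hc, Hd, LmfHyperParams(L=2, n_iter=20, seed=0),
                      cell_ids=[f"c{i}" for i in range(6)],
                      drug_ids=[f"d{j}" for j in range(4)])
        save_model(model, tmp_path)
        back = load_model(tmp_path)
        assert np.allclose(back.U, model.U)
        assert np.allclose(back.beta_d, model.beta_d)
        assert back.cell_ids == model.cell_ids
        assert back.hyper == model.hyper


class TestPredict:
    def _model(self):
        return LmfModel(U=np.array([[1.0]]), V=np.array([[0.0]]),
                        beta_c=np.zeros(1), beta_d=np.zeros(1),
                        hyper=LmfHyperParams(L=1))

    def test_zero_logit_is_half(self):
        assert predict_prob(self._model(), 0, 0) == 0.5

    def test_log3_logit_is_three_quarters(self):
        m = self._model()
        m.beta_d[0] = np.log(3.0)
        assert predict_prob(m, 0, 0) == pytest.approx(0.75)

    def test_extreme_logits_saturate_without_overflow(self):
        m = self._model()
        m.beta_c[0] = 40.0
        assert predict_prob(m, 0, 0) == pytest.approx(1.0, abs=1e-15)
        m.beta_c[0] = -40.0
        assert predict_prob(m, 0, 0) == pytest.approx(0.0, abs=1e-15)

    def test_monotone_in_logit_components(self):
        rng = np.random.default_rng(9)
        m = self._model()
        probs = []
        for b in sorted(rng.normal(size=5)):
            m.beta_c[0] = b
            probs.append(predict_prob(m, 0, 0))
        assert probs == sorted(probs)


class TestClassify:
    @pytest.mark.parametrize("prob,threshold,label", [
        (0.41, 0.4, 1),
        (0.4, 0.4, 0),     # boundary: strict inequality
        (0.001, 0.0, 1),
        (0.0, 0.0, 0),
    ])
    def test_threshold_rule(self, prob, threshold, label):
        assert classify(prob, threshold) == label


class TestColdStart:
    def test_tree_memorizes_exact_duplicate(self):
        rng = np.random.default_rng(10)
        feats = rng.uniform(-1, 1, (50, 4))
        target = feats[:, 0]  # sim_ic50 equals sim_exp
        est = SimIc50Estimator(max_depth=12, seed=0).fit(feats, target)
        pred = est.predict(feats[:1])
        # prediction is the midpoint of the true bin
        edges = np.linspace(-1, 1, 11)
        b = np.digitize(np.clip(target[0], -1, 1), edges[1:-1])
        assert pred[0] == pytest.approx((edges[b] + edges[b + 1]) / 2)

    def test_predictions_within_unit_interval_bounds(self):
        rng = np.random.default_rng(11)
        feats = rng.uniform(-1, 1, (80, 4))
        est = SimIc50Estimator(seed=0).fit(feats, rng.uniform(-1, 1, 80))
        preds = est.predict(rng.uniform(-1, 1, (30, 4)))
        assert (preds >= -1).all() and (preds <= 1).all()

    def test_monotone_signal_gives_rank_correlation(self):
        rng = np.random.default_rng(12)
        sim_exp = rng.uniform(-1, 1, (40, 40))
        sim_exp = (sim_exp + sim_exp.T) / 2; np.fill_diagonal(sim_exp, 1)
        noise = 0.1 * rng.normal(size=(40, 40)); noise = (noise + noise.T) / 2
        sim_ic50 = np.clip(0.8 * sim_exp + noise, -1, 1); np.fill_diagonal(sim_ic50, 1)
        flat = rng.uniform(0, 1, (40, 40)); flat = (flat + flat.T) / 2
        np.fill_diagonal(flat, 1)
        est = fit_sim_ic50_estimator(sim_exp, flat, flat, flat, sim_ic50, seed=0)
        new_rows = (sim_exp[0], flat[0], flat[0], flat[0])
        pred = estimate_sim_ic50_new(new_rows, est)
        from scipy.stats import spearmanr
        rho = spearmanr(pred, sim_ic50[0]).statistic
        assert rho >= 0.5

    def test_untrained_estimator_rejected(self):
        with pytest.raises(RuntimeError):
            SimIc50Estimator().predict(np.zeros((1, 4)))

    def _trained(self):
        rng = np.random.default_rng(13)
        Q, Hc, Hd = _random_instance(rng, n=6, m=4)
        return train(Q, Hc, Hd, LmfHyperParams(L=2, n_iter=50, seed=0),
                     cell_ids=[f"c{i}" for i in range(6)],
                     drug_ids=[f"d{j}" for j in range(4)])

    def test_duplicate_of_training_line_with_k1(self):
        model = self._trained()
        row = np.array([0.2, 0.95, 0.1, 0.3, 0.2, 0.1])
        u, b, probs = infer_new_cell_line(row, model, k=1)
        assert np.allclose(u, model.U[1])
        assert b == model.beta_c[1]
        assert probs == pytest.approx(expit(model.U[1] @ model.V.T + b
                                            + model.beta_d))

    def test_equal_similarities_use_plain_mean(self):
        model = self._trained()
        row = np.full(6, 0.5)
        u, b, _ = infer_new_cell_line(row, model, k=3)
        neigh = [0, 1, 2]  # id tie-break: c0 < c1 < c2
        assert np.allclose(u, model.U[neigh].mean(axis=0))

    def test_hand_weighted_combination(self):
        model = self._trained()
        row = np.array([0.6, 0.2, 0.2, 0.0, 0.0, 0.0])
        u, b, _ = infer_new_cell_line(row, model, k=3)
        w = np.array([0.6, 0.2, 0.2])
        expected = (w / w.sum()) @ model.U[[0, 1, 2]]
        assert np.allclose(u, expected)

    def test_nonpositive_similarities_fall_back_to_mean(self):
        model = self._trained()
        row = np.full(6, -0.5)
        u, b, _ = infer_new_cell_line(row, model, k=2)
        assert np.allclose(u, model.U[[0, 1]].mean(axis=0))
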