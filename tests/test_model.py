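import numpy as np
import pandas as pd
import pytest

from scanmf import ModelConfig, PriorSet, ScANMF
from scanmf.graph import build_cell_graph, laplacian_quadratic
from scanmf.model import objective, tune, update_U, update_V
from scanmf.pipeline import fit_simulated, score_simulated

from conftest import random_priors


def objective_oracle(X, U, V, priors, g, cfg):
    """Term-by-term recomputation, written independently of objective()."""
    total = np.linalg.norm(X - U @ V.T, ord="fro") ** 2
    total += cfg.alpha0 * np.sum(np.abs(U))
    total += cfg.alpha * np.sum(np.abs(U) * (1 - priors.marker_matrix))
    total += cfg.beta * np.sum(np.abs(V) * (1 - priors.label_matrix))
    if g is not None:
        W = g.W.toarray()
        pair = sum(
            W[a, b] * np.sum((V[a] - V[b]) ** 2)
            for a in range(W.shape[0]) for b in range(W.shape[0])
        )
        total += cfg.gamma * 0.5 * pair
    return total


class TestObjective:
    def test_collapses_to_frobenius_norm(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 5))
        pri = random_priors(rng, 6, 5, 2)
        cfg = ModelConfig(alpha0=0, alpha=0, beta=0, gamma=0)
        val = objective(X, np.zeros((6, 2)), np.zeros((5, 2)), pri, None, cfg)
        assert val == pytest.approx(np.sum(X ** 2))

    def test_exact_factorization_is_zero(self):
        rng = np.random.default_rng(1)
        U, V = rng.random((6, 2)), rng.random((5, 2))
        pri = random_priors(rng, 6, 5, 2)
        cfg = ModelConfig(alpha0=0, alpha=0, beta=0, gamma=0)
        assert objective(U @ V.T, U, V, pri, None, cfg) == pytest.approx(0.0)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.random((5, 4)) * 3
        U, V = rng.random((5, 2)), rng.random((4, 2))
        pri = random_priors(rng, 5, 4, 2)
        g = build_cell_graph(X, K=2)
        cfg = ModelConfig(alpha0=3.0, alpha=7.0, beta=11.0, gamma=0.5)
        assert objective(X, U, V, pri, g, cfg) == pytest.approx(
            objective_oracle(X, U, V, pri, g, cfg), rel=1e-12
        )

    def test_rejects_non_finite(self):
        rng = np.random.default_rng(3)
        pri = random_priors(rng, 3, 3, 2)
        X = np.ones((3, 3))
        U = np.ones((3, 2))
        U[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            objective(X, U, np.ones((3, 2)), pri, None, ModelConfig())


class TestUpdates:
    def test_zero_entries_are_fixed_points(self):
        rng = np.random.default_rng(4)
        X = rng.random((6, 5))
        pri = random_priors(rng, 6, 5, 3)
        U = rng.random((6, 3))
        V = rng.random((5, 3))
        U[2, 1] = 0.0
        V[3, 0] = 0.0
        cfg = ModelConfig()
        assert update_U(X, U, V, pri, cfg)[2, 1] == 0.0
        assert update_V(X, U, V, pri, None, ModelConfig(gamma=0))[3, 0] == 0.0

    def test_reduces_to_lee_seung_without_penalties(self):
        rng = np.random.default_rng(5)
        X = rng.random((7, 6))
        U, V = rng.random((7, 3)), rng.random((6, 3))
        pri = random_priors(rng, 7, 6, 3)
        cfg = ModelConfig(alpha0=0, alpha=0, beta=0, gamma=0)
        expected_u = U * (X @ V) / (U @ (V.T @ V) + cfg.eps / 2)
        assert np.allclose(update_U(X, U, V, pri, cfg), expected_u, rtol=1e-9)
        expected_v = V * (X.T @ U) / (V @ (U.T @ U) + cfg.eps)
        assert np.allclose(update_V(X, U, V, pri, None, cfg), expected_v,
                           rtol=1e-9)

    def test_sweep_never_increases_objective(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            r = np.random.default_rng(trial)
            m, n, p = int(r.integers(4, 12)), int(r.integers(5, 12)), 3
            X = r.random((m, n)) * 5
            pri = random_priors(r, m, n, p)
            g = build_cell_graph(X, K=min(3, n - 1))
            cfg = ModelConfig(alpha0=r.random() * 50, alpha=r.random() * 500,
                              beta=r.random() * 500, gamma=r.random() * 5)
            U, V = 1 - r.random((m, p)), 1 - r.random((n, p))
            before = objective(X, U, V, pri, g, cfg)
            U = update_U(X, U, V, pri, cfg)
            V = update_V(X, U, V, pri, g, cfg)
            after = objective(X, U, V, pri, g, cfg)
            assert after <= before * (1 + 1e-8)

    def test_non_negativity_preserved(self):
        rng = np.random.default_rng(7)
        X = rng.random((8, 8))
        pri = random_priors(rng, 8, 8, 3)
        g = build_cell_graph(X, K=3)
        cfg = ModelConfig(gamma=2.0)
        U, V = rng.random((8, 3)), rng.random((8, 3))
        for _ in range(10):
            U = update_U(X, U, V, pri, cfg)
            V = update_V(X, U, V, pri, g, cfg)
            assert U.min() >= 0 and V.min() >= 0


class TestFit:
    def test_same_seed_identical_results(self, small_sim, small_sim_labels,
                                          fast_config):
        r1, _ = fit_simulated(small_sim, small_sim_labels,
                              small_sim.marker_sets, fast_config, seed=9)
        r2, _ = fit_simulated(small_sim, small_sim_labels,
                              small_sim.marker_sets, fast_config, seed=9)
        assert np.array_equal(r1.U, r2.U)
        assert np.array_equal(r1.V, r2.V)

    def test_trace_non_increasing_across_seeds(self, small_sim,
                                               small_sim_labels, fast_config):
        for seed in range(3):
            res, _ = fit_simulated(small_sim, small_sim_labels,
                                   small_sim.marker_sets, fast_config,
                                   seed=seed)
            trace = res.objective_trace
            assert np.all(np.diff(trace) <= 1e-8 * trace[:-1])
            assert np.isfinite(trace).all()

    def test_planted_noiseless_recovery(self):
        # exact rank-p block matrix with perfect priors: the argmax over V
        # must reproduce the planted assignment on every cell
        from scanmf import SimulationConfig, corrupt_labels, simulate

        cfg = SimulationConfig(n_cells=90, n_types=3, markers_per_type=4,
                               n_background_genes=10, pi0=0.0,
                               sigma_hetero=0.0, sigma_homo=0.0)
        sim = simulate(cfg, seed=21)
        labels = corrupt_labels(sim.true_labels, retain_fraction=0.2, seed=22)
        res, _ = fit_simulated(sim, labels, sim.marker_sets,
                               ModelConfig(), seed=23)
        rep = score_simulated(sim, res, labels)
        assert rep.accuracy == 100.0

    def test_empty_matrix_rejected(self):
        pri = random_priors(np.random.default_rng(0), 0, 0, 2)
        with pytest.raises(ValueError, match="empty"):
            ScANMF(np.zeros((0, 0)), pri, gamma=0)

    def test_gamma_without_graph_rejected(self):
        rng = np.random.default_rng(8)
        pri = random_priors(rng, 4, 4, 2)
        with pytest.raises(ValueError, match="graph"):
            ScANMF(rng.random((4, 4)), pri, gamma=1.0)

    def test_kkt_stationarity_improves_with_iterations(self):
        # complementarity u .* |dO/dU| must shrink toward zero as the
        # multiplicative updates converge (they approach a KKT point)
        rng = np.random.default_rng(9)
        U0, V0 = rng.random((10, 2)) + 0.1, rng.random((12, 2)) + 0.1
        X = U0 @ V0.T
        pri = random_priors(rng, 10, 12, 2)

        def stationarity(res, cfg):
            grad_u = (-2 * X @ res.V + 2 * res.U @ (res.V.T @ res.V)
                      + cfg.alpha0 + cfg.alpha * (1 - pri.marker_matrix))
            return np.abs(res.U * grad_u).max()

        stats = {}
        for iters in (3, 2000):
            cfg = ModelConfig(alpha0=0.1, alpha=1.0, beta=1.0, gamma=0.0,
                              max_iter=iters, rel_tol=1e-15)
            stats[iters] = stationarity(ScANMF(X, pri, config=cfg).fit(seed=1),
                                        cfg)
        assert stats[2000] < 1e-2 * stats[3]

    def test_nndsvd_init_runs_and_stays_non_negative(self):
        rng = np.random.default_rng(10)
        X = rng.random((8, 9)) * 2
        pri = random_priors(rng, 8, 9, 3)
        cfg = ModelConfig(alpha0=1, alpha=10, beta=10, gamma=0,
                          init="nndsvd", max_iter=10)
        res = ScANMF(X, pri, config=cfg).fit()
        assert res.U.min() >= 0 and res.V.min() >= 0


class TestAnnotate:
    @staticmethod
    def _results(V, types):
        n, p = V.shape
        pri = PriorSet(np.ones((3, p)), np.ones((n, p)), types, 0, 0,
                       labeled_mask=np.zeros(n, dtype=bool))
        model = ScANMF(np.ones((3, n)), pri, gamma=0)
        res = model.fit(seed=0)
        res.V = np.asarray(V, dtype=float)
        return res

    def test_argmax_assignment(self):
        res = self._results(np.array([[0.1, 0.9, 0.0]]), ["A", "B", "C"])
        assert res.annotate().iloc[0] == "B"

    def test_tie_goes_to_first_type(self):
        res = self._results(np.array([[0.5, 0.5]]), ["A", "B"])
        assert res.annotate().iloc[0] == "A"

    def test_all_zero_row_unassigned(self, caplog):
        res = self._results(np.array([[0.0, 0.0], [1.0, 0.0]]), ["A", "B"])
        with caplog.at_level("WARNING"):
            out = res.annotate()
        assert out.iloc[0] == "unassigned"
        assert out.iloc[1] == "A"

    def test_summary_renders(self, small_sim, small_sim_labels, fast_config):
        res, _ = fit_simulated(small_sim, small_sim_labels,
                               small_sim.marker_sets, fast_config, seed=0)
        text = str(res.summary())
        assert "factors (p)" in text and "converged" in text


class TestTune:
    def test_single_grid_point_returned(self, small_sim, small_sim_labels):
        from scanmf.preprocess import build_priors

        pri = build_priors(small_sim.marker_sets, small_sim_labels,
                           small_sim.matrix.gene_ids,
                           small_sim.matrix.cell_ids)
        g = build_cell_graph(small_sim.matrix, K=30)
        best, table = tune(small_sim.matrix, pri, g,
                           alpha_grid=[1e4], beta_grid=[1e4],
                           gamma_grid=[10.0], folds=3,
                           base_config=ModelConfig(max_iter=15), seed=0)
        assert (best.alpha, best.beta, best.gamma) == (1e4, 1e4, 10.0)
        assert len(table) == 1

    def test_priors_beat_no_priors(self, small_sim, small_sim_labels):
        from scanmf.preprocess import build_priors

        pri = build_priors(small_sim.marker_sets, small_sim_labels,
                           small_sim.matrix.gene_ids,
                           small_sim.matrix.cell_ids)
        g = build_cell_graph(small_sim.matrix, K=30)
        _, table = tune(small_sim.matrix, pri, g,
                        alpha_grid=[0.0, 1e4], beta_grid=[1e4],
                        gamma_grid=[10.0], folds=3,
                        base_config=ModelConfig(max_iter=15), seed=0)
        table = table.set_index("alpha")
        assert (table.loc[1e4, "cv_accuracy"]
                >= table.loc[0.0, "cv_accuracy"] - 0.05)

    def test_requires_labels(self, small_sim):
        from scanmf.preprocess import build_priors

        pri = build_priors(small_sim.marker_sets, None,
                           small_sim.matrix.gene_ids,
                           small_sim.matrix.cell_ids)
        with pytest.raises(ValueError, match="labeled"):
            tune(small_sim.matrix, pri, None, alpha_grid=[1.0],
                 beta_grid=[1.0], gamma_grid=[0.1])
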