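"""Loss, optimization loop, checkpoint selection, evaluation and ablation."""

import numpy as np
import pytest

from citegraph.model import ModelConfig
from citegraph.simulate import SimConfig, simulate
from citegraph.training import (
    Checkpoint,
    RunResult,
    TrainConfig,
    ablate,
    best_of_runs,
    compute_metrics,
    evaluate,
    mse_loss,
    predict_from_checkpoint,
    select_best_epoch,
    train,
)


def _tiny_task(seed=0, n_cells=80):
    sim = SimConfig(n_cells=n_cells, n_genes=20, n_proteins=4, n_modules=4,
                    n_prior_features=2, seed=seed)
    expr, prot, priors, _ = simulate(sim)
    mc = ModelConfig(n_genes=20, n_proteins=4, n_prior_features=2,
                     hidden=(16, 8), d_r=4, d_c=2)
    return expr.values, prot.values, priors.matrices, mc


class TestMseLoss:
    def test_identical_is_zero(self):
        y = np.random.default_rng(0).normal(size=(3, 5))
        assert mse_loss(y, y) == 0.0

    def test_hand_value(self):
        assert mse_loss([[1.0, 2.0]], [[2.0, 0.0]]) == pytest.approx(5.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        y, p = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        base = mse_loss(y, p)
        scaled = mse_loss(y, y + 3.0 * (p - y))
        assert scaled == pytest.approx(9.0 * base)

    def test_batch_mean_reduction(self):
        y = np.zeros((2, 2))
        p = np.array([[1.0, 0.0], [0.0, 2.0]])
        # per-cell sums 1 and 4, mean 2.5
        assert mse_loss(y, p) == pytest.approx(2.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestBestEpochSelection:
    def test_interior_minimum(self):
        assert select_best_epoch([5, 3, 4, 2, 6]) == 3

    def test_tie_keeps_earlier_epoch(self):
        assert select_best_epoch([4, 2, 2, 5]) == 1

    def test_checkpoint_agrees_with_history(self):
        x, y, priors, mc = _tiny_task()
        ckpt, history = train(x, y, priors, mc,
                              TrainConfig(epochs=8, batch_size=16,
                                          learning_rate=1e-2, seed=0))
        assert ckpt.epoch == select_best_epoch(history)
        assert ckpt.loss == min(history)


class TestTrain:
    def test_deterministic_given_seed(self):
        x, y, priors, mc = _tiny_task()
        tc = TrainConfig(epochs=4, batch_size=16, learning_rate=1e-3, seed=7)
        ckpt1, hist1 = train(x, y, priors, mc, tc)
        ckpt2, hist2 = train(x, y, priors, mc, tc)
        assert hist1 == hist2
        for k in ckpt1.params:
            np.testing.assert_array_equal(ckpt1.params[k], ckpt2.params[k])

    def test_zero_learning_rate_is_inert(self):
        x, y, priors, mc = _tiny_task()
        tc = TrainConfig(epochs=3, batch_size=16, learning_rate=0.0, seed=0)
        _, history = train(x, y, priors, mc, tc)
        assert history[0] == pytest.approx(history[1]) == pytest.approx(history[2])

    def test_learning_reduces_loss(self):
        x, y, priors, mc = _tiny_task()
        ckpt, history = train(x, y, priors, mc,
                              TrainConfig(epochs=50, batch_size=16,
                                          learning_rate=1e-3, seed=1))
        assert ckpt.loss < history[0]

    def test_empty_split_rejected(self):
        _, _, priors, mc = _tiny_task()
        with pytest.raises(ValueError, match="empty"):
            train(np.zeros((0, 20)), np.zeros((0, 4)), priors, mc, TrainConfig())

    def test_checkpoint_round_trip(self, tmp_path):
        x, y, priors, mc = _tiny_task()
        tc = TrainConfig(epochs=2, batch_size=32, learning_rate=1e-3, seed=0)
        ckpt, _ = train(x, y, priors, mc, tc)
        path = tmp_path / "model.npz"
        ckpt.save(path)
        loaded = Checkpoint.load(path)
        np.testing.assert_array_equal(
            predict_from_checkpoint(loaded, x[:5]),
            predict_from_checkpoint(ckpt, x[:5]),
        )
        assert loaded.epoch == ckpt.epoch
        assert loaded.model_config.d == mc.d

    def test_gene_dimension_mismatch_on_predict(self):
        x, y, priors, mc = _tiny_task()
        tc = TrainConfig(epochs=1, batch_size=32, learning_rate=1e-3, seed=0)
        ckpt, _ = train(x, y, priors, mc, tc)
        with pytest.raises(ValueError, match="gene dimension"):
            predict_from_checkpoint(ckpt, np.zeros((2, 21)))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.random.default_rng(0).normal(size=(6, 3))
        res = compute_metrics(y, y.copy())
        np.testing.assert_allclose(res.mse, 0)
        np.testing.assert_allclose(res.pcc, 1)

    def test_anticorrelated_predictions(self):
        y = np.random.default_rng(1).normal(size=(6, 3))
        res = compute_metrics(y, -y)
        np.testing.assert_allclose(res.pcc, -1)

    def test_hand_computed_toy_table(self):
        y = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 0.0], [4.0, 1.0]])
        p = np.array([[1.5, 1.0], [2.0, 0.0], [2.5, 1.0], [5.0, 0.0]])
        res = compute_metrics(y, p, ["A", "B"])
        # protein A: errors 0.5, 0, -0.5, 1 -> MSE = 1.5/4
        assert res.mse[0] == pytest.approx(0.375)
        assert res.mse[1] == pytest.approx(1.0)
        # protein A Pearson r computed by hand from the 4 pairs
        ya, pa = y[:, 0], p[:, 0]
        r = (np.mean(ya * pa) - ya.mean() * pa.mean()) / (ya.std() * pa.std())
        assert res.pcc[0] == pytest.approx(r)
        assert res.pcc[1] == pytest.approx(-1.0)

    def test_constant_protein_warns_and_is_excluded(self):
        y = np.column_stack([np.ones(5), np.arange(5.0)])
        p = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            res = compute_metrics(y, p)
        assert np.isnan(res.pcc[0])
        assert res.pcc_mean == pytest.approx(1.0)

    def test_summary_consistent_with_training_loss(self):
        rng = np.random.default_rng(3)
        y, p = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        res = compute_metrics(y, p)
        assert np.mean(res.mse) == pytest.approx(mse_loss(y, p) / 4)

    def test_sd_uses_sample_convention(self):
        res = RunResult(["a", "b"], mse=np.array([1.0, 3.0]),
                        pcc=np.array([0.5, 0.9]))
        assert res.mse_sd == pytest.approx(np.std([1, 3], ddof=1))


class TestBestOfRuns:
    def _mk(self, mse, pcc):
        return RunResult(["a", "b"], np.asarray(mse, float), np.asarray(pcc, float))

    def test_single_run_is_identity(self):
        r = self._mk([0.3, 0.2], [0.5, 0.6])
        out = best_of_runs([r])
        np.testing.assert_array_equal(out.mse, r.mse)
        np.testing.assert_array_equal(out.pcc, r.pcc)

    def test_min_mse_max_pcc_selected_independently(self):
        runs = [
            self._mk([0.3, 0.5], [0.9, 0.1]),
            self._mk([0.2, 0.7], [0.1, 0.8]),
            self._mk([0.4, 0.6], [0.5, 0.5]),
        ]
        out = best_of_runs(runs)
        np.testing.assert_allclose(out.mse, [0.2, 0.5])
        np.testing.assert_allclose(out.pcc, [0.9, 0.8])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_of_runs([])


class TestEvaluateEndToEnd:
    def test_evaluate_on_trained_model(self):
        x, y, priors, mc = _tiny_task()
        tc = TrainConfig(epochs=5, batch_size=16, learning_rate=1e-3, seed=0)
        ckpt, _ = train(x[:60], y[:60], priors, mc, tc)
        res = evaluate(ckpt, x[60:], y[60:], ["p1", "p2", "p3", "p4"])
        assert res.mse.shape == (4,)
        assert res.checkpoint_epoch == ckpt.epoch
        assert np.isfinite(res.mse).all()

    def test_empty_test_split_rejected(self):
        x, y, priors, mc = _tiny_task()
        tc = TrainConfig(epochs=1, batch_size=32, learning_rate=1e-3, seed=0)
        ckpt, _ = train(x, y, priors, mc, tc)
        with pytest.raises(ValueError, match="empty"):
            evaluate(ckpt, np.zeros((0, 20)), np.zeros((0, 4)))


def test_ablation_table_shape_and_ranges():
    x, y, priors, mc = _tiny_task(n_cells=60)
    tc = TrainConfig(epochs=2, batch_size=32, learning_rate=1e-3, seed=0)
    rows = ablate(x[:40], y[:40], x[40:], y[40:], priors, ["f1", "f2"],
                  mc, tc, repeats=2)
    assert [r["condition"] for r in rows] == ["no_prior", "f1", "f2", "merged"]
    for r in rows:
        assert r["pcc_half_range"] >= 0 and r["mse_half_range"] >= 0
        assert np.isfinite(r["mse_mid"])
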