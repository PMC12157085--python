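"""Unit tests for the microscopic network: weights, updates, simulation."""
import math

import numpy as np
import pytest
from scipy import stats

import wtanet as wn
from wtanet.core import _hard_winners, initial_state


class TestSampleWeights:
    def test_block_law_moments(self):
        # mu_J = 0, sigma_J^2 = 1, D=5, N=1000: each block ~ N(0, 5/1000)
        spec = wn.preset_unstructured(5)
        W = wn.sample_weights(spec, 1000, seed=0, mode="dense")
        block = W.block(2, 3)
        n = block.size
        se_mean = math.sqrt(0.005 / n)
        assert abs(block.mean()) < 3 * se_mean
        se_var = 0.005 * math.sqrt(2.0 / (n - 1))
        assert abs(block.var() - 0.005) < 3 * se_var

    def test_kolmogorov_smirnov_block_law(self):
        spec = wn.WeightSpec([[0.4, 0.0], [0.0, 0.4]], [[2.0, 1.0], [1.0, 2.0]])
        N = 320  # > 1e5 entries per block
        W = wn.sample_weights(spec, N, seed=7, mode="dense")
        for d, dp in [(0, 0), (0, 1)]:
            entries = W.block(d, dp).ravel()
            mu = spec.mean_matrix[d, dp] * 2 / N
            sd = math.sqrt(spec.var_matrix[d, dp] * 2 / N)
            p = stats.kstest(entries, stats.norm(mu, sd).cdf).pvalue
            assert p > 0.01

    def test_degenerate_variance_gives_constant(self):
        spec = wn.WeightSpec(np.full((3, 3), 2.0), np.zeros((3, 3)))
        W = wn.sample_weights(spec, 4, seed=1, mode="dense")
        assert np.allclose(W.block(1, 2), 2.0 * 3 / 4)

    def test_determinism(self):
        spec = wn.preset_unstructured(3)
        for mode in ("dense", "blockwise"):
            a = wn.sample_weights(spec, 20, seed=5, mode=mode)
            b = wn.sample_weights(spec, 20, seed=5, mode=mode)
            assert np.array_equal(a.block(1, 2), b.block(1, 2))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            wn.WeightSpec(np.zeros((2, 2)), [[1.0, -1.0], [0.0, 1.0]])

    def test_dense_memory_guard(self):
        spec = wn.preset_unstructured(5)
        with pytest.raises(MemoryError, match="blockwise"):
            wn.sample_weights(spec, 10_000, seed=0, mode="dense")

    def test_blockwise_matches_dense_law(self):
        spec = wn.WeightSpec([[1.0, -0.5], [0.0, 2.0]], [[1.0, 4.0], [0.25, 9.0]])
        N = 300
        W = wn.sample_weights(spec, N, seed=3, mode="blockwise")
        for d in range(2):
            for dp in range(2):
                blk = W.block(d, dp)
                mu = spec.mean_matrix[d, dp] * 2 / N
                var = spec.var_matrix[d, dp] * 2 / N
                n = blk.size
                assert abs(blk.mean() - mu) < 3 * math.sqrt(var / n)
                assert abs(blk.var() - var) < 3 * var * math.sqrt(2.0 / (n - 1))


class TestActivations:
    def test_softmax_constant_input_is_uniform(self):
        for D in (2, 5, 9):
            out = wn.softmax_activation(np.full(D, 3.7), g=2.0)
            assert np.allclose(out, 1.0 / D, atol=1e-12)

    def test_softmax_closed_form(self):
        out = wn.softmax_activation(np.array([math.log(2.0), 0.0]), g=1.0)
        assert np.allclose(out, [2 / 3, 1 / 3], atol=1e-12)

    def test_softmax_high_gain_approaches_wta(self):
        out = wn.softmax_activation(np.array([0.5, 0.1, 0.2]), g=50.0)
        assert np.allclose(out, [1.0, 0.0, 0.0], atol=1e-6)

    def test_softmax_rows_sum_to_one_extreme_inputs(self):
        x = np.array([[1e6, -1e6, 0.0], [5.0, 5.0, 5.0]])
        out = wn.softmax_activation(x, g=10.0)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_hard_wta_unique_argmax(self, rng):
        assert np.array_equal(wn.hard_wta(np.array([0.5, 0.1, 0.2]), rng), [1, 0, 0])

    def test_hard_wta_single_neuron(self, rng):
        assert np.array_equal(wn.hard_wta(np.array([3.0]), rng), [1.0])

    def test_hard_wta_tie_break_uniform(self, rng):
        # ties split evenly between the two maxima; the non-max never wins
        x = np.array([1.0, 1.0, 0.0])
        wins = np.array([wn.hard_wta(x, rng) for _ in range(10_000)])
        freq = wins.mean(axis=0)
        assert freq[2] == 0.0
        assert abs(freq[0] - 0.5) < 0.02


class TestComputeInputs:
    def test_zero_weights_pass_external(self):
        spec = wn.WeightSpec(np.zeros((2, 2)), np.zeros((2, 2)))
        W = wn.sample_weights(spec, 3, seed=0, mode="dense")
        ext = np.tile([1.0, 0.0], (3, 1))
        y = np.full((3, 2), 0.5)
        assert np.allclose(wn.compute_inputs(y, W, ext), ext)

    def test_hand_summed_fixture(self):
        fx = wn.make_fixture("hand-net-2x2")
        J, y_prev, expected = (
            fx.payload["J"],
            fx.payload["y_prev"],
            fx.payload["x_expected"],
        )
        spec = wn.WeightSpec(np.zeros((2, 2)), np.zeros((2, 2)))
        W = wn.sample_weights(spec, 2, seed=0, mode="dense")
        for d in range(2):
            for dp in range(2):
                W.flat[d * 2 : (d + 1) * 2, dp * 2 : (dp + 1) * 2] = J[d, dp]
        got = wn.compute_inputs(y_prev, W)
        # independent re-evaluation of the double sum, element by element
        hand = np.zeros((2, 2))
        for i in range(2):
            for d in range(2):
                for j in range(2):
                    for dp in range(2):
                        hand[i, d] += J[d, dp, i, j] * y_prev[j, dp]
        assert np.allclose(got, hand, atol=1e-12)
        assert np.allclose(got, expected, atol=1e-12)

    def test_off_manifold_zero_state_gives_external(self):
        spec = wn.preset_unstructured(3)
        W = wn.sample_weights(spec, 10, seed=2, mode="dense")
        ext = np.arange(30, dtype=float).reshape(10, 3)
        assert np.allclose(wn.compute_inputs(np.zeros((10, 3)), W, ext), ext)

    def test_dense_blockwise_equivalence(self, rng):
        spec = wn.WeightSpec([[0.5, -1.0], [2.0, 0.0]], [[1.0, 3.0], [0.5, 2.0]])
        Wb = wn.sample_weights(spec, 40, seed=9, mode="blockwise")
        Wd = Wb.to_dense()
        y = rng.dirichlet(np.ones(2), size=40)
        xa = wn.compute_inputs(y, Wb)
        xb = wn.compute_inputs(y, Wd)
        assert np.allclose(xa, xb, rtol=1e-9, atol=1e-12)

    def test_shape_mismatch_raises(self):
        W = wn.sample_weights(wn.preset_unstructured(2), 4, seed=0, mode="dense")
        with pytest.raises(ValueError):
            wn.compute_inputs(np.zeros((5, 2)), W)


class TestDrawExternal:
    def test_empty_schedule_is_zero(self, rng):
        sched = wn.InputSchedule.empty(3)
        assert np.all(wn.draw_external(sched, 5, 10, rng) == 0)

    def test_deterministic_columns(self, rng):
        sched = wn.InputSchedule.single(0, 10, u=[2.0, 0.0, 0.0])
        ext = wn.draw_external(sched, 3, 7, rng)
        assert np.all(ext[:, 0] == 2.0) and np.all(ext[:, 1:] == 0.0)

    def test_variance_realized(self, rng):
        sched = wn.InputSchedule.single(0, 10, u=[0.0, 0.0], v=[4.0, 0.0])
        col = wn.draw_external(sched, 0, 10_000, rng)[:, 0]
        se = 4.0 * math.sqrt(2.0 / (col.size - 1))
        assert abs(col.var() - 4.0) < 3 * se

    def test_half_open_epochs(self, rng):
        sched = wn.InputSchedule.single(5, 8, u=[1.0])
        assert wn.draw_external(sched, 4, 2, rng).sum() == 0
        assert wn.draw_external(sched, 5, 2, rng).sum() == 2
        assert wn.draw_external(sched, 7, 2, rng).sum() == 2
        assert wn.draw_external(sched, 8, 2, rng).sum() == 0


class TestStepAndSimulate:
    def test_total_activity_conserved(self, rng, unstructured5):
        W = wn.sample_weights(unstructured5, 50, seed=0, mode="dense")
        y = rng.dirichlet(np.ones(5), size=50)
        out = wn.step_full(y, W, None, g=2.0)
        assert abs(out.sum() - 50) < 1e-9
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_dominant_input_wins_everywhere(self, rng):
        spec = wn.WeightSpec(np.zeros((3, 3)), np.zeros((3, 3)))
        W = wn.sample_weights(spec, 20, seed=0, mode="dense")
        ext = np.tile([5.0, 0.0, 0.0], (20, 1))
        y = wn.step_full(np.zeros((20, 3)), W, ext, g=math.inf, rng=rng)
        assert np.all(y[:, 0] == 1.0)

    def test_low_gain_reaches_fixed_point(self, unstructured5):
        cfg = wn.ModelConfig(N=500, D=5, g=0.5, T=100, seed=3)
        res = wn.simulate_full(cfg, unstructured5, record="activations")
        delta = np.abs(res.activations[-1] - res.activations[-2]).max()
        assert delta < 1e-6

    def test_raster_has_one_spike_per_unit_per_step(self, unstructured5):
        cfg = wn.ModelConfig(N=60, D=5, g=math.inf, T=40, seed=4)
        res = wn.simulate_full(cfg, unstructured5, record="raster")
        assert len(res.raster) == 60 * 40
        per_step = np.bincount(res.raster.t, minlength=40)
        assert np.all(per_step == 60)
        assert np.allclose(res.rates.sum(axis=1), 1.0)

    def test_bit_identical_reruns(self, unstructured5):
        cfg = wn.ModelConfig(N=40, D=5, g=math.inf, T=30, seed=8)
        a = wn.simulate_full(cfg, unstructured5, record="raster")
        b = wn.simulate_full(cfg, unstructured5, record="raster")
        assert a.raster == b.raster

    def test_seed_changes_raster(self, unstructured5):
        a = wn.simulate_full(
            wn.ModelConfig(N=40, D=5, g=math.inf, T=30, seed=8), unstructured5, record="raster"
        )
        b = wn.simulate_full(
            wn.ModelConfig(N=40, D=5, g=math.inf, T=30, seed=9), unstructured5, record="raster"
        )
        assert a.raster != b.raster

    def test_raster_requires_hard_gain(self, unstructured5):
        cfg = wn.ModelConfig(N=10, D=5, g=1.0, T=5, seed=0)
        with pytest.raises(ValueError):
            wn.simulate_full(cfg, unstructured5, record="raster")

    def test_initial_state_hard_is_onehot(self):
        cfg = wn.ModelConfig(N=100, D=4, g=math.inf, T=1, seed=0)
        y = initial_state(cfg)
        assert np.all(y.sum(axis=1) == 1.0)
        assert set(np.unique(y)) <= {0.0, 1.0}

    def test_unstructured_spiking_is_poisson_like(self):
        # per-neuron CV2 concentrates near unity; at rate 1/D the exact
        # discrete (geometric-ISI) expectation is 0.922 for D = 12
        import wtanet.analysis as ana

        cfg = wn.ModelConfig(N=300, D=12, g=math.inf, T=3000, seed=2)
        res = wn.simulate_full(cfg, wn.preset_unstructured(12), record="raster")
        stats = ana.spike_train_stats(res.raster)
        ok = stats[~stats.undersampled]
        assert 0.85 < ok["cv2"].median() < 1.15
        assert abs(ok["cv2"].median() - 0.922) < 0.05

    def test_hard_winner_rows_match_hard_wta(self, rng):
        x = rng.standard_normal((50, 4))
        w = _hard_winners(x, rng)
        assert np.array_equal(w, np.argmax(x, axis=1))
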