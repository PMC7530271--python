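"""The shallow modulatory network: activations, plasticity, rate adaptation,
weight updates, and online training behaviour."""

import numpy as np
import pytest

from modnet import core, synthetic
from modnet.core import ModNetConfig, sigmoid


def tiny_state(n_in=6, n_hidden=4, n_out=3, seed=0, **kw):
    cfg = ModNetConfig(n_in=n_in, n_out=n_out, n_hidden=n_hidden, seed=seed, **kw)
    return core.init_state(cfg), cfg


class TestForward:
    def test_zero_weights_give_half(self):
        state, _ = tiny_state()
        state.W[:] = 0.0
        _, out = core.forward(state, np.zeros(6))
        assert np.allclose(out, 0.5)

    def test_single_output_dot_product(self):
        state, _ = tiny_state(n_in=2, n_hidden=2, n_out=1)
        state.W = np.array([[0.5, 0.25]])
        hidden = np.array([1.0, 2.0])
        out = sigmoid(state.W @ hidden)
        assert np.allclose(out, 1.0 / (1.0 + np.exp(-1.0)))
        assert abs(out[0] - 0.7311) < 1e-4

    def test_outputs_in_open_unit_interval(self):
        state, _ = tiny_state(seed=3)
        rng = np.random.default_rng(0)
        for _ in range(10):
            hidden, out = core.forward(state, rng.standard_normal(6))
            assert np.all((hidden > 0) & (hidden < 1))
            assert np.all((out > 0) & (out < 1))

    def test_shape_mismatch_rejected(self):
        state, _ = tiny_state()
        with pytest.raises(ValueError):
            core.forward(state, np.zeros(7))


class TestModulatoryActivation:
    def test_zero_error_gives_zero(self):
        state, _ = tiny_state()
        assert np.allclose(core.modulatory_activation(state, np.zeros(3)), 0.0)

    def test_identity_weights_pass_error_through(self):
        state, _ = tiny_state(n_out=2, n_hidden=2)
        state.W_mod = np.eye(2)
        e = np.array([1.0, -0.2])
        assert np.allclose(core.modulatory_activation(state, e), e)

    def test_matches_elementwise_loop(self):
        state, _ = tiny_state(seed=5)
        rng = np.random.default_rng(1)
        e = rng.standard_normal(3)
        M = core.modulatory_activation(state, e)
        expected = [sum(state.W_mod[i, j] * e[j] for j in range(3))
                    for i in range(3)]
        assert np.allclose(M, expected, atol=1e-12)


class TestPlasticityTerm:
    def test_only_bias_survives_without_activity(self):
        state, cfg = tiny_state()
        delta = core.plasticity_term(state, np.zeros(4), np.zeros(3), cfg)
        assert np.allclose(delta, state.eta * cfg.beta3)

    def test_hand_computed_value(self):
        state, cfg = tiny_state(n_hidden=3, n_out=3)
        state.eta[:] = 0.001
        delta = core.plasticity_term(
            state, np.full(3, 0.5), np.full(3, 0.8), cfg)
        # 0.001 * (0.1*0.8*0.5 + 0.2*(0.5-0.8) + 0.001) = -1.9e-5
        assert np.allclose(delta, -1.9e-5)

    def test_correlation_only_limit_sign(self):
        state, cfg = tiny_state(beta2=1e-12, beta3=1e-12)
        cfg.beta2 = cfg.beta3 = 0.0
        rng = np.random.default_rng(2)
        hidden, output = rng.random(4), rng.random(3)
        state.eta = rng.standard_normal((3, 4)) * 0.01
        delta = core.plasticity_term(state, hidden, output, cfg)
        assert np.array_equal(np.sign(delta),
                              np.sign(state.eta * output[:, None] * hidden[None, :]))


class TestAdaptiveRate:
    def test_zero_error_resets_to_initial(self):
        state, cfg = tiny_state()
        error = np.array([0.0, 0.5, 0.0])
        output = np.array([0.5, 0.5, 0.5])
        eta = core.adapt_learning_rate(state, error, output, cfg)
        assert np.allclose(np.abs(eta[0]), cfg.eta_in)
        assert np.allclose(np.abs(eta[2]), cfg.eta_in)

    def test_singularity_is_clipped(self):
        state, cfg = tiny_state()
        eta = core.adapt_learning_rate(
            state, np.array([1e-9, 1e-9, 1e-9]), np.full(3, 1e-0), cfg)
        assert np.all(np.abs(eta) <= cfg.eta_clip + 1e-15)
        assert np.allclose(np.abs(eta), cfg.eta_clip)

    def test_quotient_magnitude(self):
        state, cfg = tiny_state()
        eta = core.adapt_learning_rate(
            state, np.array([0.5, 0.5, 0.5]), np.array([0.4, 0.4, 0.4]), cfg)
        assert np.allclose(np.abs(eta), 0.005)   # 0.001 / 0.2

    def test_quotient_sign_follows_error(self):
        state, cfg = tiny_state()
        eta = core.adapt_learning_rate(
            state, np.array([0.3, -0.3, 0.3]), np.full(3, 0.5), cfg)
        assert np.all(eta[0] > 0) and np.all(eta[1] < 0)


class TestWeightUpdates:
    def test_zero_modulation_gives_half_gate(self):
        state, cfg = tiny_state()
        state.W_mod[:] = 0.0
        rng = np.random.default_rng(0)
        hidden, output = rng.random(4), rng.random(3)
        delta = core.plasticity_term(state, hidden, output, cfg)
        dW = core.update_standard_weights(state, hidden, output,
                                          np.zeros(3), cfg, delta=delta)
        assert np.allclose(dW, 0.5 * delta)

    def test_zero_plasticity_freezes_weights(self):
        state, cfg = tiny_state()
        W0 = state.W.copy()
        core.update_standard_weights(state, np.zeros(4), np.zeros(3),
                                     np.zeros(3), cfg,
                                     delta=np.zeros((3, 4)))
        assert np.array_equal(state.W, W0)

    def test_zero_error_freezes_modulatory_weights(self):
        state, cfg = tiny_state()
        W0 = state.W_mod.copy()
        core.update_modulatory_weights(state, np.zeros(3), np.full(3, 0.7), cfg)
        assert np.array_equal(state.W_mod, W0)

    def test_modulatory_update_sign_follows_error(self):
        state, cfg = tiny_state()
        e = np.array([0.4, -0.4, 0.1])
        dW = core.update_modulatory_weights(state, e, np.full(3, 0.7), cfg)
        assert np.all(np.sign(dW) == np.sign(e)[:, None])

    def test_modulatory_update_magnitude_2x2(self):
        state, cfg = tiny_state(n_out=2, n_hidden=2)
        e = np.array([0.5, -0.5])
        x = np.array([0.3, 0.9])
        dW = core.update_modulatory_weights(state, e, x, cfg)
        expected = np.sign(e)[:, None] * cfg.mod_eta_in * x[:, None] * cfg.mod_scale
        assert np.allclose(dW, expected)


class TestTraining:
    def test_learns_separable_task(self, sep_task, sep_test_set):
        cfg = ModNetConfig(n_in=100, n_out=10, n_hidden=1000, seed=1)
        state = core.init_state(cfg)
        state, hist = core.train(state, sep_task.features, sep_task.labels, cfg)
        Xte, yte = sep_test_set
        assert core.evaluate(state, Xte, yte) >= 0.90

    def test_null_task_stays_at_chance(self):
        task = synthetic.make_vector_task(2, 2, 300, 0.0, 1.0, seed=1)
        cfg = ModNetConfig(n_in=2, n_out=2, n_hidden=50, seed=0)
        state = core.init_state(cfg)
        state, _ = core.train(state, task.features, task.labels, cfg)
        X, y = synthetic.draw_samples(task, 500, seed=9)
        assert abs(core.evaluate(state, X, y) - 0.5) < 0.15

    def test_projection_is_frozen(self, sep_task):
        cfg = ModNetConfig(n_in=100, n_out=10, n_hidden=200, seed=2, epochs=1)
        state = core.init_state(cfg)
        W_proj0 = state.W_proj.copy()
        core.train(state, sep_task.features[:1000], sep_task.labels[:1000], cfg)
        assert np.array_equal(state.W_proj, W_proj0)

    def test_modulation_decays_as_learning_saturates(self, sep_task):
        """The mean |M| trace falls between early and late training on a
        learnable task: modulation rewards/penalises hardest early on."""
        cfg = ModNetConfig(n_in=100, n_out=10, n_hidden=500, seed=3)
        state = core.init_state(cfg)
        _, hist = core.train(state, sep_task.features, sep_task.labels, cfg)
        absM = hist["mean_abs_modulation"]
        q = len(absM) // 4
        assert absM[-q:].mean() < absM[:q].mean()

    def test_state_stays_finite_under_random_stress(self):
        state, cfg = tiny_state(n_in=5, n_hidden=8, n_out=3, seed=4)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10_000, 5)) * 3
        y = rng.integers(0, 3, size=10_000)
        cfg.epochs = 1
        state, _ = core.train(state, X, y, cfg)
        for arr in (state.W, state.W_mod, state.eta, state.mod_eta):
            assert np.all(np.isfinite(arr))

    def test_bad_labels_rejected(self):
        state, cfg = tiny_state()
        with pytest.raises(ValueError):
            core.train(state, np.zeros((4, 6)), np.array([0, 1, 2, 3]), cfg)

    def test_capacity_grows_with_hidden_dimension(self, sep_task, sep_test_set):
        """Expanding the random projection never hurts: 2,500 hidden units
        separate features at least as well as 100 (averaged over 5 seeds)."""
        Xte, yte = sep_test_set
        accs = {}
        for n_hidden in (100, 2500):
            runs = []
            for seed in range(5):
                cfg = ModNetConfig(n_in=100, n_out=10, n_hidden=n_hidden,
                                   seed=seed, epochs=1)
                state = core.init_state(cfg)
                state, _ = core.train(state, sep_task.features[:3000],
                                      sep_task.labels[:3000], cfg)
                runs.append(core.evaluate(state, Xte, yte))
            accs[n_hidden] = np.mean(runs)
        assert accs[2500] >= accs[100]
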