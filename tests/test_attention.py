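"""Region attention: activity factors, update scaling, inhibition and pruning;
the covariance rule; compartment gating; and the pruning behaviour of the
attention-only and compartmentalized variants during training."""

import numpy as np
import pytest

from modnet import attention, core, synthetic
from modnet.attention import (CompartmentConfig, CompartmentGater,
                              CompartmentalModNet, RegionAttention,
                              RegionPartition, TrainingError)


class TestActivityFactor:
    def test_uniform_activity_is_one(self):
        assert attention.activity_factor(np.full(10, 0.4)) == 1.0

    def test_hand_computed(self):
        assert attention.activity_factor([0.2, 0.4, 0.8, 0.6]) == \
            pytest.approx(0.625)

    def test_dead_region_is_zero(self):
        assert attention.activity_factor(np.zeros(8)) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            attention.activity_factor(np.array([]))

    def test_partitioned_window(self):
        part = RegionPartition(n_neurons=4, n_regions=2)
        window = np.array([[0.2, 0.4, 0.0, 0.0],
                           [0.8, 0.6, 0.0, 0.0]])
        A = attention.activity_factors(window, part)
        assert A[0] == pytest.approx(0.625)
        assert A[1] == 0.0


class TestUpdateScaling:
    def test_scaling_ratio(self):
        part = RegionPartition(n_neurons=4, n_regions=2)
        pending = np.ones((3, 4))
        out = attention.scale_update(pending, np.array([1.0, 0.5]), part)
        assert np.allclose(out[:, :2] / out[:, 2:], 2.0)

    def test_zero_activity_kills_update(self):
        part = RegionPartition(n_neurons=4, n_regions=2)
        out = attention.scale_update(np.ones((2, 4)), np.array([0.0, 1.0]), part)
        assert np.all(out[:, :2] == 0.0)

    def test_never_flips_sign(self):
        part = RegionPartition(n_neurons=6, n_regions=3)
        rng = np.random.default_rng(0)
        pending = rng.standard_normal((4, 6))
        out = attention.scale_update(pending, rng.random(3), part)
        assert np.all(out * pending >= 0)


class TestInhibition:
    def test_zero_weight_stays_zero(self):
        w = np.zeros((2, 3))
        new, pruned = attention.inhibition_step(w, 0.05, np.ones((2, 3)))
        assert np.all(new == 0.0)
        assert not pruned.any()

    def test_sign_preserving_decay_to_zero(self):
        w = np.array([[0.3, -0.3]])
        pending = np.full((1, 2), 0.5)
        for _ in range(100):
            w, pruned = attention.inhibition_step(w, 0.05, pending)
            assert w[0, 0] >= 0.0 and w[0, 1] <= 0.0
            if pruned.all():
                break
        assert np.all(w == 0.0)

    def test_decay_is_monotone(self):
        w = np.array([[0.4]])
        pending = np.array([[0.1]])
        mags = []
        for _ in range(10):
            w, _ = attention.inhibition_step(w, 0.08, pending)
            mags.append(abs(w[0, 0]))
        assert all(b <= a for a, b in zip(mags, mags[1:]))


class TestRegionAttentionHook:
    def make_hook(self, n_neurons=8, n_regions=2, eval_period=4, thr=0.5,
                  n_out=3, **kw):
        part = RegionPartition(n_neurons=n_neurons, n_regions=n_regions,
                               eval_period=eval_period,
                               activity_threshold=thr, **kw)
        return RegionAttention(part, n_out=n_out)

    def feed(self, hook, hidden, times):
        for _ in range(times):
            hook.observe(hidden)

    def test_dead_region_is_pruned_outright(self):
        """A region with zero activity across its whole window loses all its
        connections at the next update."""
        hook = self.make_hook()
        hidden = np.concatenate([np.full(4, 0.8), np.zeros(4)])
        self.feed(hook, hidden, 4)
        state = core.init_state(core.ModNetConfig(n_in=2, n_out=3, n_hidden=8))
        hook.transform_update(state, np.zeros((3, 8)))
        hook.enforce_pruned(state)
        assert np.all(state.W[:, 4:] == 0.0)
        assert hook.pruned[:, 4:].all()
        assert not hook.pruned[:, :4].any()

    def test_silent_region_fully_pruned_within_bounded_steps(self):
        """A persistently weak (sub-threshold but non-zero) region decays to
        100% pruned in finitely many update steps."""
        hook = self.make_hook(thr=0.9)
        state = core.init_state(core.ModNetConfig(n_in=2, n_out=3, n_hidden=8))
        weak = np.concatenate([np.full(4, 0.9),
                               np.array([0.02, 0.05, 0.3, 0.04])])
        pending = np.full((3, 8), 0.05)
        for step in range(3000):
            hook.observe(weak)
            dW = hook.transform_update(state, pending)
            state.W += dW
            hook.enforce_pruned(state)
            if hook.pruned[:, 4:].all():
                break
        assert hook.pruned[:, 4:].all()
        assert np.all(state.W[:, 4:] == 0.0)

    def test_sparse_init_marks_structural_zeros(self):
        part = RegionPartition(n_neurons=100, n_regions=5, alpha_init=0.4)
        hook = RegionAttention(part, n_out=2, seed=0)
        assert hook.pruned_fraction == pytest.approx(0.6)
        assert hook.rule_pruned_fraction == 0.0


class TestCovarianceRule:
    def test_pre_at_threshold_gives_zero_update(self):
        W = np.full((2, 2), 0.3)
        out = attention.covariance_update(W, np.full(2, 0.5), np.array([0.9, 0.1]),
                                          cov_eta=0.01)
        assert np.allclose(out, W)

    def test_hand_computed(self):
        W = np.array([[0.2]])
        out = attention.covariance_update(W, np.array([1.0]), np.array([1.0]),
                                          cov_eta=0.01, s1=0.5, s2=0.5)
        assert np.allclose(out - W, 5e-4)

    def test_zero_weight_never_revives(self):
        W = np.array([[0.0, 0.4]])
        rng = np.random.default_rng(0)
        for _ in range(50):
            W = attention.covariance_update(W, rng.random(2), rng.random(1),
                                            cov_eta=0.5)
        assert W[0, 0] == 0.0

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((3, 4))
        pre, post = rng.random(4), rng.random(3)
        got = attention.covariance_update(W, pre, post, 0.02, 0.4, 0.6)
        for i in range(3):
            for j in range(4):
                expected = W[i, j] + 0.02 * (pre[j] - 0.4) * (post[i] - 0.6) * W[i, j]
                assert abs(got[i, j] - expected) < 1e-12


class TestCompartmentGating:
    def test_dead_compartment_gated_after_two_evaluations(self):
        gater = CompartmentGater(3, threshold=0.2)
        active = gater.update(np.array([0.5, 0.0, 0.6]))
        assert active.all()                        # one strike only
        active = gater.update(np.array([0.5, 0.0, 0.6]))
        assert list(active) == [True, False, True]

    def test_recovery_resets_the_count(self):
        gater = CompartmentGater(1, threshold=0.2)
        gater.update(np.array([0.1]))
        gater.update(np.array([0.5]))              # recovered in between
        active = gater.update(np.array([0.1]))
        assert active[0]

    def test_equally_active_none_gated(self):
        active = attention.gate_compartments(
            np.tile(np.full(4, 0.6), (5, 1)), threshold=0.2)
        assert active.all()

    def test_gating_is_idempotent(self):
        gater = CompartmentGater(2, threshold=0.3)
        for _ in range(5):
            active = gater.update(np.array([0.5, 0.0]))
        assert list(active) == [True, False]

    def test_all_gated_is_an_error(self):
        with pytest.raises(TrainingError):
            attention.gate_compartments(np.zeros((2, 3)), threshold=0.2)


@pytest.fixture(scope="module")
def pruning_task():
    return synthetic.make_vector_task(10, 50, 600, separation=6.0,
                                      noise_sd=1.0, seed=31)


def attention_run(task, seed, alpha_init=1.0, thr=0.48, n_hidden=400,
                  epochs=4):
    cfg = core.ModNetConfig(n_in=task.dims, n_out=task.n_classes,
                            n_hidden=n_hidden, seed=seed, epochs=epochs)
    part = RegionPartition(n_neurons=n_hidden, n_regions=10,
                           activity_threshold=thr, alpha_init=alpha_init)
    hook = RegionAttention(part, n_out=task.n_classes, seed=seed)
    state = core.init_state(cfg)
    state, hist = core.train(state, task.features, task.labels, cfg,
                             attention=hook)
    return state, hook, hist


class TestTrainingBehaviour:
    def test_pruned_fraction_never_decreases(self, pruning_task):
        _, hook, hist = attention_run(pruning_task, seed=0)
        pf = hist["pruned_fraction"]
        assert len(pf) > 2
        assert np.all(np.diff(pf) >= 0)

    def test_accuracy_with_attention_close_to_baseline(self, pruning_task,
                                                       sep_task, sep_test_set):
        """Attention trades connections for efficiency at a small accuracy
        cost: within 5 points of the unattended network on the same task."""
        Xte, yte = synthetic.draw_samples(pruning_task, 100, seed=500)
        cfg = core.ModNetConfig(n_in=50, n_out=10, n_hidden=400, seed=3,
                                epochs=4)
        base_state = core.init_state(cfg)
        base_state, _ = core.train(base_state, pruning_task.features,
                                   pruning_task.labels, cfg)
        base_acc = core.evaluate(base_state, Xte, yte)
        att_state, hook, _ = attention_run(pruning_task, seed=3)
        att_acc = core.evaluate(att_state, Xte, yte)
        assert att_acc >= base_acc - 0.05

    def test_self_regulating_sparsity(self, pruning_task):
        """Rule-driven pruning converges to a similar fraction of the existing
        connections whether the readout starts dense or 50% disconnected."""
        _, dense, _ = attention_run(pruning_task, seed=5, alpha_init=1.0)
        _, sparse, _ = attention_run(pruning_task, seed=5, alpha_init=0.5)
        diff = abs(dense.rule_pruned_fraction - sparse.rule_pruned_fraction)
        assert diff < 0.15

    def test_compartments_prune_more_than_attention_alone(self, pruning_task):
        """Matched runs: the compartmentalized network (extra layer, gating)
        removes a larger fraction of its connections than region attention on
        the shallow network."""
        for seed in (0, 1):
            _, hook, _ = attention_run(pruning_task, seed=seed)
            ccfg = CompartmentConfig(
                n_in=pruning_task.dims, n_out=pruning_task.n_classes,
                n_hidden1=400, n_hidden2=400, epochs=4, seed=seed,
                activity_threshold=0.48, gating_threshold=0.48)
            net = CompartmentalModNet(ccfg)
            net.train(pruning_task.features, pruning_task.labels)
            assert net.pruned_fraction >= hook.pruned_fraction

    def test_compartment_history_is_recorded(self, pruning_task):
        ccfg = CompartmentConfig(
            n_in=pruning_task.dims, n_out=pruning_task.n_classes,
            n_hidden1=200, n_hidden2=200, epochs=1, seed=2,
            activity_threshold=0.48, gating_threshold=0.42)
        net = CompartmentalModNet(ccfg)
        hist = net.train(pruning_task.features[:1200],
                         pruning_task.labels[:1200])
        assert hist["activity_h1"].shape[1] == 10
        assert np.all(np.diff(hist["pruned_fraction"]) >= -1e-12)
        assert np.all((hist["activity_h1"] >= 0) & (hist["activity_h1"] <= 1))
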