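"""Unit, oracle and property tests for the spiking-network core."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from astrosnn.datasets import generate
from astrosnn.harness import (ExperimentConfig, _child, assign_classes,
                              response_counts, train_snn)
from astrosnn.snn import (LifParams, LifState, NetworkConfig, StdpTraces,
                          WeightMatrix, lif_step, normalize_weights,
                          poisson_encode, run_batch, stdp_update,
                          threshold_step, trace_step)


def _lif(**kw):
    return LifParams(**kw)


class TestLif:
    def test_rest_is_fixed_point(self):
        p = _lif()
        s = LifState.resting(1, 3, p)
        for _ in range(50):
            lif_step(s, np.zeros((1, 3)), p)
        np.testing.assert_array_equal(s.v, p.v_rest)

    def test_constant_drive_steady_state(self):
        """Euler steady state: v -> v_rest + I * tau/dt (subthreshold)."""
        p = _lif()
        s = LifState.resting(1, 1, p)
        s.theta[:] = 1e6  # no spiking
        drive = np.full((1, 1), 0.05)
        for _ in range(5000):
            lif_step(s, drive, p)
        assert s.v[0, 0] == pytest.approx(p.v_rest + 0.05 * p.tau_mem / p.dt,
                                          rel=1e-6)

    def test_spike_reset_and_refractory_five_ms(self):
        p = _lif()  # delta_ref = 5 ms
        s = LifState.resting(1, 1, p)
        s.v[0, 0] = p.theta0 + 1.0
        lif_step(s, np.zeros((1, 1)), p)
        assert s.spiked[0, 0]
        assert s.v[0, 0] == p.v_reset
        big = np.full((1, 1), 100.0)
        for _ in range(5):  # 5 ms: inputs ignored, held at reset
            lif_step(s, big, p)
            assert not s.spiked[0, 0]
            assert s.v[0, 0] == p.v_reset
        lif_step(s, big, p)
        assert s.spiked[0, 0]

    def test_non_finite_drive_identifies_neuron(self):
        p = _lif()
        s = LifState.resting(1, 4, p)
        drive = np.zeros((1, 4))
        drive[0, 2] = np.inf
        with pytest.raises(FloatingPointError, match="2"):
            lif_step(s, drive, p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LifParams(theta0=-70.0)  # below rest
        with pytest.raises(ValueError):
            LifParams(tau_mem=0.0)


class TestThreshold:
    def test_base_threshold_is_theta0(self):
        """With theta=0 the firing threshold sits at theta0 = -52 mV."""
        p = _lif()
        s = LifState.resting(1, 1, p)
        a = p.dt / p.tau_mem
        v_crit = (p.theta0 - a * p.v_rest) / (1 - a)  # reaches theta0 post-leak
        s.v[0, 0] = v_crit - 1e-6
        lif_step(s, np.zeros((1, 1)), p)
        assert not s.spiked[0, 0]
        s.v[0, 0] = v_crit + 1e-6
        lif_step(s, np.zeros((1, 1)), p)
        assert s.spiked[0, 0]

    def test_spike_increments_theta_by_table_constant(self):
        p = _lif()
        s = LifState.resting(1, 2, p)
        s.spiked = np.array([[True, False]])
        threshold_step(s, p)
        assert s.theta[0] == pytest.approx(0.05, rel=1e-9)
        assert s.theta[1] == pytest.approx(0.0, abs=1e-12)

    def test_exponential_decay_over_tau_theta(self):
        p = _lif(tau_theta=100.0)
        s = LifState.resting(1, 1, p)
        s.theta[:] = 2.0
        s.spiked[...] = False
        for _ in range(100):
            threshold_step(s, p)
        assert s.theta[0] == pytest.approx(2.0 * np.exp(-1), rel=1e-9)

    def test_frozen_theta_untouched(self):
        p = _lif()
        s = LifState.resting(1, 1, p)
        s.theta[:] = 1.0
        s.spiked[...] = True
        threshold_step(s, p, frozen=True)
        assert s.theta[0] == 1.0


class TestTraces:
    def test_spike_sets_trace_to_one(self):
        tr = StdpTraces.zeros(1, 2, 2)
        tr.x_pre[0, 0] = 0.37
        trace_step(tr, np.array([[True, False]]), np.array([[False, True]]))
        assert tr.x_pre[0, 0] == 1.0
        assert tr.x_post[0, 1] == 1.0

    def test_decay_to_inverse_e_after_tau(self):
        tr = StdpTraces.zeros(1, 1, 1, tau_trace=20.0)
        tr.x_pre[:] = 1.0
        no = np.array([[False]])
        for _ in range(20):
            trace_step(tr, no, no)
        assert tr.x_pre[0, 0] == pytest.approx(np.exp(-1), rel=1e-9)

    def test_toy_spike_train_matches_event_driven_oracle(self):
        """Per-step simulation equals closed-form e^{-dt/tau} evaluation at
        event times for a fixed printed spike train."""
        spikes = [0, 3, 4, 9, 15]
        tau = 20.0
        tr = StdpTraces.zeros(1, 1, 1, tau_trace=tau)
        values = []
        for t in range(20):
            pre = np.array([[t in spikes]])
            trace_step(tr, pre, np.array([[False]]))
            values.append(tr.x_pre[0, 0])
        # oracle: trace(t) = exp(-(t - t_last_spike)/tau)
        for t in range(20):
            last = max(s for s in spikes if s <= t)
            assert values[t] == pytest.approx(np.exp(-(t - last) / tau),
                                              rel=1e-9)

    @given(st.lists(st.integers(0, 1), min_size=5, max_size=40))
    def test_trace_bounds(self, raster):
        tr = StdpTraces.zeros(1, 1, 1)
        for bit in raster:
            trace_step(tr, np.array([[bool(bit)]]), np.array([[False]]))
            assert 0.0 <= tr.x_pre[0, 0] <= 1.0


class TestStdp:
    def test_post_spike_potentiation_product(self):
        w = WeightMatrix(np.full((1, 1), 0.3))
        tr = StdpTraces.zeros(1, 1, 1, eta_post=1e-2)
        tr.x_pre[:] = 0.5
        stdp_update(w, tr, np.array([[0.0]]), np.array([[1.0]]))
        assert w.w[0, 0] == pytest.approx(0.3 + 5e-3, rel=1e-12)

    def test_pre_spike_with_zero_post_trace_is_noop(self):
        w = WeightMatrix(np.full((1, 1), 0.3))
        tr = StdpTraces.zeros(1, 1, 1)
        stdp_update(w, tr, np.array([[1.0]]), np.array([[0.0]]))
        assert w.w[0, 0] == 0.3

    def test_random_raster_matches_hand_replay_oracle(self, rng):
        """20 steps on a 3x2 net equal a scalar step-by-step replay."""
        n_in, n_out, T = 3, 2, 20
        pre = rng.random((T, n_in)) < 0.4
        post = rng.random((T, n_out)) < 0.3
        w0 = rng.uniform(0.2, 0.8, (n_in, n_out))

        w = WeightMatrix(w0.copy())
        tr = StdpTraces.zeros(1, n_in, n_out)
        for t in range(T):
            trace_step(tr, pre[None, t], post[None, t])
            stdp_update(w, tr, pre[None, t].astype(float),
                        post[None, t].astype(float))

        # independent scalar oracle
        ow = w0.copy()
        xp, xq = np.zeros(n_in), np.zeros(n_out)
        decay = np.exp(-1.0 / 20.0)
        for t in range(T):
            for i in range(n_in):
                xp[i] = 1.0 if pre[t, i] else xp[i] * decay
            for j in range(n_out):
                xq[j] = 1.0 if post[t, j] else xq[j] * decay
            for j in range(n_out):
                if post[t, j]:
                    for i in range(n_in):
                        ow[i, j] += 1e-2 * xp[i]
            for i in range(n_in):
                if pre[t, i]:
                    for j in range(n_out):
                        ow[i, j] -= 1e-4 * xq[j]
            ow = np.clip(ow, 0.0, 1.0)
        np.testing.assert_allclose(w.w, ow, atol=1e-9)

    def test_dead_synapses_never_move(self, rng):
        mask = rng.random((4, 3)) < 0.5
        w = WeightMatrix(rng.uniform(0, 1, (4, 3)) * mask, fault_mask=mask)
        tr = StdpTraces.zeros(1, 4, 3)
        tr.x_pre[:] = 0.7
        tr.x_post[:] = 0.7
        stdp_update(w, tr, np.ones((1, 4)), np.ones((1, 3)))
        assert np.all(w.w[~mask] == 0.0)
        assert w.w.min() >= 0.0 and w.w.max() <= w.w_max


class TestNormalize:
    def test_table_normalization_factor(self):
        w = WeightMatrix(np.array([[10.0, 20.0]]), w_norm=78.4, w_max=100.0)
        normalize_weights(w)
        np.testing.assert_allclose(w.w, [[78.4, 78.4]], rtol=1e-12)

    def test_idempotent(self, rng):
        w = WeightMatrix(rng.uniform(0, 1, (30, 4)), w_norm=12.0)
        normalize_weights(w)
        before = w.w.copy()
        normalize_weights(w)
        np.testing.assert_allclose(w.w, before, rtol=1e-12)

    def test_live_column_sums_exact(self, rng):
        for _ in range(20):
            mask = rng.random((64, 8)) < 0.7
            w = WeightMatrix(rng.uniform(0, 1, (64, 8)) * mask,
                             fault_mask=mask, w_norm=7.0)
            normalize_weights(w)
            np.testing.assert_allclose(w.w.sum(axis=0), 7.0, rtol=1e-9)
            assert np.all(w.w[~mask] == 0.0)

    def test_all_zero_column_skipped(self, caplog):
        w = WeightMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]), w_norm=4.0,
                         w_max=10.0)
        with caplog.at_level("WARNING"):
            normalize_weights(w)
        assert "all-zero" in caplog.text
        np.testing.assert_allclose(w.w[:, 0], [2.0, 2.0])
        np.testing.assert_allclose(w.w[:, 1], 0.0)

    def test_bound_respected_when_few_synapses_survive(self):
        w = WeightMatrix(np.array([[0.5], [0.5]]), w_norm=78.4, w_max=1.0)
        normalize_weights(w)
        assert w.w.max() <= 1.0


class TestPoissonEncoding:
    def _cfg(self, **kw):
        kw.setdefault("n_input", 4)
        kw.setdefault("n_neurons", 2)
        return NetworkConfig(**kw)

    def test_zero_image_empty_raster(self, rng):
        raster = poisson_encode(np.zeros(4), self._cfg(), rng)
        assert raster.sum() == 0

    def test_max_intensity_rate_within_binomial_bounds(self, rng):
        cfg = self._cfg(exposure_ms=350.0, max_rate_hz=63.75)
        counts = [poisson_encode(np.full(4, 255.0), cfg, rng).sum(axis=0).mean()
                  for _ in range(200)]
        expected = 63.75 * 0.350
        p = 63.75 / 1000.0
        sigma = np.sqrt(cfg.n_steps * p * (1 - p) / (4 * 200))
        assert abs(np.mean(counts) - expected) < 3 * sigma

    def test_same_seed_identical_raster(self):
        cfg = self._cfg()
        img = np.array([10.0, 100.0, 200.0, 255.0])
        a = poisson_encode(img, cfg, np.random.default_rng(5))
        b = poisson_encode(img, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_out_of_range_intensity_rejected(self, rng):
        with pytest.raises(ValueError):
            poisson_encode(np.array([0.0, 300.0, 0.0, 0.0]), self._cfg(), rng)


def _scalar_reference(raster, w0, mask, theta0, lif, tau_trace, eta_pre,
                      eta_post, w_max, w_rec, learning):
    """Deliberately simple non-vectorized reference simulator (the oracle)."""
    B, T, n_in = raster.shape
    n_out = w0.shape[1]
    w = w0.copy()
    theta = theta0.copy()
    v = np.full((B, n_out), lif.v_rest)
    refrac = np.zeros((B, n_out))
    xp = np.zeros((B, n_in))
    xq = np.zeros((B, n_out))
    prev = np.zeros((B, n_out), dtype=bool)
    counts = np.zeros((B, n_out))
    decay = np.exp(-lif.dt / tau_trace)
    th_decay = np.exp(-lif.dt / lif.tau_theta)
    for t in range(T):
        spiked = np.zeros((B, n_out), dtype=bool)
        for b in range(B):
            for j in range(n_out):
                drive = w_rec * (prev[b].sum() - prev[b, j])
                for i in range(n_in):
                    if raster[b, t, i]:
                        drive += w[i, j]
                if refrac[b, j] > 0:
                    v[b, j] = lif.v_reset
                    refrac[b, j] = max(refrac[b, j] - lif.dt, 0.0)
                else:
                    v[b, j] += (lif.dt / lif.tau_mem) * (lif.v_rest - v[b, j])
                    v[b, j] += drive
                    if v[b, j] >= lif.theta0 + theta[j]:
                        spiked[b, j] = True
                        v[b, j] = lif.v_reset
                        refrac[b, j] = lif.delta_ref
                        counts[b, j] += 1
        if learning:
            theta = theta * th_decay + lif.theta_plus * spiked.sum(axis=0)
        for b in range(B):
            for i in range(n_in):
                xp[b, i] = 1.0 if raster[b, t, i] else xp[b, i] * decay
            for j in range(n_out):
                xq[b, j] = 1.0 if spiked[b, j] else xq[b, j] * decay
        if learning:
            dw = np.zeros_like(w)
            for b in range(B):
                for j in range(n_out):
                    if spiked[b, j]:
                        for i in range(n_in):
                            dw[i, j] += eta_post * xp[b, i]
                for i in range(n_in):
                    if raster[b, t, i]:
                        for j in range(n_out):
                            dw[i, j] -= eta_pre * xq[b, j]
            w = np.clip(w + dw, 0.0, w_max) * mask
        prev = spiked
    return counts, w, theta


class TestRunBatch:
    def _setup(self, rng, B=2, n_in=5, n_out=2, T=50):
        raster = rng.random((B, T, n_in)) < 0.25
        mask = rng.random((n_in, n_out)) < 0.9
        w = WeightMatrix(rng.uniform(0.5, 4.0, (n_in, n_out)) * mask,
                         fault_mask=mask, w_max=5.0, w_norm=10.0,
                         w_recurrent=-3.0)
        lif = LifParams(tau_theta=50.0)
        state = LifState.resting(B, n_out, lif)
        traces = StdpTraces.zeros(B, n_in, n_out)
        return raster, w, state, traces, lif

    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    @pytest.mark.parametrize("learning", [False, True])
    def test_matches_scalar_reference(self, rng, backend, learning):
        """5-input/2-output network over 50 steps equals the non-vectorized
        reference to floating-point tolerance."""
        raster, w, state, traces, lif = self._setup(rng)
        ref_counts, ref_w, ref_theta = _scalar_reference(
            raster, w.w, w.fault_mask, state.theta, lif, traces.tau_trace,
            traces.eta_pre, traces.eta_post, w.w_max, w.w_recurrent, learning)
        counts = run_batch(raster, w, state, traces, lif, learning=learning,
                           backend=backend)
        np.testing.assert_allclose(counts, ref_counts, atol=0)
        np.testing.assert_allclose(w.w, ref_w, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(state.theta, ref_theta, rtol=1e-9)

    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    def test_learning_off_leaves_weights_bit_identical(self, rng, backend):
        raster, w, state, traces, lif = self._setup(rng)
        before = w.w.copy()
        theta_before = state.theta.copy()
        run_batch(raster, w, state, traces, lif, learning=False,
                  backend=backend)
        assert np.array_equal(w.w, before)
        assert np.array_equal(state.theta, theta_before)

    def test_batch_independence_when_not_learning(self, rng):
        """An image simulated alone equals the same image inside a batch of
        duplicates (private replica state)."""
        raster, w, state, traces, lif = self._setup(rng, B=1)
        c1 = run_batch(raster, w, state, traces, lif, learning=False)
        B = 4
        rep = np.repeat(raster, B, axis=0)
        state4 = LifState.resting(B, 2, lif)
        traces4 = StdpTraces.zeros(B, 5, 2)
        c4 = run_batch(rep, w, state4, traces4, lif, learning=False)
        for b in range(B):
            np.testing.assert_array_equal(c4[b], c1[0])

    def test_soft_wta_winner_dominates(self, rng):
        """Identical strong images + strong inhibition: the top responder's
        count is >= any other neuron's for every replica."""
        n_in, n_out, B, T = 16, 8, 4, 200
        raster = np.repeat(rng.random((1, T, n_in)) < 0.3, B, axis=0)
        w = WeightMatrix(rng.uniform(0, 1, (n_in, n_out)), w_max=1.0,
                         w_norm=8.0, w_recurrent=-120.0)
        normalize_weights(w)
        lif = LifParams()
        state = LifState.resting(B, n_out, lif)
        traces = StdpTraces.zeros(B, n_in, n_out)
        counts = run_batch(raster, w, state, traces, lif, learning=False)
        for b in range(B):
            winner = counts[b].max()
            assert winner > 0
            assert (counts[b] <= winner).all()

    def test_dimension_mismatch_rejected(self, rng):
        raster, w, state, traces, lif = self._setup(rng)
        with pytest.raises(ValueError):
            run_batch(raster[:, :, :3], w, state, traces, lif)


@pytest.fixture(scope="module")
def quick_training():
    """One epoch on the default synthetic task (the learnability gate)."""
    cfg = ExperimentConfig(seed=3)
    data = generate(cfg.synth)
    ss = np.random.SeedSequence(3)
    w, theta, _ = train_snn(data.train_images, cfg, _child(ss, 2), epochs=1)
    return cfg, data, w, theta


class TestUnsupervisedLearning:
    def test_exceeds_five_times_chance_after_one_epoch(self, quick_training):
        cfg, data, w, theta = quick_training
        rng = np.random.default_rng(99)
        traces = cfg.traces_template()
        counts = response_counts(data.train_images[:400], w, theta, cfg.net,
                                 cfg.lif, traces, rng)
        lab = assign_classes(counts, data.train_labels[:400], 10)
        test_counts = response_counts(data.test_images, w, theta, cfg.net,
                                      cfg.lif, traces, rng)
        from astrosnn.harness import predict

        acc = 100.0 * np.mean(predict(test_counts, lab) == data.test_labels)
        assert acc > 50.0  # 5x chance on the 10-class task

    def test_weight_columns_correlate_with_assigned_templates(self, quick_training):
        """>= 75% of responsive neurons develop receptive fields matching
        their assigned class template (Pearson r > 0.5)."""
        cfg, data, w, theta = quick_training
        rng = np.random.default_rng(7)
        traces = cfg.traces_template()
        counts = response_counts(data.train_images[:400], w, theta, cfg.net,
                                 cfg.lif, traces, rng)
        lab = assign_classes(counts, data.train_labels[:400], 10)
        flat_templates = data.templates.reshape(10, -1)
        good = total = 0
        for j in range(cfg.net.n_neurons):
            if lab.inactive[j]:
                continue
            total += 1
            r = np.corrcoef(w.w[:, j], flat_templates[lab.labels[j]])[0, 1]
            good += r > 0.5
        assert total > 0
        assert good / total >= 0.75
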