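"""Oja-style Hebbian tactile-to-motor learning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somadev.spinal_plasticity import (RunningPercentileNormalizer,
                                       SpinalWeights, hebbian_update,
                                       spinal_drive)


class TestHebbianUpdate:
    def test_zero_tactile_only_decays(self, rng):
        w = SpinalWeights.zeros(5, 3, init_sd=0.2, seed=0)
        before = w.W_alpha.copy()
        hebbian_update(w, np.zeros(5), rng.random(3), lr=0.1)
        assert np.all(w.W_alpha <= before + 1e-12)

    def test_scalar_oja_fixed_point_monotone(self):
        # one taxel and one muscle co-active at 1: dW = lr (1 - W),
        # approaching the normalized fixed point W* = 1 monotonically
        w = SpinalWeights(W_alpha=np.zeros((1, 1)), W_osc=np.zeros((1, 1)),
                          w_max=2.0)
        history = []
        for _ in range(200):
            hebbian_update(w, [1.0], [1.0], lr=0.05)
            history.append(w.W_alpha[0, 0])
        history = np.asarray(history)
        assert np.all(np.diff(history) >= -1e-12)
        assert history[-1] == pytest.approx(1.0, abs=1e-3)

    def test_mean_drift_matches_analytic_expectation(self, rng):
        # independent uniform pre/post streams: E[dW] = lr*(E[pre]E[post]
        # - E[post^2] W); verify at W=0 over 1e4 steps
        lr = 1e-3
        n_steps = 10_000
        w = SpinalWeights.zeros(4, 4)
        total = 0.0
        predicted = 0.0
        for _ in range(n_steps):
            pre = rng.random(4)
            post = rng.random(4)
            before = w.W_alpha.mean()
            # E[dW] = lr*(E[pre]E[post] - E[post^2] W) with E=1/2, E2=1/3
            predicted += lr * (0.25 - before / 3.0)
            hebbian_update(w, pre, post, lr)
            total += w.W_alpha.mean() - before
        assert total == pytest.approx(predicted, rel=0.05)

    def test_shape_mismatch_rejected(self):
        w = SpinalWeights.zeros(5, 3)
        with pytest.raises(ValueError):
            hebbian_update(w, np.zeros(4), np.zeros(3), 0.1)

    @given(seed=st.integers(0, 2 ** 16))
    @settings(max_examples=10, deadline=None)
    def test_boundedness_under_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        w = SpinalWeights.zeros(6, 4, init_sd=0.3, seed=seed, w_max=1.0)
        for _ in range(1000):
            hebbian_update(w, rng.random(6), rng.random(4), lr=0.05)
            assert np.all(w.W_alpha >= 0) and np.all(w.W_alpha <= 1.0)
            assert np.all(w.W_osc >= 0) and np.all(w.W_osc <= 1.0)


class TestSpinalDrive:
    def test_zero_weights_zero_drive(self):
        w = SpinalWeights.zeros(5, 3)
        assert np.allclose(spinal_drive(w, np.ones(5)), 0.0)

    def test_gain_tripling_scales_presquash_drive(self, rng):
        tac = rng.random(5)
        w1 = SpinalWeights.zeros(5, 3, init_sd=0.2, seed=1, gain=1.0)
        w3 = SpinalWeights(W_alpha=w1.W_alpha.copy(), W_osc=w1.W_osc.copy(),
                           gain=3.0)
        pre1 = np.arctanh(spinal_drive(w1, tac))
        pre3 = np.arctanh(spinal_drive(w3, tac))
        assert pre3 == pytest.approx(3 * pre1)

    def test_saturating_input_bounded(self):
        w = SpinalWeights(W_alpha=np.full((50, 2), 1.0),
                          W_osc=np.zeros((50, 2)), gain=10.0)
        out = spinal_drive(w, np.full(50, 1.0))
        assert np.all(out <= 1.0)


def test_running_percentile_normalizer_scale_free(rng):
    norm = RunningPercentileNormalizer()
    small = rng.random(20) * 0.01
    for _ in range(50):
        norm.update(small)
    out_small = norm.update(small)
    norm2 = RunningPercentileNormalizer()
    for _ in range(50):
        norm2.update(small * 1000)
    out_big = norm2.update(small * 1000)
    assert np.allclose(out_small, out_big, atol=0.05)


def test_closed_loop_tactile_motor_correlation_grows(uterus_env, fetus_body):
    """Early learning strengthens the tactile-motor coupling (majority of
    seeds show a non-decreasing windowed correlation)."""
    from somadev.controllers import SpinalController
    from somadev.embodiment import compiled, simulate

    cb = compiled(fetus_body)
    wins = 0
    seeds = (0, 1, 2, 3, 4)
    for seed in seeds:
        w = SpinalWeights.zeros(cb.n_taxels, cb.n_muscles, gain=2.0)
        ctrl = SpinalController(cb.n_muscles, weights=w, learning_rate=2e-4,
                                seed=seed)
        traj = simulate(fetus_body, uterus_env, ctrl, 20.0, dt=0.004,
                        seed=seed)
        tac = traj.tactile.sum(axis=1)
        act = traj.motor.sum(axis=1)
        def corr(sl):
            return np.corrcoef(tac[sl], act[sl])[0, 1]
        first = corr(slice(100, 600))        # before weights have grown
        early = max(corr(slice(600, 1100)),  # during early learning
                    corr(slice(1100, 1600)))
        wins += early >= first - 0.02
    assert wins > len(seeds) / 2
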