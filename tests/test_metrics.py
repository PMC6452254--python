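"""Dynamical and behavioural statistics against analytic oracles."""

import numpy as np
import pytest

from somadev import metrics
from somadev.fixtures import synth_oscillatory_signals


class TestLyapunov:
    def test_alpha_two_matches_tent_map_conjugacy(self):
        # at alpha=2 the map is conjugate to the tent map: exponent ln 2
        lam = metrics.largest_lyapunov_map(2.0)
        assert lam == pytest.approx(np.log(2), rel=0.01)

    def test_periodic_regime_is_negative(self):
        assert metrics.largest_lyapunov_map(1.0) < 0

    def test_short_orbits_rejected(self):
        with pytest.raises(ValueError):
            metrics.largest_lyapunov_map(1.5, n_iter=100)

    def test_onset_bisection(self):
        onset = metrics.chaos_onset_alpha()
        assert onset == pytest.approx(1.4011, abs=0.01)


class TestPhaseSync:
    def test_identical_sinusoids_fully_locked(self):
        x = synth_oscillatory_signals(3, 2.0, seed=0)
        plv = metrics.phase_sync_matrix(np.stack([x[0]] * 3))
        assert np.allclose(plv, 1.0, atol=1e-6)

    def test_constant_phase_offset_invariance(self):
        x = synth_oscillatory_signals(2, 2.0, phase_offsets=[0.0, np.pi / 2],
                                      seed=0)
        plv = metrics.phase_sync_matrix(x)
        assert plv[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_matrix_symmetry(self, rng):
        x = rng.standard_normal((4, 512))
        plv = metrics.phase_sync_matrix(x)
        assert np.allclose(plv, plv.T)

    def test_independent_noise_below_surrogate_bound(self, rng):
        x = rng.standard_normal((4, 2048))
        plv = metrics.phase_sync_matrix(x)
        iu = np.triu_indices(4, 1)
        bound = metrics.surrogate_plv_bound(x, n_surrogates=49, seed=1)
        assert np.nanmean(plv[iu]) <= bound + 0.05

    def test_constant_channel_flagged_nan(self):
        x = np.vstack([np.sin(np.linspace(0, 20, 400)), np.ones(400)])
        plv = metrics.phase_sync_matrix(x)
        assert np.isnan(plv[0, 1]) and np.isnan(plv[1, 1])

    def test_pattern_similarity_detects_relabelled_constellation(self):
        x = synth_oscillatory_signals(4, 3.0, phase_offsets=[0, 1, 2, 3],
                                      duration=20.0, seed=0)
        # constellation is stable, so similarity to the early reference ~1
        t, sim = metrics.phase_pattern_similarity(x, 100.0, (1.0, 3.0))
        assert np.nanmean(sim[(t > 4) & (t < 18)]) > 0.95


class TestDFA:
    def test_white_noise_exponent(self, rng):
        x = rng.standard_normal(4096)
        assert metrics.dfa_exponent(x) == pytest.approx(0.5, abs=0.05)

    def test_random_walk_exponent(self, rng):
        x = np.cumsum(rng.standard_normal(4096))
        assert metrics.dfa_exponent(x) == pytest.approx(1.5, abs=0.1)

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError):
            metrics.dfa_exponent(np.ones(4096))

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            metrics.dfa_exponent(rng.standard_normal(2048), windows=[8, 16])


class TestJerkEvents:
    def test_constant_velocity_has_no_events(self):
        theta = np.linspace(0, 10, 2000)
        assert metrics.jerk_event_rate(theta[None, :], 100.0, 1.0) == 0.0

    def test_injected_pulses_counted_exactly(self):
        fs = 100.0
        theta = np.zeros(3000)
        t = np.arange(3000) / fs
        for t0 in (5.0, 12.0, 20.0):  # three acceleration bumps
            theta += 0.5 * np.exp(-((t - t0) / 0.05) ** 2)
        ev = metrics.jerk_event_times(theta[None, :], fs, accel_threshold=50.0)
        assert len(ev) == 3

    def test_monotone_in_threshold(self, rng):
        theta = np.cumsum(rng.standard_normal(2000)) / 50
        r_low = metrics.jerk_event_rate(theta[None, :], 100.0, 10.0)
        r_high = metrics.jerk_event_rate(theta[None, :], 100.0, 1e9)
        assert r_high == 0.0 and r_low >= r_high


class TestSegregation:
    def test_orthogonal_one_hot_maps(self):
        maps = {"a": [1, 0, 0], "b": [0, 1, 0], "c": [0, 0, 1]}
        assert metrics.segregation_index(maps).value == pytest.approx(1.0)

    def test_identical_maps(self):
        maps = {"a": [1, 2, 3], "b": [1, 2, 3]}
        assert metrics.segregation_index(maps).value == pytest.approx(0.0)

    def test_sixty_degree_maps(self):
        # unit vectors at 60 degrees: cosine 0.5 -> segregation 0.5
        maps = {"a": [1.0, 0.0], "b": [0.5, np.sqrt(3) / 2]}
        assert metrics.segregation_index(maps).value == pytest.approx(0.5)

    def test_positive_rescaling_invariance(self, rng):
        a, b = rng.random(16), rng.random(16)
        s1 = metrics.segregation_index({"a": a, "b": b}).value
        s2 = metrics.segregation_index({"a": 7.3 * a, "b": 0.2 * b}).value
        assert s1 == pytest.approx(s2)

    def test_zero_map_excluded_and_reported(self):
        score = metrics.segregation_index(
            {"a": [1, 0], "b": [0, 1], "c": [0, 0]})
        assert ("a", "c") in score.excluded_pairs
        assert score.value == pytest.approx(1.0)


class TestMultimodalIndex:
    def test_equal_vectors_additive_case(self):
        r = np.array([1.0, 1.0])
        # combined equals the sum of two identical unimodal responses
        assert metrics.multimodal_index(2 * r, [r, r]) == pytest.approx(1.0)

    def test_linear_in_numerator(self, rng):
        c = rng.random(8)
        u = [rng.random(8), rng.random(8)]
        assert metrics.multimodal_index(2 * c, u) == pytest.approx(
            2 * metrics.multimodal_index(c, u))

    def test_zero_unimodal_flagged(self):
        with pytest.raises(ValueError):
            metrics.multimodal_index(np.ones(3), [np.zeros(3)])


class TestOnset:
    def test_flat_series_no_onset(self):
        t = np.arange(0, 100, 5.0)
        assert metrics.onset_time(t, np.full(len(t), 3.0), (0, 20)) is None

    def test_step_function_found_within_one_window(self):
        t = np.arange(0, 100, 5.0)
        r = np.where(t >= 50, 10.0, 0.5)
        onset = metrics.onset_time(t, r, (0, 20), m=2)
        assert onset is not None and abs(onset - 50) <= 5.0

    def test_ordering_of_two_steps(self):
        t = np.arange(0, 100, 5.0)
        a = np.where(t >= 30, 10.0, 0.1)
        b = np.where(t >= 60, 10.0, 0.1)
        oa = metrics.onset_time(t, a, (0, 20), m=2)
        ob = metrics.onset_time(t, b, (0, 20), m=2)
        assert oa < ob
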