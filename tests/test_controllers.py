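"""Chaotic-map elements, BVP oscillators and the spinal circuit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somadev.controllers import (BVP_REST, BVPUnit, ChaoticController,
                                 ChaoticUnit, DomainError, SpinalController,
                                 SpinalUnit, bvp_step, chaotic_controller_step,
                                 logistic_step, spinal_step)


class TestLogisticStep:
    @pytest.mark.parametrize("x, alpha, expected", [
        (0.0, 1.8, 1.0),          # f(0) = 1 for any alpha
        (1.0, 2.0, -1.0),         # boundary of the invariant interval
        (0.1, 2.0, 0.98),         # hand arithmetic
    ])
    def test_values(self, x, alpha, expected):
        assert logistic_step(x, alpha) == pytest.approx(expected)

    def test_two_iterates_hand_arithmetic(self):
        x1 = logistic_step(0.1, 2.0)
        assert logistic_step(x1, 2.0) == pytest.approx(-0.9208)

    @pytest.mark.parametrize("x, alpha", [(0.5, 2.5), (0.5, -0.1), (1.5, 1.0)])
    def test_domain_errors_name_the_value(self, x, alpha):
        with pytest.raises(DomainError):
            logistic_step(x, alpha)

    @given(x=st.floats(-1.0, 1.0), alpha=st.floats(0.0, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_range_preservation_property(self, x, alpha):
        assert abs(logistic_step(x, alpha)) <= 1.0

    @pytest.mark.parametrize("alpha", [1.0, 1.5, 2.0])
    def test_million_iterates_stay_in_interval(self, alpha, rng):
        # 1e4 parallel orbits x 100 iterates = 1e6 map evaluations
        x = rng.uniform(-1.0, 1.0, 10_000)
        for _ in range(100):
            x = logistic_step(x, alpha)
            assert np.all(np.abs(x) <= 1.0)


class TestChaoticControllerStep:
    def test_zero_input_zero_coupling_gives_ones(self):
        units = [ChaoticUnit(alpha=a, x=0.3, eps_self=0.0, eps_mix=0.0)
                 for a in (1.5, 1.7, 2.0)]
        out = chaotic_controller_step(np.zeros(3), units)
        assert np.allclose(out, 1.0)

    def test_tiny_self_feedback_is_a_small_perturbation(self):
        s = np.array([0.3, -0.2])
        u0 = chaotic_controller_step(
            s, [ChaoticUnit(alpha=1.7, x=0.5, eps_self=0.0, eps_mix=0.0),
                ChaoticUnit(alpha=1.7, x=-0.5, eps_self=0.0, eps_mix=0.0)])
        u1 = chaotic_controller_step(
            s, [ChaoticUnit(alpha=1.7, x=0.5, eps_self=1e-9, eps_mix=0.0),
                ChaoticUnit(alpha=1.7, x=-0.5, eps_self=1e-9, eps_mix=0.0)])
        assert np.max(np.abs(u0 - u1)) < 1e-6

    def test_mixing_hand_arithmetic(self):
        # two units, eps_mix=0.2, eps_self=0: effective input is
        # 0.8*s_i + 0.2*mean(u_prev); one iterate computed by hand
        units = [ChaoticUnit(alpha=2.0, x=0.5, eps_self=0.0, eps_mix=0.2),
                 ChaoticUnit(alpha=2.0, x=-0.1, eps_self=0.0, eps_mix=0.2)]
        s = np.array([0.25, -0.5])
        mean_u = 0.2
        exp0 = 1 - 2.0 * (0.8 * 0.25 + 0.2 * mean_u) ** 2
        exp1 = 1 - 2.0 * (0.8 * -0.5 + 0.2 * mean_u) ** 2
        out = chaotic_controller_step(s, units)
        assert out == pytest.approx([exp0, exp1])
        # unit states were updated in place
        assert units[0].x == pytest.approx(exp0)

    def test_length_mismatch_is_configuration_error(self):
        with pytest.raises(ValueError):
            chaotic_controller_step(np.zeros(2), [ChaoticUnit()])

    def test_eps_budget_invariant(self):
        with pytest.raises(DomainError):
            ChaoticUnit(eps_self=0.6, eps_mix=0.5)


class TestBVP:
    def test_rest_convergence_from_nearby_start(self):
        u = BVPUnit(v=-0.8, w=-0.4)
        for _ in range(int(100 / 0.001)):
            bvp_step(u, 0.0, 0.001)
        assert u.v == pytest.approx(BVP_REST[0], abs=1e-4)
        assert u.w == pytest.approx(BVP_REST[1], abs=1e-4)

    def test_supra_threshold_drive_gives_stable_limit_cycle(self):
        u = BVPUnit()
        vs = []
        for _ in range(int(30 / 0.001)):
            bvp_step(u, 0.875, 0.001)
            vs.append(u.v)
        vs = np.asarray(vs[len(vs) // 2:])
        assert vs.max() > 1.0 and vs.min() < -1.0  # bounded oscillation
        up = np.nonzero((vs[:-1] < 0) & (vs[1:] >= 0))[0]
        periods = np.diff(up)
        assert len(periods) >= 5
        assert np.abs(np.diff(periods)).max() / periods.mean() < 0.01

    def test_integrator_consistency_dt_halving(self):
        u1, u2 = BVPUnit(v=-0.5, w=-0.3), BVPUnit(v=-0.5, w=-0.3)
        for _ in range(1000):
            bvp_step(u1, 0.5, 0.001)
        for _ in range(2000):
            bvp_step(u2, 0.5, 0.0005)
        # first-order agreement at t=1
        assert abs(u1.v - u2.v) < 0.05


class TestSpinalUnit:
    def test_zero_afferent_gain_matches_isolated_oscillator(self):
        su = SpinalUnit(afferent_gain=0.0)
        ref = BVPUnit()
        aff = {"spindle_length": 0.7, "spindle_velocity": -0.2,
               "tendon_tension": 0.4}
        for _ in range(2000):
            spinal_step(su, aff, 0.001)
            bvp_step(ref, su.drive_bias, 0.001)
        assert su.oscillator.v == pytest.approx(ref.v)

    def test_gamma_zero_with_zero_tendon_matches_decoupled(self):
        su1 = SpinalUnit(afferent_gain=0.0)
        su2 = SpinalUnit(gamma_mn=0.0)
        aff = {"spindle_length": 0.7, "spindle_velocity": -0.2,
               "tendon_tension": 0.0}
        for _ in range(2000):
            a1 = spinal_step(su1, aff, 0.001)
            a2 = spinal_step(su2, aff, 0.001)
        assert a1 == pytest.approx(a2)

    def test_activation_bounded(self):
        su = SpinalUnit()
        for k in range(3000):
            a = spinal_step(su, {"spindle_length": np.sin(k / 50),
                                 "spindle_velocity": 0.0,
                                 "tendon_tension": 0.5}, 0.001)
            assert 0.0 <= a <= 1.0

    def test_nonfinite_afferent_rejected(self):
        with pytest.raises(DomainError):
            spinal_step(SpinalUnit(), {"spindle_length": np.nan}, 0.001)


def test_body_coupled_muscles_phase_lock(fetus_body):
    """Two antagonists sharing one joint entrain through the body alone."""
    from somadev.embodiment import Environment, simulate
    from somadev.experiments.bodymap import fitted_uterus
    from somadev.metrics import phase_sync_matrix, surrogate_plv_bound
    from somadev.embodiment import compiled

    cb = compiled(fetus_body)
    env = fitted_uterus(fetus_body)
    ctrl = SpinalController(cb.n_muscles, seed=3)
    traj = simulate(fetus_body, env, ctrl, 20.0, dt=0.004, seed=3)
    # the two spine antagonists share one joint; uncoupled controls are two
    # independent oscillators stepped open loop
    sig = traj.motor[500:, :2].T
    plv = phase_sync_matrix(sig)[0, 1]
    open_ctrl = SpinalController(2, seed=3)
    from types import SimpleNamespace
    frame = SimpleNamespace(tactile=np.zeros(1), spindle_length=np.zeros(2),
                            spindle_velocity=np.zeros(2), tendon_tension=np.zeros(2))
    acts = np.array([open_ctrl.step(frame, 0.01) for _ in range(2001)])
    plv_open = phase_sync_matrix(acts[500:, :2].T)[0, 1]
    assert plv > plv_open


def test_controller_state_determinism(insect_body):
    from somadev.embodiment import Environment, simulate

    env = Environment.walled_arena(half_size=5.0)
    out = []
    for _ in range(2):
        ctrl = ChaoticController(12, seed=7)
        traj = simulate(insect_body, env, ctrl, 3.0, dt=0.002,
                        control_dt=0.03, seed=7)
        out.append(traj.motor.copy())
    assert np.array_equal(out[0], out[1])


def test_no_hidden_coupling_with_rigid_body(rng):
    """With a non-moving body and no mixing, unit traces are independent."""
    from somadev.metrics import phase_sync_matrix, surrogate_plv_bound

    # near-unity self feedback keeps each map in its chaotic regime even
    # though the frozen sensors contribute nothing
    units = [ChaoticUnit(alpha=1.95, x=float(x), eps_self=0.97, eps_mix=0.0)
             for x in rng.uniform(-0.9, 0.9, 6)]
    s = np.zeros(6)  # rigid body: sensors frozen
    trace = np.array([chaotic_controller_step(s, units) for _ in range(3200)]).T
    trace = trace[:, 200:]  # drop transient
    corr = np.corrcoef(trace)
    iu = np.triu_indices(6, 1)
    observed = np.abs(corr[iu]).mean()
    # empirical p-value against circular-shift surrogates: the observed
    # cross-correlation must not sit in the top 5% of the null
    null = []
    for k in range(99):
        sur = np.stack([np.roll(ch, rng.integers(1, trace.shape[1]))
                        for ch in trace])
        c = np.corrcoef(sur)
        null.append(np.abs(c[iu]).mean())
    p = (1 + sum(b >= observed for b in null)) / 100.0
    assert p > 0.05
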