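"""Body builders, muscle model, receptors and simulation plumbing."""

import numpy as np
import pytest

from somadev.controllers import ChaoticController, ConfigurationError
from somadev.embodiment import (BodyState, Environment, Muscle, build_fetus_body,
                                build_insect_body, compiled, muscle_torque,
                                sense, simulate)
from somadev.embodiment.physics import Kinematics
from somadev.embodiment.simulate import initial_state


class TestInsectBody:
    def test_default_counts(self, insect_body):
        cb = compiled(insect_body)
        assert cb.n_joints == 12           # one rotary joint per leg
        assert cb.n_muscles == 24          # antagonist pair each
        assert sum(1 for t in insect_body.taxels if t.region == "foot") == 12

    def test_minimal_tripod_valid(self):
        cb = compiled(build_insect_body(n_legs=3))
        assert cb.n_joints == 3

    def test_too_few_legs_rejected(self):
        with pytest.raises(ValueError):
            build_insect_body(n_legs=2)

    def test_rotational_symmetry(self, insect_body):
        legs = [s for s in insect_body.segments if s.name.startswith("leg")]
        assert len({(s.mass, s.length, s.radius) for s in legs}) == 1
        cb = compiled(insect_body)
        offs = np.sort(cb.rest_offset[1:])
        assert np.allclose(np.diff(offs), 2 * np.pi / 12)


class TestFetusBody:
    def test_humanlike_concentrates_taxels(self):
        dense = ("face", "hand", "foot")
        def share(body):
            regions = [t.region for t in body.taxels]
            return sum(r in dense for r in regions) / len(regions)
        assert share(build_fetus_body(taxel_distribution="humanlike")) > \
            share(build_fetus_body(taxel_distribution="uniform"))

    def test_uniform_density_per_arc(self):
        body = build_fetus_body(taxel_distribution="uniform", taxel_count=600)
        counts = {}
        for t in body.taxels:
            counts[t.segment] = counts.get(t.segment, 0) + 1
        seg_arc = {s.name: 2 * max(s.length, 2 * s.radius)
                   for s in body.segments}
        density = np.array([counts[n] / seg_arc[n] for n in counts])
        assert density.std() / density.mean() < 0.25  # equal within rounding

    def test_forty_weeks_strictly_larger(self):
        b32 = build_fetus_body(32.0)
        b40 = build_fetus_body(40.0)
        assert all(s40.length > s32.length
                   for s40, s32 in zip(b40.segments, b32.segments))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_fetus_body(age_weeks=20.0)
        with pytest.raises(ValueError):
            build_fetus_body(taxel_distribution="martian")
        with pytest.raises(ValueError):
            build_fetus_body(taxel_count=5)

    def test_taxel_scale_invariance(self):
        c300 = compiled(build_fetus_body(taxel_count=300))
        c600 = compiled(build_fetus_body(taxel_count=600))
        for region in ("face", "hand", "foot", "other"):
            n300 = int(np.sum(c300.t_region == region))
            n600 = int(np.sum(c600.t_region == region))
            assert n600 == pytest.approx(2 * n300, abs=0.1 * n300 + 4)


class TestMuscleTorque:
    MUSCLE = Muscle("m", "j", +1, max_torque=2.0, theta_opt=0.1, width=1.0,
                    damping=0.05)

    def test_zero_activation_pure_damping(self):
        tau = muscle_torque(0.0, self.MUSCLE, 0.3, velocity=2.0)
        assert tau == pytest.approx(-0.05 * 2.0)

    def test_antagonist_coactivation_cancels(self):
        flex = Muscle("f", "j", +1, 2.0, theta_opt=0.0)
        ext = Muscle("e", "j", -1, 2.0, theta_opt=0.0)
        total = muscle_torque(0.5, flex, 0.0, 0.0) + muscle_torque(0.5, ext, 0.0, 0.0)
        assert total == pytest.approx(0.0)

    def test_hand_evaluated_formula(self):
        # sign*a*tau_max*exp(-((th-opt)/width)^2) - damping*vel
        expected = 1 * 0.7 * 2.0 * np.exp(-((0.5 - 0.1) / 1.0) ** 2) - 0.05 * 1.5
        assert muscle_torque(0.7, self.MUSCLE, 0.5, 1.5) == pytest.approx(expected)

    def test_activation_domain(self):
        with pytest.raises(ValueError):
            muscle_torque(1.2, self.MUSCLE, 0.0, 0.0)


class TestSense:
    def test_static_body_in_still_fluid_silent(self, fetus_body, uterus_env):
        cb = compiled(fetus_body)
        state = BodyState.initial(cb)
        state.base[2] = np.pi / 2
        frame = sense(fetus_body, state, uterus_env)
        # at rest the only nonzero tactile entries are static self-touch
        # pressure; every taxel not involved in a self-contact reads zero
        touched = set()
        for i, j, _f in np.asarray(frame.self_contacts).reshape(-1, 3):
            touched.add(int(i)); touched.add(int(j))
        free = np.setdiff1d(np.arange(cb.n_taxels), sorted(touched))
        assert len(free) > 0
        assert np.allclose(frame.tactile[free], 0.0)

    def test_moving_limb_feels_fluid_on_its_own_taxels(self, fetus_body,
                                                       uterus_env):
        cb = compiled(fetus_body)
        state = BodyState.initial(cb)
        state.base[2] = np.pi / 2
        k = cb.joint_names.index("shoulder_r")
        state.qd[k] = 2.0  # only the right arm moves
        frame = sense(fetus_body, state, uterus_env)
        touched = set()
        for i, j, _f in np.asarray(frame.self_contacts).reshape(-1, 3):
            touched.add(int(i)); touched.add(int(j))
        arm_r = cb.t_part == "arm_r"
        leg_l = (cb.t_part == "leg_l")             & ~np.isin(np.arange(cb.n_taxels), sorted(touched))
        assert frame.tactile[arm_r].max() > 0
        assert np.allclose(frame.tactile[leg_l], 0.0, atol=1e-9)

    def test_vision_sees_hand_in_front_not_behind(self, fetus_body):
        cb = compiled(fetus_body)
        env = Environment.flat_plane()
        state = BodyState.initial(cb)
        state.base[2] = np.pi / 2
        # arm raised in front of the face
        state.q[cb.joint_names.index("shoulder_r")] = 0.4
        frame = sense(fetus_body, state, env, visual_on=True)
        assert frame.visual.max() > 0
        # arm swung far behind/below: the frame darkens
        state.q[cb.joint_names.index("shoulder_r")] = -1.2
        state.q[cb.joint_names.index("hip_l")] = -1.0
        state.q[cb.joint_names.index("hip_r")] = -1.0
        frame2 = sense(fetus_body, state, env, visual_on=True)
        assert frame2.visual.sum() < frame.visual.sum()

    def test_contact_bookkeeping_matches_taxels(self, fetus_body):
        env = Environment.flat_plane()
        state = initial_state(fetus_body, env, seed=0)
        from somadev.embodiment import physics_step
        for _ in range(500):
            physics_step(fetus_body, state, np.zeros(compiled(fetus_body).n_joints),
                         env, 0.002)
        frame = sense(fetus_body, state, env)
        assert frame.contact_normal.shape == (compiled(fetus_body).n_taxels,)
        assert np.array_equal(frame.contact_normal, state.contact_forces)
        assert frame.contact_normal.max() > 0  # resting on the ground


class TestSimulate:
    def test_zero_duration_single_frame(self, insect_body):
        env = Environment.walled_arena(half_size=5.0)
        ctrl = ChaoticController(12, seed=0)
        traj = simulate(insect_body, env, ctrl, 0.0, seed=0)
        assert len(traj.times) == 1

    def test_same_seed_identical_trajectories(self, fetus_body, uterus_env):
        from somadev.controllers import SpinalController
        cb = compiled(fetus_body)
        runs = []
        for _ in range(2):
            ctrl = SpinalController(cb.n_muscles, seed=11)
            runs.append(simulate(fetus_body, uterus_env, ctrl, 2.0,
                                 dt=0.004, seed=11))
        assert np.array_equal(runs[0].q, runs[1].q)
        assert np.array_equal(runs[0].tactile, runs[1].tactile)

    def test_component_mismatch_rejected_before_stepping(self, insect_body):
        env = Environment.walled_arena(half_size=5.0)
        with pytest.raises(ConfigurationError):
            simulate(insect_body, env, ChaoticController(5, seed=0), 1.0)

    def test_trajectory_round_trip_and_export(self, insect_body, tmp_path):
        env = Environment.walled_arena(half_size=5.0)
        traj = simulate(insect_body, env, ChaoticController(12, seed=0), 1.0,
                        control_dt=0.03, seed=0)
        traj.save_hdf5(tmp_path / "traj.h5")
        traj.export_csv(tmp_path / "traj.csv")
        import h5py
        with h5py.File(tmp_path / "traj.h5") as f:
            assert f["states"]["q"].shape == traj.q.shape
            assert "receptors" in f and "motors" in f
        assert (tmp_path / "traj.csv").stat().st_size > 0
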