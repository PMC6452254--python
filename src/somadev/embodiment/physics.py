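"""Reduced 2D articulated dynamics with penalty contacts.

The model integrates each joint as a 1-DOF rotational equation with a fixed
effective (rest-pose subtree) inertia, plus a 3-DOF rigid base, with
semi-implicit Euler.  Forces applied at material points are projected onto
the generalized coordinates through cross products with the instantaneous
joint origins.  Inertial coupling (off-diagonal mass-matrix terms, Coriolis
forces) is neglected; joint springs, viscous damping and penalty contacts
dominate the regimes simulated here.  Contacts are penalty springs with
damping; ground friction is Coulomb-like with a smooth stiction
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bodies import BodySpec, CompiledBody, Muscle, compiled, _dirs
from .environments import Environment
from ..controllers import NumericalDivergenceError

__all__ = ["BodyState", "Kinematics", "kinematics", "muscle_torque",
           "muscle_joint_torques", "physics_step", "total_energy"]


@dataclass
class BodyState:
    q: np.ndarray                 # joint angles, rad
    qd: np.ndarray                # joint angular velocities, rad/s
    base: np.ndarray              # (x, y, heading)
    base_vel: np.ndarray          # (vx, vy, omega)
    contact_forces: np.ndarray    # per-taxel normal force magnitude, N
    muscle_torques: np.ndarray    # last applied per-muscle torque, N*m
    t: float = 0.0
    step_index: int = 0

    @classmethod
    def initial(cls, cb: CompiledBody, base=(0.0, 0.0, 0.0)):
        return cls(q=np.zeros(cb.n_joints), qd=np.zeros(cb.n_joints),
                   base=np.array(base, dtype=float), base_vel=np.zeros(3),
                   contact_forces=np.zeros(cb.n_taxels),
                   muscle_torques=np.zeros(cb.n_muscles))

    def copy(self):
        return BodyState(self.q.copy(), self.qd.copy(), self.base.copy(),
                         self.base_vel.copy(), self.contact_forces.copy(),
                         self.muscle_torques.copy(), self.t, self.step_index)


class Kinematics:
    """World-frame poses and point velocities for one instant."""

    def __init__(self, cb: CompiledBody, state: BodyState):
        self.cb = cb
        self.seg_angle, self.seg_origin = cb._fk_frames(state.q, state.base)
        d = _dirs(self.seg_angle)
        self.seg_dir = d
        self.seg_com = self.seg_origin + 0.5 * cb.seg_len[:, None] * d
        self.seg_tip = self.seg_origin + cb.seg_len[:, None] * d
        self.joint_origin = self.seg_origin[cb.child_seg]
        # taxel world positions
        ca, sa = np.cos(self.seg_angle[cb.t_seg]), np.sin(self.seg_angle[cb.t_seg])
        lx, ly = cb.t_local[:, 0], cb.t_local[:, 1]
        self.taxel_pos = self.seg_origin[cb.t_seg] + \
            np.stack([ca * lx - sa * ly, sa * lx + ca * ly], axis=1)
        self._state = state

    def point_vel(self, pts: np.ndarray, segs: np.ndarray) -> np.ndarray:
        """Velocities of material points ``pts`` on segments ``segs``."""
        st, cb = self._state, self.cb
        rel_b = pts - st.base[:2]
        v = st.base_vel[:2] + st.base_vel[2] * _perp(rel_b)
        # sum_j qd_j * perp(p - joint_origin_j) over ancestor joints
        rel_j = pts[:, None, :] - self.joint_origin[None, :, :]  # (P, J, 2)
        wj = cb.anc[segs] * st.qd[None, :]                       # (P, J)
        v[:, 0] += np.einsum("pj,pj->p", wj, -rel_j[:, :, 1])
        v[:, 1] += np.einsum("pj,pj->p", wj, rel_j[:, :, 0])
        return v


def kinematics(body: BodySpec, state: BodyState) -> Kinematics:
    return Kinematics(compiled(body), state)


def _perp(v):
    out = np.empty_like(v)
    out[..., 0] = -v[..., 1]
    out[..., 1] = v[..., 0]
    return out


def muscle_torque(activation: float, muscle: Muscle, angle: float,
                  velocity: float) -> float:
    """Joint torque of one muscle.

    ``sign * activation * max_torque * overlap(angle) - damping * velocity``
    with a smooth unimodal Gaussian length-tension overlap factor in (0, 1].
    """
    if not (0.0 <= activation <= 1.0):
        raise ValueError(f"activation out of [0, 1]: {activation:g}")
    overlap = np.exp(-((angle - muscle.theta_opt) / muscle.width) ** 2)
    return float(muscle.sign * activation * muscle.max_torque * overlap
                 - muscle.damping * velocity)


def muscle_joint_torques(cb: CompiledBody, state: BodyState, activations,
                         include_viscous: bool = True):
    """Per-joint torque from all muscles; records per-muscle torques.

    With ``include_viscous=False`` returns ``(active torques, per-joint
    viscous coefficient)`` so the integrator can treat muscle damping
    implicitly.
    """
    act = np.clip(np.asarray(activations, dtype=float), 0.0, 1.0)
    th = state.q[cb.m_joint]
    om = state.qd[cb.m_joint]
    overlap = np.exp(-((th - cb.m_opt) / cb.m_width) ** 2)
    tau_act = cb.m_sign * act * cb.m_tau * overlap
    torques = np.zeros(cb.n_joints)
    if include_viscous:
        state.muscle_torques = tau_act - cb.m_damp * om
        np.add.at(torques, cb.m_joint, state.muscle_torques)
        return torques
    state.muscle_torques = tau_act
    np.add.at(torques, cb.m_joint, tau_act)
    damp = np.zeros(cb.n_joints)
    np.add.at(damp, cb.m_joint, cb.m_damp)
    return torques, damp


class _Wrench:
    """Accumulated generalized forces plus diagonal damping estimates.

    ``damp_*`` collect the coefficients of velocity-proportional force
    components so the integrator can apply them implicitly (stable for any
    overestimate); the explicit torque already contains the same damping,
    which the implicit update removes and re-applies.
    """

    def __init__(self, cb):
        self.tau = np.zeros(cb.n_joints)
        self.f_base = np.zeros(2)
        self.tau_base = 0.0
        self.damp_j = np.zeros(cb.n_joints)
        self.damp_lin = 0.0
        self.damp_rot = 0.0

    def add(self, cb, kin, state, pts, segs, forces, visc=None):
        self.f_base += forces.sum(axis=0)
        rel = pts - state.base[:2]
        self.tau_base += float(np.sum(rel[:, 0] * forces[:, 1]
                                      - rel[:, 1] * forces[:, 0]))
        contrib = cb.anc[segs]                                   # (P, J)
        rel_j = pts[:, None, :] - kin.joint_origin[None, :, :]   # (P, J, 2)
        cross = rel_j[:, :, 0] * forces[:, None, 1] - rel_j[:, :, 1] * forces[:, None, 0]
        self.tau += np.einsum("pj,pj->j", contrib, cross)
        if visc is not None:
            visc = np.asarray(visc, dtype=float)
            if visc.ndim == 0:
                visc = np.full(len(pts), float(visc))
            self.damp_lin += float(visc.sum())
            self.damp_rot += float(np.sum(visc * np.sum(rel ** 2, axis=1)))
            r2 = np.sum(rel_j ** 2, axis=2)
            self.damp_j += np.einsum("pj,pj,p->j", contrib, r2, visc)


def close_taxel_pairs(body: BodySpec, state: BodyState, margin: float = 3.0):
    """Broad-phase for self-collision: candidate pair indices currently
    within ``margin`` times the touch threshold."""
    cb = compiled(body)
    if not cb.touch_i.size:
        return np.zeros(0, dtype=int)
    from .sensing import TOUCH_FACTOR
    kin = Kinematics(cb, state)
    diff = kin.taxel_pos[cb.touch_i] - kin.taxel_pos[cb.touch_j]
    d2 = np.einsum("pc,pc->p", diff, diff)
    thresh = margin * TOUCH_FACTOR * (cb.seg_rad[cb.t_seg[cb.touch_i]]
                                      + cb.seg_rad[cb.t_seg[cb.touch_j]])
    return np.nonzero(d2 < thresh ** 2)[0]


def physics_step(body: BodySpec, state: BodyState, torques, env: Environment,
                 dt: float, joint_damping_extra=None,
                 close_pairs=None) -> BodyState:
    """Advance joint and base dynamics one semi-implicit Euler step.

    Includes joint springs and damping, muscle/actuator torques (``torques``
    per joint), gravity minus buoyancy, linear fluid drag, wall penalty
    forces (recorded per taxel), ground penalty contact with smooth Coulomb
    friction, and anisotropic foot traction in top-down arenas.  All
    velocity-proportional damping is integrated implicitly, which keeps the
    step stable even for the smallest limb inertias.
    """
    if not (0.0 < dt <= 0.005):
        raise ValueError(f"dt must be in (0, 5 ms], got {dt:g}")
    cb = compiled(body)
    torques = np.asarray(torques, dtype=float)
    if torques.shape != (cb.n_joints,):
        raise ValueError(f"need one torque per joint ({cb.n_joints})")
    kin = Kinematics(cb, state)
    wr = _Wrench(cb)
    wr.tau += torques - cb.K * state.q - cb.jdamp * state.qd
    wr.damp_j += cb.jdamp
    if joint_damping_extra is not None:
        wr.damp_j += joint_damping_extra
    state.contact_forces = np.zeros(cb.n_taxels)
    all_segs = np.arange(cb.n_seg)

    # gravity / buoyancy at segment COMs (sagittal worlds)
    g_eff = env.gravity * (1.0 - env.buoyancy) if not env.planar else 0.0
    if g_eff:
        fg = np.zeros((cb.n_seg, 2))
        fg[:, 1] = -g_eff * cb.seg_mass
        wr.add(cb, kin, state, kin.seg_com, all_segs, fg)

    # linear fluid drag at segment COMs
    if env.fluid_drag > 0:
        v_com = kin.point_vel(kin.seg_com, all_segs)
        visc = env.fluid_drag * cb.seg_mass
        wr.add(cb, kin, state, kin.seg_com, all_segs, -visc[:, None] * v_com,
               visc=visc)

    # ground contact on taxels (sagittal plane at y = 0)
    if env.ground and cb.n_taxels:
        pen = -kin.taxel_pos[:, 1]
        touching = pen > 0
        if np.any(touching):
            pts = kin.taxel_pos[touching]
            segs = cb.t_seg[touching]
            v = kin.point_vel(pts, segs)
            fn = np.clip(env.ground_k * pen[touching] - env.ground_c * v[:, 1],
                         0.0, None)
            ft = -env.mu_ground * fn * np.tanh(v[:, 0] / 0.01)
            visc = env.ground_c + env.mu_ground * fn / 0.01  # stiction slope
            wr.add(cb, kin, state, pts, segs, np.stack([ft, fn], axis=1),
                   visc=visc)
            state.contact_forces[touching] = fn

    # wall penalties on taxels
    if env.wall is not None and cb.n_taxels:
        c = np.asarray(env.wall["center"])
        size = env.wall["size"]
        rel = kin.taxel_pos - c
        if env.wall["shape"] == "circle":
            r = np.linalg.norm(rel, axis=1) + 1e-12
            pen = r - size
            touching = pen > 0
            if np.any(touching):
                n_in = -rel[touching] / r[touching, None]
                pts = kin.taxel_pos[touching]
                segs = cb.t_seg[touching]
                v = kin.point_vel(pts, segs)
                v_out = -np.sum(v * n_in, axis=1)
                fn = np.clip(env.wall_k * pen[touching] + env.wall_c * v_out,
                             0.0, None)
                wr.add(cb, kin, state, pts, segs, fn[:, None] * n_in,
                       visc=np.full(fn.size, env.wall_c))
                state.contact_forces[touching] = np.maximum(
                    state.contact_forces[touching], fn)
        else:  # square
            mu_w = env.extra.get("wall_friction", 0.0)
            for axis, sgn in ((0, 1), (0, -1), (1, 1), (1, -1)):
                pen = sgn * rel[:, axis] - size
                touching = pen > 0
                if not np.any(touching):
                    continue
                pts = kin.taxel_pos[touching]
                segs = cb.t_seg[touching]
                v = kin.point_vel(pts, segs)
                v_out = sgn * v[:, axis]
                fn = np.clip(env.wall_k * pen[touching] + env.wall_c * v_out,
                             0.0, None)
                forces = np.zeros((fn.size, 2))
                forces[:, axis] = -sgn * fn
                visc = np.full(fn.size, env.wall_c)
                if mu_w > 0:  # tangential grip pins contacting taxels
                    tang = 1 - axis
                    forces[:, tang] = -mu_w * fn * np.tanh(v[:, tang] / 0.01)
                    visc = visc + mu_w * fn / 0.01
                wr.add(cb, kin, state, pts, segs, forces, visc=visc)
                state.contact_forces[touching] = np.maximum(
                    state.contact_forces[touching], fn)

    # self-collision repulsion between non-adjacent same-plane segments
    # (same pairs and stiffness as the self-touch sensing, so the skin
    # cannot interpenetrate and self-touch is a transient event)
    if cb.touch_i.size and not env.planar:
        from .sensing import TOUCH_FACTOR, TOUCH_STIFFNESS
        sel = np.arange(cb.touch_i.size) if close_pairs is None else close_pairs
        ti, tj = cb.touch_i[sel], cb.touch_j[sel]
        diff = kin.taxel_pos[ti] - kin.taxel_pos[tj]
        d = np.sqrt(np.einsum("pc,pc->p", diff, diff)) + 1e-12
        thresh = TOUCH_FACTOR * (cb.seg_rad[cb.t_seg[ti]]
                                 + cb.seg_rad[cb.t_seg[tj]])
        hit = d < thresh
        if np.any(hit):
            f = TOUCH_STIFFNESS * (thresh[hit] - d[hit])
            n_ij = diff[hit] / d[hit, None]
            i_hit = ti[hit]
            j_hit = tj[hit]
            wr.add(cb, kin, state, kin.taxel_pos[i_hit], cb.t_seg[i_hit],
                   f[:, None] * n_ij)
            wr.add(cb, kin, state, kin.taxel_pos[j_hit], cb.t_seg[j_hit],
                   -f[:, None] * n_ij)

    # anisotropic foot-ground traction (top-down insect arena)
    if env.traction is not None and cb.foot_segs.size:
        tips = kin.seg_tip[cb.foot_segs]
        v = kin.point_vel(tips, cb.foot_segs)
        e_r = tips - state.base[:2]
        e_r /= np.linalg.norm(e_r, axis=1, keepdims=True) + 1e-12
        v_rad = np.sum(v * e_r, axis=1)
        mu = np.where(v_rad > 0, env.traction[0], env.traction[1])
        wr.add(cb, kin, state, tips, cb.foot_segs, -mu[:, None] * v, visc=mu)

    # semi-implicit Euler with implicit diagonal damping: the explicit
    # torque contains -D*qd; adding D*qd back and dividing by (1 + dt*D/I)
    # applies the self-damping implicitly while cross terms stay explicit.
    state.qd = (state.qd + dt * (wr.tau + wr.damp_j * state.qd) / cb.I_joint) \
        / (1.0 + dt * wr.damp_j / cb.I_joint)
    state.q += dt * state.qd
    low = state.q < cb.jlo
    high = state.q > cb.jhi
    state.q = np.clip(state.q, cb.jlo, cb.jhi)
    state.qd[low & (state.qd < 0)] = 0.0
    state.qd[high & (state.qd > 0)] = 0.0
    state.base_vel[:2] = (state.base_vel[:2]
                          + dt * (wr.f_base + wr.damp_lin * state.base_vel[:2])
                          / cb.M_total) / (1.0 + dt * wr.damp_lin / cb.M_total)
    state.base_vel[2] = (state.base_vel[2]
                         + dt * (wr.tau_base + wr.damp_rot * state.base_vel[2])
                         / cb.I_base) / (1.0 + dt * wr.damp_rot / cb.I_base)
    state.base[:2] += dt * state.base_vel[:2]
    state.base[2] += dt * state.base_vel[2]
    state.t += dt
    state.step_index += 1
    if not (np.all(np.isfinite(state.q)) and np.all(np.isfinite(state.base))
            and np.all(np.isfinite(state.qd)) and np.all(np.isfinite(state.base_vel))):
        raise NumericalDivergenceError(
            f"physics diverged at step {state.step_index} "
            f"(body={body.name!r}, env={env.kind!r}, dt={dt:g})",
            step=state.step_index)
    return state


def total_energy(body: BodySpec, state: BodyState, env: Environment) -> float:
    """Mechanical energy consistent with the reduced model.

    Kinetic (joint + base), joint-spring potential, gravitational potential
    and ground/wall penalty-spring potential.  Used by the passive
    dissipation tests.
    """
    cb = compiled(body)
    kin = Kinematics(cb, state)
    ke = 0.5 * float(np.sum(cb.I_joint * state.qd ** 2)) \
        + 0.5 * cb.M_total * float(np.sum(state.base_vel[:2] ** 2)) \
        + 0.5 * cb.I_base * state.base_vel[2] ** 2
    pe = 0.5 * cb.K * float(np.sum(state.q ** 2))
    g_eff = env.gravity * (1.0 - env.buoyancy) if not env.planar else 0.0
    if g_eff:
        pe += g_eff * float(np.sum(cb.seg_mass * kin.seg_com[:, 1]))
    if env.ground and cb.n_taxels:
        pen = np.clip(-kin.taxel_pos[:, 1], 0.0, None)
        pe += 0.5 * env.ground_k * float(np.sum(pen ** 2))
    if env.wall is not None and cb.n_taxels:
        c = np.asarray(env.wall["center"])
        rel = kin.taxel_pos - c
        if env.wall["shape"] == "circle":
            pen = np.clip(np.linalg.norm(rel, axis=1) - env.wall["size"], 0.0, None)
        else:
            pen = np.clip(np.abs(rel) - env.wall["size"], 0.0, None).sum(axis=1)
        pe += 0.5 * env.wall_k * float(np.sum(pen ** 2))
    if cb.touch_i.size and not env.planar:
        from .sensing import TOUCH_FACTOR, TOUCH_STIFFNESS
        diff = kin.taxel_pos[cb.touch_i] - kin.taxel_pos[cb.touch_j]
        d = np.sqrt(np.einsum("pc,pc->p", diff, diff))
        thresh = TOUCH_FACTOR * (cb.seg_rad[cb.t_seg[cb.touch_i]]
                                 + cb.seg_rad[cb.t_seg[cb.touch_j]])
        pen = np.clip(thresh - d, 0.0, None)
        pe += 0.5 * TOUCH_STIFFNESS * float(np.sum(pen ** 2))
    return ke + pe
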