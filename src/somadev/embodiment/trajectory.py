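"""Time-indexed simulation output: states, receptor frames, motor outputs.

Stored column-wise in numpy arrays, savable to an HDF5 container with
``/states``, ``/receptors`` and ``/motors`` groups, exportable to columnar
CSV, and convertible to a :class:`~somadev.fixtures.ReceptorStream` for
cortical training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "config_hash"]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration dict."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Trajectory:
    times: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    base: np.ndarray
    base_vel: np.ndarray
    motor: np.ndarray
    tactile: np.ndarray
    contact_normal: np.ndarray
    spindle_length: np.ndarray
    spindle_velocity: np.ndarray
    tendon_tension: np.ndarray
    self_contacts: list
    taxel_regions: np.ndarray
    taxel_parts: np.ndarray
    joint_names: list
    muscle_names: list
    visual: np.ndarray | None = None
    config_hash: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    @classmethod
    def allocate(cls, body, cb, n_frames, dt, visual_on=False, config_hash="",
                 seed=None):
        from .sensing import VISION_SHAPE
        return cls(
            times=np.zeros(n_frames),
            q=np.zeros((n_frames, cb.n_joints)),
            qd=np.zeros((n_frames, cb.n_joints)),
            base=np.zeros((n_frames, 3)),
            base_vel=np.zeros((n_frames, 3)),
            motor=np.zeros((n_frames, max(cb.n_muscles, cb.n_joints))),
            tactile=np.zeros((n_frames, cb.n_taxels)),
            contact_normal=np.zeros((n_frames, cb.n_taxels)),
            spindle_length=np.zeros((n_frames, cb.n_muscles)),
            spindle_velocity=np.zeros((n_frames, cb.n_muscles)),
            tendon_tension=np.zeros((n_frames, cb.n_muscles)),
            self_contacts=[[] for _ in range(n_frames)],
            taxel_regions=cb.t_region.copy(),
            taxel_parts=cb.t_part.copy(),
            joint_names=list(cb.joint_names),
            muscle_names=list(cb.muscle_names),
            visual=(np.zeros((n_frames,) + VISION_SHAPE) if visual_on else None),
            config_hash=config_hash,
            seed=seed,
            meta={"dt": dt, "body": body.name},
        )

    def record(self, k, t, state, frame, motor):
        self.times[k] = t
        self.q[k] = state.q
        self.qd[k] = state.qd
        self.base[k] = state.base
        self.base_vel[k] = state.base_vel
        self.motor[k, :len(motor)] = motor
        self.tactile[k] = frame.tactile
        self.contact_normal[k] = frame.contact_normal
        self.spindle_length[k] = frame.spindle_length
        self.spindle_velocity[k] = frame.spindle_velocity
        self.tendon_tension[k] = frame.tendon_tension
        self.self_contacts[k] = frame.self_contacts
        if self.visual is not None and frame.visual is not None:
            self.visual[k] = frame.visual

    # -- views --------------------------------------------------------------

    @property
    def dt(self):
        return float(self.meta.get("dt", np.median(np.diff(self.times))
                                   if len(self.times) > 1 else 0.01))

    @property
    def fs(self):
        return 1.0 / self.dt

    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.base[-1, :2] - self.base[0, :2]))

    def to_stream(self, modalities=("tactile", "proprio"), muscle_parts=None):
        """Receptor channels as a :class:`~somadev.fixtures.ReceptorStream`.

        Tactile channels carry their taxel's part label; proprio channels
        (spindle stretch rectified, |stretch rate|) carry their muscle's
        part; visual pixels are labelled ``visual``.
        """
        from ..fixtures import ReceptorStream
        cols, labels, modal = [], [], []
        if "tactile" in modalities:
            cols.append(self.tactile)
            labels += list(self.taxel_parts)
            modal += ["tactile"] * self.tactile.shape[1]
        if "proprio" in modalities:
            if muscle_parts is None:
                muscle_parts = _muscle_parts_from_names(self.muscle_names)
            cols.append(np.clip(self.spindle_length, 0.0, None))
            cols.append(np.abs(self.spindle_velocity))
            labels += list(muscle_parts) * 2
            modal += ["proprio"] * (2 * self.spindle_length.shape[1])
        if "visual" in modalities and self.visual is not None:
            cols.append(self.visual.reshape(len(self.times), -1))
            labels += ["visual"] * self.visual[0].size
            modal += ["visual"] * self.visual[0].size
        vals = np.concatenate(cols, axis=1) if cols else np.zeros((len(self.times), 0))
        return ReceptorStream(values=vals, dt=self.dt, part_labels=labels,
                              modality=modal)

    # -- persistence --------------------------------------------------------

    def save_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            st = f.create_group("states")
            st["times"] = self.times
            st["q"] = self.q
            st["qd"] = self.qd
            st["base"] = self.base
            st["base_vel"] = self.base_vel
            rc = f.create_group("receptors")
            rc["tactile"] = self.tactile
            rc["contact_normal"] = self.contact_normal
            rc["spindle_length"] = self.spindle_length
            rc["spindle_velocity"] = self.spindle_velocity
            rc["tendon_tension"] = self.tendon_tension
            if self.visual is not None:
                rc["visual"] = self.visual
            f.create_group("motors")["outputs"] = self.motor
            f.attrs["config_hash"] = self.config_hash
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["dt"] = self.dt

    def export_csv(self, path):
        import pandas as pd
        cols = {"time": self.times}
        for j, n in enumerate(self.joint_names):
            cols[f"q.{n}"] = self.q[:, j]
            cols[f"qd.{n}"] = self.qd[:, j]
        for c, n in enumerate(("x", "y", "heading")):
            cols[f"base.{n}"] = self.base[:, c]
        for m in range(self.motor.shape[1]):
            cols[f"motor.{m}"] = self.motor[:, m]
        pd.DataFrame(cols).to_csv(path, index=False)


def _muscle_parts_from_names(names):
    parts = []
    for n in names:
        if n.endswith(("_l_flex", "_l_ext")) or "_l_" in n:
            side = "_l"
        elif n.endswith(("_r_flex", "_r_ext")) or "_r_" in n:
            side = "_r"
        else:
            side = ""
        stem = n.split("_")[0]
        if stem in ("shoulder", "elbow", "wrist"):
            parts.append(f"arm{side}" if side else "arm")
        elif stem in ("hip", "knee"):
            parts.append(f"leg{side}" if side else "leg")
        elif stem in ("spine",):
            parts.append("trunk")
        elif stem in ("neck", "head"):
            parts.append("head")
        else:
            parts.append("body")
    return parts
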