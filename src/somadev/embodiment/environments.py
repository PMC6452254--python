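"""The three simulated environments coupling controllers through the body.

* ``uterus_fluid`` — elastic membrane sphere (circle in 2D) filled with
  fluid: near-neutral buoyancy, linear-in-velocity drag on every segment and
  taxel, soft wall penalty.  Sagittal plane, gravity almost cancelled.
* ``flat_plane`` — gravity on, no fluid: the "extreme preterm" condition for
  the fetus.  Sagittal plane with a ground at y = 0 and Coulomb-style
  friction.
* ``walled_arena`` — top-down planar world for the insect robot: no in-plane
  gravity, anisotropic foot-ground traction, optional square walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Environment"]


@dataclass
class Environment:
    kind: str
    gravity: float = 9.81            # m/s^2 (in-plane, -y), 0 in top-down worlds
    buoyancy: float = 0.0            # fraction of gravity cancelled, ~1 in fluid
    fluid_drag: float = 0.0          # 1/s translational drag per unit mass
    skin_drag: float = 0.0           # N*s/m fluid-resistance pressure per taxel speed
    ground: bool = False             # ground plane at y=0 (sagittal worlds)
    ground_k: float = 12000.0        # penalty stiffness N/m
    ground_c: float = 30.0           # penalty damping N*s/m
    mu_ground: float = 0.6           # Coulomb friction coefficient
    wall: dict | None = None         # {'shape': 'circle'|'square', 'size': m, 'center': (x,y)}
    wall_k: float = 800.0
    wall_c: float = 10.0
    planar: bool = False             # top-down (no gravity axis in-plane)
    traction: tuple | None = None    # (mu_extend, mu_retract) foot drag N*s/m
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "uterus_fluid" and (self.buoyancy < 0.9 or self.fluid_drag <= 0):
            raise ValueError("uterus_fluid must be near-neutrally buoyant with drag")
        if self.kind == "flat_plane" and (self.gravity <= 0 or self.fluid_drag != 0):
            raise ValueError("flat_plane has gravity on and no fluid drag")

    @classmethod
    def uterus(cls, radius: float = 0.16, center=(0.0, 0.0), buoyancy: float = 0.98,
               fluid_drag: float = 4.0, skin_drag: float = 6.0,
               wall_k: float = 400.0, wall_c: float = 8.0):
        """Fluid-filled elastic uterus (sagittal plane)."""
        return cls(kind="uterus_fluid", gravity=9.81, buoyancy=buoyancy,
                   fluid_drag=fluid_drag, skin_drag=skin_drag, ground=False,
                   wall={"shape": "circle", "size": radius, "center": tuple(center)},
                   wall_k=wall_k, wall_c=wall_c)

    @classmethod
    def flat_plane(cls, mu: float = 0.6, ground_k: float = 12000.0,
                   ground_c: float = 40.0):
        """Open flat plane with gravity (sagittal), the extreme-preterm world."""
        return cls(kind="flat_plane", gravity=9.81, buoyancy=0.0, fluid_drag=0.0,
                   ground=True, ground_k=ground_k, ground_c=ground_c, mu_ground=mu)

    @classmethod
    def walled_arena(cls, half_size: float = 1.5, mu_extend: float = 6.0,
                     mu_retract: float = 0.6, wall_k: float = 300.0,
                     wall_c: float = 30.0, body_drag: float = 0.8,
                     wall_friction: float = 3.0):
        """Top-down arena for the insect robot, square walls at +-half_size.

        Foot traction is anisotropic: a foot sliding radially outward
        (extending, pushing against the ground) grips with ``mu_extend``
        while a retracting foot slides with ``mu_retract`` — the ratchet that
        converts radial leg oscillation into thrust.
        """
        return cls(kind="walled_arena", gravity=0.0, buoyancy=0.0,
                   fluid_drag=body_drag, ground=False, planar=True,
                   wall={"shape": "square", "size": half_size, "center": (0.0, 0.0)},
                   wall_k=wall_k, wall_c=wall_c,
                   traction=(mu_extend, mu_retract),
                   extra={"wall_friction": wall_friction})
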