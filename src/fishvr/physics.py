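"""2D rigid-body pose integration with game-engine-style drag.

Emulates the Unity point-mass setup (mass 1, drag 1, angular drag 10000)
at one integration step per 10 Hz control tick.  Per tick::

    v     <- (v + F_trans/mass * dt) * max(1 - linear_drag*dt, 0)
    w_eff <- w + torque * dt                      (torque in rad/s^2)
    heading <- heading + w_eff * dt               (then normalized to [0,360))
    w     <- w_eff * max(1 - angular_drag*dt, 0)
    pos   <- pos + v * dt * (sin heading, cos heading)

With the published angular drag the angular damping factor clamps to zero,
so rotation has no carry-over between ticks (purely force-driven), which
reproduces the rig's crisp stop at the end of a turn, while the linear
damping gives the gradual coasting inertia at the start and end of forward
bouts.  The arena boundary is impenetrable: positions leaving the disk are
projected back to the circle and the outward radial velocity component is
zeroed, leaving tangential sliding; the heading is untouched so the agent
must steer away itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .config import PhysicsConfig
from .locomotion import ForceCommand, TurnDirection


@dataclass
class AgentState:
    """2D pose: position (x, z) in arena units, heading in degrees
    (0 = +Z, clockwise positive), linear speed v (units/s, along heading)
    and angular speed omega (rad/s, CW positive)."""

    x: float = 0.0
    z: float = 0.0
    heading_deg: float = 0.0
    v: float = 0.0
    omega: float = 0.0

    def heading_unit(self) -> tuple[float, float]:
        h = math.radians(self.heading_deg)
        return math.sin(h), math.cos(h)


def normalize_heading(deg: float) -> float:
    return deg % 360.0


def step(state: AgentState, cmd: ForceCommand, cfg: PhysicsConfig) -> AgentState:
    """Advance one control tick under a ForceCommand."""
    vals = (state.x, state.z, state.heading_deg, state.v, state.omega,
            cmd.f_translation, cmd.f_rotation)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite state or command")
    if cmd.f_translation < 0 or cmd.f_rotation < 0:
        raise ValueError("forces must be non-negative")

    dt = cfg.dt
    lin_damp = max(1.0 - cfg.linear_drag * dt, 0.0)
    ang_damp = max(1.0 - cfg.angular_drag * dt, 0.0)

    v = (state.v + cmd.f_translation / cfg.mass * dt) * lin_damp
    if v < cfg.speed_floor:
        v = 0.0

    if cmd.turn_direction is TurnDirection.CW:
        torque = cmd.f_rotation
    elif cmd.turn_direction is TurnDirection.CCW:
        torque = -cmd.f_rotation
    else:
        torque = 0.0
    omega_eff = state.omega + torque / cfg.mass * dt
    heading = normalize_heading(state.heading_deg + math.degrees(omega_eff * dt))
    omega = omega_eff * ang_damp

    h = math.radians(heading)
    x = state.x + v * dt * math.sin(h)
    z = state.z + v * dt * math.cos(h)
    return AgentState(x=x, z=z, heading_deg=heading, v=v, omega=omega)


def resolve_boundary(state: AgentState, arena_radius: float) -> AgentState:
    """Impenetrable circular wall: project escapes back onto the circle and
    zero the outward radial velocity component (tangential part kept)."""
    r = math.hypot(state.x, state.z)
    if r <= arena_radius or r == 0.0:
        return state
    scale = arena_radius / r
    x, z = state.x * scale, state.z * scale
    ux, uz = state.heading_unit()
    rx, rz = x / arena_radius, z / arena_radius
    c = ux * rx + uz * rz  # cosine between heading and outward radial
    v = state.v
    if c > 0.0:
        # remove outward component of the velocity vector, keep what remains
        # along the heading: |v_vec - (v_vec.rhat)rhat| projected on heading
        v = v * (1.0 - c * c)
    return replace(state, x=x, z=z, v=v)


def terminal_speed(f_translation: float, cfg: PhysicsConfig) -> float:
    """Closed-form limit of the damped speed update under constant force.

    v_{n+1} = (v_n + F/m*dt)*a with a = max(1-drag*dt,0) converges to
    a*F*dt/(m*(1-a)) (geometric series).
    """
    a = max(1.0 - cfg.linear_drag * cfg.dt, 0.0)
    if a >= 1.0:
        return math.inf
    return a * f_translation * cfg.dt / (cfg.mass * (1.0 - a))
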