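"""Virtual Morris-water-maze (VMWM) trial and session protocol.

Each 2-minute trial starts the agent at one of four start positions with a
uniformly random heading.  Shocked-group agents receive a logged 300 ms
shock pulse every 2 s from trial onset until they first reach the invisible
safe zone (the pulse ceases on entry and the zone becomes visible only
while occupied).  Staying inside the zone for five consecutive seconds is a
success, after which movement stalls for the trial remainder; a trial whose
final position lies in the zone also counts as a success.  Trials are
separated by a 30 s inter-trial interval during which tail movement is
ignored, and a 10-minute break after every ten trials is recorded as
metadata.  Control-group agents run the identical protocol without shock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .config import ArenaConfig, PhysicsConfig, TrialConfig
from .locomotion import ForceCommand
from .physics import AgentState, resolve_boundary, step


@dataclass
class TrialObservation:
    """What a policy may see at each tick."""

    t: float
    in_safe_zone: bool
    shock_on: bool
    safe_zone_visible: bool


Policy = Callable[[AgentState, TrialObservation], ForceCommand]


def shock_pulse_phase(t: float, trial_cfg: TrialConfig) -> bool:
    """True while t falls inside a shock pulse window [k*period, k*period+pulse)."""
    return (t % trial_cfg.shock_period_s) < trial_cfg.shock_pulse_s - 1e-12


def shock_scheduler(
    t: float,
    in_safe_zone: bool,
    entered_before: bool,
    group: str,
    period_s: float = 2.0,
    pulse_s: float = 0.3,
) -> bool:
    """Shock state at time t.

    Control group: never.  Shocked group: pulse phase of the 300 ms / 2 s
    schedule, from trial start until the agent first reaches the safe zone;
    cessation on entry is permanent and shock is always off inside the zone.
    """
    if group != "shocked":
        return False
    if in_safe_zone or entered_before:
        return False
    return (t % period_s) < pulse_s - 1e-12


def safe_zone_visibility(in_safe_zone: bool) -> bool:
    """The safe zone is visible exactly while the agent occupies it."""
    return in_safe_zone


@dataclass
class TrialRecord:
    """Complete record of one trial: trajectory, per-tick flags and outcome."""

    start_position_id: int
    initial_heading_deg: float
    success: bool
    entered_safe_zone: bool
    time_to_success: Optional[float]
    t: Optional[np.ndarray] = None
    x: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None
    heading_deg: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    omega_deg_s: Optional[np.ndarray] = None
    in_safe_zone: Optional[np.ndarray] = None
    shock_on: Optional[np.ndarray] = None
    safe_zone_visible: Optional[np.ndarray] = None
    stalled: Optional[np.ndarray] = None

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.z])

    def summary(self) -> dict:
        return {
            "start_position_id": int(self.start_position_id),
            "initial_heading_deg": round(float(self.initial_heading_deg), 6),
            "success": bool(self.success),
            "entered_safe_zone": bool(self.entered_safe_zone),
            "time_to_success": None
            if self.time_to_success is None
            else round(float(self.time_to_success), 6),
        }


def init_trial(arena: ArenaConfig, rng: np.random.Generator) -> tuple[int, float, float, float]:
    """Draw a start position (uniform over the configured set) and a heading
    uniform on [0, 360).  Returns (position_id, x, z, heading_deg)."""
    ids = sorted(arena.start_positions)
    if not ids:
        raise ValueError("no start positions configured")
    pid = ids[rng.integers(len(ids))]
    x, z = arena.start_positions[pid]
    heading = float(rng.uniform(0.0, 360.0))
    return pid, x, z, heading


def run_trial(
    policy: Policy,
    arena: ArenaConfig,
    trial_cfg: TrialConfig,
    phys_cfg: PhysicsConfig,
    rng: np.random.Generator,
    record: bool = True,
    start: Optional[tuple[int, float, float, float]] = None,
) -> TrialRecord:
    """Run one trial tick loop; returns the TrialRecord (trajectory arrays
    omitted when record=False, for cheap outcome-only simulation)."""
    if start is None:
        start = init_trial(arena, rng)
    pid, x0, z0, h0 = start
    state = AgentState(x=x0, z=z0, heading_deg=h0, v=0.0, omega=0.0)

    dt = phys_cfg.dt
    n = int(round(trial_cfg.duration_s / dt))  # samples at t=0..duration inclusive -> n+1
    need_ticks = int(round(trial_cfg.stay_required_s / dt))

    if record:
        T = np.empty(n + 1)
        X = np.empty(n + 1)
        Z = np.empty(n + 1)
        H = np.empty(n + 1)
        V = np.empty(n + 1)
        W = np.empty(n + 1)
        IZ = np.zeros(n + 1, dtype=bool)
        SH = np.zeros(n + 1, dtype=bool)
        VI = np.zeros(n + 1, dtype=bool)
        ST = np.zeros(n + 1, dtype=bool)

    entered = False
    success = False
    time_to_success: Optional[float] = None
    timer = 0
    group = trial_cfg.group
    stall_from: Optional[int] = None

    for k in range(n + 1):
        t = k * dt
        inz = arena.in_safe_zone(state.x, state.z)
        shock = shock_scheduler(
            t, inz, entered, group, trial_cfg.shock_period_s, trial_cfg.shock_pulse_s
        )
        if inz:
            entered = True
            timer += 1
        else:
            timer = 0
        if record:
            T[k] = t
            X[k] = state.x
            Z[k] = state.z
            H[k] = state.heading_deg
            V[k] = state.v
            W[k] = math.degrees(state.omega)
            IZ[k] = inz
            SH[k] = shock
            VI[k] = safe_zone_visibility(inz)
        if not success and timer >= need_ticks:
            success = True
            time_to_success = t
            stall_from = k + 1
            break
        if k == n:
            break
        obs = TrialObservation(t=t, in_safe_zone=inz, shock_on=shock, safe_zone_visible=inz)
        cmd = policy(state, obs)
        state = resolve_boundary(step(state, cmd, phys_cfg), arena.radius)

    if success and record and stall_from is not None and stall_from <= n:
        ks = np.arange(stall_from, n + 1)
        T[ks] = ks * dt
        X[ks] = state.x
        Z[ks] = state.z
        H[ks] = state.heading_deg
        V[ks] = 0.0
        W[ks] = 0.0
        IZ[ks] = True
        SH[ks] = False
        VI[ks] = True
        ST[ks] = True

    if not success:
        # last-position clause: final sample inside the zone
        if arena.in_safe_zone(state.x, state.z):
            success = True
            time_to_success = trial_cfg.duration_s

    return TrialRecord(
        start_position_id=pid,
        initial_heading_deg=h0,
        success=success,
        entered_safe_zone=entered,
        time_to_success=time_to_success,
        t=T if record else None,
        x=X if record else None,
        z=Z if record else None,
        heading_deg=H if record else None,
        v=V if record else None,
        omega_deg_s=W if record else None,
        in_safe_zone=IZ if record else None,
        shock_on=SH if record else None,
        safe_zone_visible=VI if record else None,
        stalled=ST if record else None,
    )


@dataclass
class SessionRecord:
    """One day's ordered trials for one agent, plus protocol metadata."""

    agent_id: str
    day: int
    group: str
    trials: list[TrialRecord] = field(default_factory=list)
    iti_s: float = 30.0
    break_every_n_trials: int = 10
    break_minutes: float = 10.0
    seed: Optional[int] = None

    @property
    def successes(self) -> list[bool]:
        return [tr.success for tr in self.trials]

    @property
    def success_rate(self) -> float:
        if not self.trials:
            return float("nan")
        return float(np.mean(self.successes))

    def to_dict(self) -> dict:
        return {
            "agent_id": self.agent_id,
            "day": int(self.day),
            "group": self.group,
            "iti_s": self.iti_s,
            "break_every_n_trials": self.break_every_n_trials,
            "break_minutes": self.break_minutes,
            "seed": self.seed,
            "n_trials": len(self.trials),
            "success_rate": None if not self.trials else round(self.success_rate, 10),
            "trials": [tr.summary() for tr in self.trials],
        }


def run_session(
    policy: Policy,
    arena: ArenaConfig,
    trial_cfg: TrialConfig,
    phys_cfg: PhysicsConfig,
    n_trials: int,
    rng: np.random.Generator,
    agent_id: str = "agent",
    day: int = 1,
    record: bool = True,
    reset_policy: bool = False,
) -> SessionRecord:
    """Run n_trials sequentially.  The inter-trial interval is metadata only
    (tail movement during ITI never reaches the simulator).  Policies with a
    ``reset()`` method are reset per trial when reset_policy is True."""
    session = SessionRecord(
        agent_id=agent_id,
        day=day,
        group=trial_cfg.group,
        iti_s=trial_cfg.iti_s,
        break_every_n_trials=trial_cfg.break_every_n_trials,
        break_minutes=trial_cfg.break_minutes,
    )
    for _ in range(n_trials):
        if reset_policy and hasattr(policy, "reset"):
            policy.reset()
        session.trials.append(
            run_trial(policy, arena, trial_cfg, phys_cfg, rng, record=record)
        )
    return session
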