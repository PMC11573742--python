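"""Synthetic inputs for the whole stack: tail signals, silhouette frames,
histogram-sampled random swimmers, and goal-seeking agents.

No animal data ships with the package; everything the trackers, the task
and the statistics consume can be generated here.  The random swimmers
reproduce the published chance-level construction: artificial trajectories
whose per-tick speed and turn are drawn independently from kinematic
histograms whose shapes emulate the head-fixed VR data (speed peak at zero
with an exponential tail; symmetric zero-mean turn distribution).  Exact
bin contents of the rig histograms are not published, so only the shapes
are emulated; defaults are scaled to the simulator's own terminal speed
(~38 units/s) and turn rate (~3.9 deg/tick).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import ArenaConfig, LocomotionConfig, TrialConfig
from .locomotion import ForceCommand, TurnDirection, forces
from .physics import AgentState


# ---------------------------------------------------------------------------
# tail-deviation signals and silhouette frames
# ---------------------------------------------------------------------------

@dataclass
class TailPattern:
    """Parametric tail-deviation pattern.

    kinds: ``symmetric_oscillation`` (sinusoid about the bias),
    ``one_sided_oscillation`` (oscillates within one side of the bias, as
    occasionally seen in head-fixed fish), ``rest`` (constant bias), and
    ``bout_train`` (alternating oscillation bouts and rest).
    """

    kind: str = "symmetric_oscillation"
    frequency_hz: float = 3.0
    amplitude_px: float = 20.0
    bias_px: float = 0.0
    duration_s: float = 10.0
    noise_px: float = 0.0
    bout_s: float = 2.0
    rest_s: float = 2.0

    def __post_init__(self) -> None:
        kinds = ("symmetric_oscillation", "one_sided_oscillation", "rest", "bout_train")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")


def synth_tail_signal(
    pattern: TailPattern, rate_hz: float = 10.0, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Realize a TailPattern as a raw tail-deviation series (t, raw_px)."""
    if pattern.kind != "rest" and pattern.frequency_hz > rate_hz / 2 + 1e-12:
        raise ValueError("pattern frequency above Nyquist of the sampling rate")
    n = int(round(pattern.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    f, a, b = pattern.frequency_hz, pattern.amplitude_px, pattern.bias_px
    if pattern.kind == "rest":
        raw = np.full(n, b)
    elif pattern.kind == "symmetric_oscillation":
        raw = b + a * np.sin(2 * np.pi * f * t)
    elif pattern.kind == "one_sided_oscillation":
        # oscillates in [bias, bias + amplitude]: never crosses the bias side
        raw = b + 0.5 * a * (1.0 - np.cos(2 * np.pi * f * t))
    else:  # bout_train
        cycle = pattern.bout_s + pattern.rest_s
        in_bout = (t % cycle) < pattern.bout_s
        raw = np.where(in_bout, b + a * np.sin(2 * np.pi * f * t), b)
    if pattern.noise_px > 0:
        if rng is None:
            rng = np.random.default_rng()
        raw = raw + rng.normal(0.0, pattern.noise_px, size=n)
    return t, raw


def render_fish_frame(
    tail_deviation_px: float,
    shape: tuple[int, int] = (120, 160),
    body_rows: tuple[int, int] = (10, 110),
    head_x: float | None = None,
    half_width: float = 6.0,
    foreground: str = "dark",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a synthetic top-view fish silhouette with a known centerline.

    The centerline bends quadratically from ``head_x`` at the head row to
    ``head_x + tail_deviation_px`` at the tail row (a smooth C-bend), with a
    constant body half-width.  Returns ``(frame, rows, true_centerline)``;
    the ground-truth curve is the oracle for centerline-recovery tests.
    """
    h, w = shape
    r0, r1 = body_rows
    if head_x is None:
        head_x = w / 2.0
    rows = np.arange(r0, r1)
    s = (rows - r0) / max(r1 - 1 - r0, 1)
    center = head_x + tail_deviation_px * s**2
    bg, fg = (255, 0) if foreground == "dark" else (0, 255)
    frame = np.full((h, w), bg, dtype=np.uint8)
    for r, c in zip(rows, center):
        lo = max(int(math.ceil(c - half_width)), 0)
        hi = min(int(math.floor(c + half_width)), w - 1)
        frame[r, lo : hi + 1] = fg
    return frame, rows, center


# ---------------------------------------------------------------------------
# kinematic histograms and random swimmers
# ---------------------------------------------------------------------------

@dataclass
class KinematicsHistograms:
    """Speed (units/s) and turn (deg/tick, CW positive) sampling histograms.

    A bin whose two edges coincide is a point mass at that value (used for
    the resting-speed peak, so random swimmers produce genuinely static
    frames).  Probabilities must each sum to 1.
    """

    speed_edges: np.ndarray
    speed_probs: np.ndarray
    turn_edges: np.ndarray
    turn_probs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("speed", "turn"):
            edges = np.asarray(getattr(self, f"{name}_edges"), dtype=float)
            probs = np.asarray(getattr(self, f"{name}_probs"), dtype=float)
            setattr(self, f"{name}_edges", edges)
            setattr(self, f"{name}_probs", probs)
            if edges.size != probs.size + 1:
                raise ValueError(f"{name}: need len(edges) == len(probs) + 1")
            if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name}: probabilities must be non-negative and sum to 1")
            if np.any(np.diff(edges) < 0):
                raise ValueError(f"{name}: edges must be non-decreasing")
            setattr(self, f"{name}_probs", probs / probs.sum())  # absorb I/O rounding

    def _sample(self, edges, probs, rng, size) -> np.ndarray:
        bins = rng.choice(probs.size, size=size, p=probs)
        lo, hi = edges[bins], edges[bins + 1]
        return lo + (hi - lo) * rng.random(size)

    def sample_speed(self, rng: np.random.Generator, size) -> np.ndarray:
        return self._sample(self.speed_edges, self.speed_probs, rng, size)

    def sample_turn(self, rng: np.random.Generator, size) -> np.ndarray:
        return self._sample(self.turn_edges, self.turn_probs, rng, size)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, edges, probs in (
            ("speed", self.speed_edges, self.speed_probs),
            ("turn", self.turn_edges, self.turn_probs),
        ):
            for i, p in enumerate(probs):
                rows.append({"kind": kind, "bin_lo": edges[i], "bin_hi": edges[i + 1], "prob": p})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "KinematicsHistograms":
        df = pd.read_csv(path)
        out = {}
        for kind in ("speed", "turn"):
            sub = df[df["kind"] == kind]
            edges = np.append(sub["bin_lo"].to_numpy(float), sub["bin_hi"].to_numpy(float)[-1])
            out[f"{kind}_edges"] = edges
            out[f"{kind}_probs"] = sub["prob"].to_numpy(float)
        return cls(**out)


def default_histograms(
    rest_prob: float = 0.35,
    speed_max: float = 40.0,
    speed_scale: float = 10.0,
    turn_max: float = 4.0,
) -> KinematicsHistograms:
    """Default shapes: a resting point mass at speed 0 plus an exponential
    tail, and a symmetric zero-mean triangular turn distribution."""
    edges = np.concatenate([[0.0], np.arange(0.0, speed_max + 1e-9, 2.0)])
    centers = (edges[1:-1] + edges[2:]) / 2.0
    tail = np.exp(-centers / speed_scale)
    probs = np.concatenate([[rest_prob], (1.0 - rest_prob) * tail / tail.sum()])
    t_edges = np.arange(-turn_max, turn_max + 1e-9, 0.5)
    t_centers = (t_edges[:-1] + t_edges[1:]) / 2.0
    tri = turn_max - np.abs(t_centers)
    t_probs = tri / tri.sum()
    return KinematicsHistograms(edges, probs, t_edges, t_probs)


@dataclass
class Trajectory:
    """Light trajectory container used by the random-swimmer generator."""

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    heading_deg: np.ndarray
    start_position_id: int = 0

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.z])


def sample_random_trajectories(
    hists: KinematicsHistograms,
    starts: np.ndarray,
    headings0: np.ndarray,
    n_ticks: int,
    dt: float,
    arena_radius: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch of random trajectories.

    Per tick and per trajectory, a turn (deg) and a speed (units/s) are
    drawn independently; heading accumulates the turns and the position
    advances ``speed*dt`` along the heading, with escapes projected back to
    the arena circle.  Returns ``(positions, headings)`` of shapes
    ``(m, n_ticks+1, 2)`` and ``(m, n_ticks+1)``.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    m = starts.shape[0]
    pos = np.empty((m, n_ticks + 1, 2))
    hdg = np.empty((m, n_ticks + 1))
    pos[:, 0] = starts
    hdg[:, 0] = np.asarray(headings0, dtype=float)
    p = starts.copy()
    h = hdg[:, 0].copy()
    for k in range(1, n_ticks + 1):
        h = (h + hists.sample_turn(rng, m)) % 360.0
        speed = hists.sample_speed(rng, m)
        rad = np.radians(h)
        p = p + (speed * dt)[:, None] * np.column_stack([np.sin(rad), np.cos(rad)])
        r = np.hypot(p[:, 0], p[:, 1])
        out = r > arena_radius
        if out.any():
            p[out] *= (arena_radius / r[out])[:, None]
        pos[:, k] = p
        hdg[:, k] = h
    return pos, hdg


def sample_random_trajectory(
    hists: KinematicsHistograms,
    start,
    heading0: float,
    duration_s: float,
    dt: float,
    arena: ArenaConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Single random trajectory (see sample_random_trajectories)."""
    n = int(round(duration_s / dt))
    pos, hdg = sample_random_trajectories(
        hists, np.asarray([start]), np.asarray([heading0]), n, dt, arena.radius, rng
    )
    t = dt * np.arange(n + 1)
    return Trajectory(t=t, x=pos[0, :, 0], z=pos[0, :, 1], heading_deg=hdg[0])


def run_random_trials(
    hists: KinematicsHistograms,
    arena: ArenaConfig,
    trial_cfg: TrialConfig,
    n_per_position: int = 300,
    rng: Optional[np.random.Generator] = None,
    duration_s: Optional[float] = None,
    dt: float = 0.1,
) -> list[Trajectory]:
    """The chance-level construction: ``n_per_position`` random trajectories
    from each configured start position (1200 total at the default 300),
    each of trial length unless ``duration_s`` overrides it."""
    if rng is None:
        rng = np.random.default_rng()
    duration = trial_cfg.duration_s if duration_s is None else duration_s
    n_ticks = int(round(duration / dt))
    t = dt * np.arange(n_ticks + 1)
    out: list[Trajectory] = []
    for pid in sorted(arena.start_positions):
        starts = np.tile(arena.start_positions[pid], (n_per_position, 1))
        headings0 = rng.uniform(0.0, 360.0, size=n_per_position)
        pos, hdg = sample_random_trajectories(
            hists, starts, headings0, n_ticks, dt, arena.radius, rng
        )
        for i in range(n_per_position):
            out.append(
                Trajectory(t=t, x=pos[i, :, 0], z=pos[i, :, 1], heading_deg=hdg[i], start_position_id=pid)
            )
    return out


# ---------------------------------------------------------------------------
# agent policies
# ---------------------------------------------------------------------------

class RandomSwimPolicy:
    """Closed-loop null agent: each tick emits forces at a uniformly random
    HFR within fixed bounds and a random turn side."""

    def __init__(
        self,
        rng: np.random.Generator,
        loco: Optional[LocomotionConfig] = None,
        hfr_bounds: tuple[float, float] = (0.0, 0.75),
    ):
        self.rng = rng
        self.loco = loco or LocomotionConfig()
        self.hfr_min, self.hfr_max = hfr_bounds

    def __call__(self, state: AgentState, obs) -> ForceCommand:
        hfr = self.rng.uniform(self.hfr_min, self.hfr_max)
        cmd = forces(hfr, self.hfr_min, self.hfr_max, self.loco)
        cmd.turn_direction = (
            TurnDirection.CW if self.rng.random() < 0.5 else TurnDirection.CCW
        )
        return cmd


class GoalSeekingPolicy:
    """Positive-control agent that steers toward the safe-zone center.

    When misaligned beyond ``align_tol_deg`` it emits the turn-only regime
    (HFR at the lower bound) toward the goal; when aligned it emits the
    straight-swim regime (HFR at the upper bound); inside the safe zone it
    rests.  ``strength`` in [0, 1] is the per-tick probability of taking the
    goal-directed action instead of a random one (0 degenerates to a random
    walk); ``noise_deg`` jitters the perceived bearing.
    """

    def __init__(
        self,
        arena: ArenaConfig,
        rng: np.random.Generator,
        strength: float = 1.0,
        noise_deg: float = 0.0,
        loco: Optional[LocomotionConfig] = None,
        hfr_bounds: tuple[float, float] = (0.0, 0.75),
        align_tol_deg: float = 10.0,
    ):
        if not 0.0 <= strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        self.arena = arena
        self.rng = rng
        self.strength = strength
        self.noise_deg = noise_deg
        self.loco = loco or LocomotionConfig()
        self.hfr_min, self.hfr_max = hfr_bounds
        self.align_tol_deg = align_tol_deg
        self._random = RandomSwimPolicy(rng, self.loco, hfr_bounds)

    def __call__(self, state: AgentState, obs) -> ForceCommand:
        if obs.in_safe_zone:
            return ForceCommand(0.0, 0.0, TurnDirection.NONE)
        if self.strength == 0.0 or (
            self.strength < 1.0 and self.rng.random() >= self.strength
        ):
            return self._random(state, obs)
        cx, cz = self.arena.safe_center
        bearing = math.degrees(math.atan2(cx - state.x, cz - state.z))
        err = (bearing - state.heading_deg + 180.0) % 360.0 - 180.0
        if self.noise_deg > 0:
            err += self.rng.normal(0.0, self.noise_deg)
        if abs(err) <= self.align_tol_deg:
            cmd = forces(self.hfr_max, self.hfr_min, self.hfr_max, self.loco)
            cmd.turn_direction = TurnDirection.NONE
        else:
            cmd = forces(self.hfr_min, self.hfr_min, self.hfr_max, self.loco)
            cmd.turn_direction = TurnDirection.CW if err > 0 else TurnDirection.CCW
        return cmd


def reference_session_successes(
    rate: float, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Synthetic control-session outcome vector whose success count is
    round(rate * n_trials), with successes placed at random trial indices
    (used to stand in for reference control sessions)."""
    k = int(round(rate * n_trials))
    out = np.zeros(n_trials, dtype=bool)
    out[rng.choice(n_trials, size=k, replace=False)] = True
    return out
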