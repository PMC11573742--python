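"""Configuration dataclasses for the VR rig, physics, arena and trial protocol.

All defaults are the published rig parameters: a 10 Hz control loop, a
circular arena of radius 335 Unity units with an 80-unit safe zone centered
at (160, 160), 2-minute trials with a 300 ms shock pulse every 2 s, and
Unity rigid-body physics with mass 1, drag 1, angular drag 10000.

Coordinate convention (Unity, left-handed): positions are (X, Z) with X
right and Z forward; heading is measured in degrees clockwise from +Z, so
heading 0 points along +Z and heading 90 along +X.  Angles are stored in
degrees; physics works in radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class TailConfig:
    """Tail-tracking stage parameters.

    ``rate_hz`` is the camera/sampling rate of the deviation signal; the
    reference mid-position window is defined in seconds, so the number of
    samples in the moving average is ``reference_window_s * rate_hz``.
    """

    binarize_threshold: float = 128.0
    foreground: str = "dark"  # fish darker ("dark") or brighter ("bright") than background
    noise_threshold_px: float = 6.0  # usable range ~5-7 px
    reference_window_s: float = 10.0
    rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.foreground not in ("dark", "bright"):
            raise ConfigError(f"foreground must be 'dark' or 'bright', got {self.foreground!r}")
        if self.noise_threshold_px < 0:
            raise ConfigError("noise_threshold_px must be non-negative")
        if self.reference_window_s <= 0 or self.rate_hz <= 0:
            raise ConfigError("reference_window_s and rate_hz must be positive")

    @property
    def reference_window_samples(self) -> int:
        return max(1, int(round(self.reference_window_s * self.rate_hz)))


@dataclass
class LocomotionConfig:
    """Tail-to-force transform parameters.

    ``gain_translation`` (0.5-1) and ``gain_rotation`` (0.1-0.15) scale the
    squared HFR terms of the forward and turning forces.  The HFR band is
    1-5 Hz; its upper edge cannot exceed the Nyquist frequency of the
    control loop (``rate_hz / 2``).
    """

    gain_translation: float = 0.75
    gain_rotation: float = 0.12
    rate_hz: float = 10.0
    hfr_band_lo: float = 1.0
    hfr_band_hi: float = 5.0
    fft_window_samples: int = 32

    def __post_init__(self) -> None:
        if self.gain_translation <= 0 or self.gain_rotation <= 0:
            raise ConfigError("gains must be positive")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.hfr_band_hi > self.nyquist_hz + 1e-12:
            raise ConfigError(
                f"hfr_band_hi={self.hfr_band_hi} exceeds Nyquist {self.nyquist_hz} of rate_hz={self.rate_hz}"
            )
        if not 0 <= self.hfr_band_lo < self.hfr_band_hi:
            raise ConfigError("need 0 <= hfr_band_lo < hfr_band_hi")
        if self.fft_window_samples < 2:
            raise ConfigError("fft_window_samples must be >= 2")

    @property
    def nyquist_hz(self) -> float:
        return self.rate_hz / 2.0

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz


@dataclass
class PhysicsConfig:
    """Rigid-body emulation parameters (Unity convention: mass 1, drag 1,
    angular drag 10000).

    Drag acts as a multiplicative per-tick damping ``max(1 - drag*dt, 0)``;
    with angular drag 10000 and dt 0.1 the angular damping factor clamps to
    zero, so rotation carries no momentum between ticks and is purely
    force-driven.  ``speed_floor`` snaps near-zero coasting speeds to exactly
    zero so that a resting agent produces genuinely static frames.
    """

    mass: float = 1.0
    linear_drag: float = 1.0
    angular_drag: float = 10000.0
    dt: float = 0.1
    speed_floor: float = 0.01  # units/s below which v snaps to 0

    def __post_init__(self) -> None:
        if min(self.mass, self.linear_drag, self.angular_drag, self.dt) <= 0:
            raise ConfigError("mass, drags and dt must all be positive")
        if self.speed_floor < 0:
            raise ConfigError("speed_floor must be non-negative")


@dataclass
class ArenaConfig:
    """Circular VMWM arena geometry.

    Start positions P1-P3 are equidistant (within 0.13%) from the safe-zone
    center and lie in the three quadrants not containing the safe zone; P4
    is the arena center.  The safe zone covers (80/335)^2 = 5.7% of the
    arena, under the 6% bound of the rodent maze it mimics.
    """

    radius: float = 335.0
    safe_center: tuple[float, float] = (160.0, 160.0)
    safe_radius: float = 80.0
    start_positions: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {
            1: (160.0, -292.0),
            2: (-160.0, -160.0),
            3: (-292.0, 160.0),
            4: (0.0, 0.0),
        }
    )
    has_safe_zone: bool = True  # False = free-swim arena

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.safe_radius <= 0:
            raise ConfigError("radii must be positive")
        cx, cz = self.safe_center
        if math.hypot(cx, cz) + self.safe_radius > self.radius:
            raise ConfigError("safe zone must lie fully inside the arena")
        for pid, (x, z) in self.start_positions.items():
            if math.hypot(x, z) > self.radius:
                raise ConfigError(f"start position {pid} outside arena")

    def in_safe_zone(self, x: float, z: float) -> bool:
        """Agent-center-in-open-disk test for safe-zone occupancy."""
        if not self.has_safe_zone:
            return False
        cx, cz = self.safe_center
        return (x - cx) ** 2 + (z - cz) ** 2 < self.safe_radius**2

    @property
    def safe_zone_area_fraction(self) -> float:
        return (self.safe_radius / self.radius) ** 2


@dataclass
class TrialConfig:
    """VMWM trial protocol: 2-min trials, 30 s inter-trial interval, 300 ms
    shock every 2 s for the shocked group, and success after 5 consecutive
    seconds inside the safe zone (movement stalls for the trial remainder).

    Shock voltage (0.5-1 V in the rig) is recorded as metadata only; the
    simulated shock is a logged boolean event.
    """

    duration_s: float = 120.0
    iti_s: float = 30.0
    shock_pulse_s: float = 0.3
    shock_period_s: float = 2.0
    stay_required_s: float = 5.0
    group: str = "shocked"
    shock_voltage_v: float = 0.75  # metadata only
    break_every_n_trials: int = 10  # 10-min break metadata
    break_minutes: float = 10.0

    def __post_init__(self) -> None:
        if self.group not in ("control", "shocked"):
            raise ConfigError("group must be 'control' or 'shocked'")
        if not self.stay_required_s < self.duration_s:
            raise ConfigError("stay_required_s must be shorter than the trial")
        if not 0 < self.shock_pulse_s < self.shock_period_s:
            raise ConfigError("need 0 < shock_pulse_s < shock_period_s")


@dataclass
class DisplayConfig:
    """Virtual-camera layout metadata: left/front/right cameras each with a
    90 degree horizontal view (270 degrees total) plus a bottom camera; the
    camera object sits 50 units above the floor."""

    horizontal_fov_deg: tuple[float, float, float] = (90.0, 90.0, 90.0)
    camera_height_units: float = 50.0

    @property
    def total_horizontal_fov_deg(self) -> float:
        return float(sum(self.horizontal_fov_deg))


@dataclass
class RunConfig:
    """Aggregate run configuration (arena + trial + locomotion + physics +
    tail tracking), a random seed, and the experimental group."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)
    locomotion: LocomotionConfig = field(default_factory=LocomotionConfig)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    tail: TailConfig = field(default_factory=TailConfig)
    display: DisplayConfig = field(default_factory=DisplayConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        # tuples -> lists handled by yaml/json naturally
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        def tup(v):
            return tuple(v) if isinstance(v, (list, tuple)) else v

        arena_d = dict(d.get("arena", {}))
        if "safe_center" in arena_d:
            arena_d["safe_center"] = tup(arena_d["safe_center"])
        if "start_positions" in arena_d:
            arena_d["start_positions"] = {
                int(k): tup(v) for k, v in arena_d["start_positions"].items()
            }
        display_d = dict(d.get("display", {}))
        if "horizontal_fov_deg" in display_d:
            display_d["horizontal_fov_deg"] = tup(display_d["horizontal_fov_deg"])
        return cls(
            arena=ArenaConfig(**arena_d),
            trial=TrialConfig(**d.get("trial", {})),
            locomotion=LocomotionConfig(**d.get("locomotion", {})),
            physics=PhysicsConfig(**d.get("physics", {})),
            tail=TailConfig(**d.get("tail", {})),
            display=DisplayConfig(**display_d),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
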