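"""Tail-movement -> force transform.

The refined tail-movement signal oscillates when the fish beats its tail.
The high-frequency ratio (HFR) is the share of FFT magnitude in the 1-5 Hz
band out of all summed (non-DC) magnitudes up to the 5 Hz Nyquist limit of
the 10 Hz control loop.  HFR drives two mutually exclusive forces::

    F_translation = gain_translation * ((HFR(t) - HFR_min) * 10)^2
    F_rotation    = gain_rotation    * ((HFR_max - HFR(t)) * 10)^2

so a fast symmetric tail beat (high HFR) swims the fish straight while a
slow or one-sided beat (low HFR) turns it, with the squared terms
sharpening the mutual exclusiveness.  HFR_min / HFR_max are running bounds
updated continuously throughout an experiment (typically ~0 and 0.7-0.8).
Turn direction follows the side of the reference mid-position on which the
last two tail-end positions fell.
"""

from __future__ import annotations

import enum
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .config import LocomotionConfig


class TurnDirection(enum.Enum):
    CW = "CW"
    CCW = "CCW"
    NONE = "NONE"


@dataclass
class ForceCommand:
    """One control tick's output: forward force, turning force, turn side."""

    f_translation: float
    f_rotation: float
    turn_direction: TurnDirection = TurnDirection.NONE


def compute_hfr(buffer, cfg: LocomotionConfig, warn_short: bool = True) -> float:
    """High-frequency ratio of a trailing actual-movement window.

    Magnitude (not power) spectrum; the DC bin is excluded from both sums.
    Numerator: bins in [band_lo, band_hi] Hz.  Denominator: all bins in
    (0, band_hi] Hz.  An all-zero window returns 0 (0/0 convention).  A
    short buffer is zero-padded to the configured window and flagged as
    warm-up with a warning.
    """
    buf = np.asarray(buffer, dtype=float)
    n = cfg.fft_window_samples
    if buf.size < n:
        if warn_short:
            warnings.warn("HFR warm-up: buffer shorter than FFT window, zero-padding", stacklevel=2)
        buf = np.concatenate([np.zeros(n - buf.size), buf])
    elif buf.size > n:
        buf = buf[-n:]
    mags = np.abs(np.fft.rfft(buf))
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.rate_hz)
    denom_mask = (freqs > 0) & (freqs <= cfg.hfr_band_hi + 1e-12)
    num_mask = denom_mask & (freqs >= cfg.hfr_band_lo - 1e-12)
    denom = mags[denom_mask].sum()
    if denom == 0.0:
        return 0.0
    return float(mags[num_mask].sum() / denom)


@dataclass
class HFRState:
    """Running HFR with continuously updated min/max bounds and the FFT buffer."""

    hfr: float = 0.0
    hfr_min: float = float("inf")
    hfr_max: float = float("-inf")
    buffer: deque = None  # set in __post_init__

    def __post_init__(self):
        if self.buffer is None:
            self.buffer = deque()

    @property
    def initialized(self) -> bool:
        return self.hfr_min <= self.hfr_max


def update_bounds(state: HFRState, hfr: float) -> HFRState:
    """Fold a new HFR value into the running min/max bounds."""
    state.hfr = hfr
    state.hfr_min = min(state.hfr_min, hfr)
    state.hfr_max = max(state.hfr_max, hfr)
    return state


def forces(hfr: float, hfr_min: float, hfr_max: float, cfg: LocomotionConfig) -> ForceCommand:
    """Evaluate the two force equations at the current HFR.

    Degenerate bounds (hfr_max == hfr_min) yield zero forces.  The turn
    direction is left NONE here; the streaming transform (or an agent
    policy) assigns it.
    """
    if hfr_max <= hfr_min:
        return ForceCommand(0.0, 0.0, TurnDirection.NONE)
    f_t = cfg.gain_translation * ((hfr - hfr_min) * 10.0) ** 2
    f_r = cfg.gain_rotation * ((hfr_max - hfr) * 10.0) ** 2
    return ForceCommand(f_t, f_r, TurnDirection.NONE)


def turn_direction(tail_positions, reference_mid: float) -> TurnDirection:
    """Turn side from the last two tail-end positions vs the reference mid.

    Both strictly right of the reference -> CW (rightward turn); both
    strictly left -> CCW; mixed, on-reference, or fewer than two samples ->
    NONE.
    """
    if len(tail_positions) < 2:
        return TurnDirection.NONE
    a, b = tail_positions[-2], tail_positions[-1]
    if a > reference_mid and b > reference_mid:
        return TurnDirection.CW
    if a < reference_mid and b < reference_mid:
        return TurnDirection.CCW
    return TurnDirection.NONE


class LocomotionTransform:
    """Streaming transform: one (actual movement, raw tail position) sample
    in, one ForceCommand out per control tick.

    HFR bounds persist for the lifetime of the transform (one agent or
    fish-session per instance).  When the two-sample turn criterion is not
    met the previously held direction is kept, so an ongoing one-sided
    oscillation keeps turning the same way.
    """

    def __init__(self, cfg: LocomotionConfig | None = None, hold_direction: bool = True):
        self.cfg = cfg or LocomotionConfig()
        self.state = HFRState()
        self._last_raw: deque[float] = deque(maxlen=2)
        self._direction = TurnDirection.NONE
        self.hold_direction = hold_direction

    def tick(self, actual_movement: float, raw_dev: float, reference_mid: float) -> ForceCommand:
        self.state.buffer.append(actual_movement)
        while len(self.state.buffer) > self.cfg.fft_window_samples:
            self.state.buffer.popleft()
        hfr = compute_hfr(self.state.buffer, self.cfg, warn_short=False)
        update_bounds(self.state, hfr)
        cmd = forces(hfr, self.state.hfr_min, self.state.hfr_max, self.cfg)
        self._last_raw.append(raw_dev)
        d = turn_direction(list(self._last_raw), reference_mid)
        if d is TurnDirection.NONE and self.hold_direction:
            d = self._direction
        else:
            self._direction = d
        cmd.turn_direction = d
        return cmd

    def reset_bounds(self) -> None:
        """Reset HFR bounds (new agent/fish; bounds persist across trials otherwise)."""
        self.state = HFRState()


def force_trace_frame(times, hfrs, commands):
    """Assemble a force trace table (t_s, hfr, f_trans, f_rot, direction)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t_s": times,
            "hfr": hfrs,
            "f_trans": [c.f_translation for c in commands],
            "f_rot": [c.f_rotation for c in commands],
            "direction": [c.turn_direction.value for c in commands],
        }
    )
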