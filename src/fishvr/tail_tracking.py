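"""Tail tracking: silhouette frames -> signed tail-deviation signal.

A top-view camera images the head-fixed fish with the body along the image
row axis (row 0 = head end).  Each frame is binarized, the largest connected
foreground blob kept, and a centerline formed by connecting per-row blob
midpoints.  The tail-end deviation is the x-difference between the mean of
the three lowermost and three uppermost centerline points (positive = tail
right of the upper body).  Because individual fish rest with a left/right
bias that drifts over minutes, the deviation is referenced against a
trailing-window mean ("reference mid-position", 10 s by default), and a
noise threshold (5-7 px in practice) is soft-subtracted to give the "actual
movement" driving locomotion.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label


class NoFishError(ValueError):
    """Raised when binarization leaves no foreground blob in the frame."""


def binarize(frame: np.ndarray, threshold: float, foreground: str = "dark") -> np.ndarray:
    """Threshold a grayscale frame into a boolean foreground mask."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2D grayscale raster")
    if foreground == "dark":
        return frame < threshold
    if foreground == "bright":
        return frame > threshold
    raise ValueError(f"unknown foreground polarity {foreground!r}")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise NoFishError("no fish detected: empty foreground mask")
    if n > 1:
        warnings.warn(f"{n} foreground blobs; using the largest", stacklevel=3)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        return labels == int(np.argmax(sizes))
    return labels == 1


def _row_midpoint(row: np.ndarray) -> float:
    """Midpoint of the longest foreground run in one mask row.

    Rows where the blob is split into several runs take the midpoint of the
    longest run (ties -> first).
    """
    idx = np.flatnonzero(row)
    # split into consecutive runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    lengths = ends - starts
    k = int(np.argmax(lengths))
    lo, hi = idx[starts[k]], idx[ends[k]]
    return (lo + hi) / 2.0


def extract_centerline(
    frame: np.ndarray, binarize_threshold: float, foreground: str = "dark"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the body centerline as per-row midpoints, ordered head->tail.

    Returns ``(rows, midpoints)`` where ``rows`` are the row indices that
    intersect the fish blob and ``midpoints`` the corresponding x
    coordinates (column units).  Rows without foreground are omitted.
    """
    mask = binarize(frame, binarize_threshold, foreground)
    blob = _largest_component(mask)
    rows = np.flatnonzero(blob.any(axis=1))
    mids = np.array([_row_midpoint(blob[r]) for r in rows], dtype=float)
    return rows, mids


def body_endpoints(midpoints: np.ndarray) -> tuple[float, float]:
    """Mean x of the three uppermost and three lowermost centerline points.

    Raises if the centerline has fewer than 6 points (fish too short or
    occluded).
    """
    midpoints = np.asarray(midpoints, dtype=float)
    if midpoints.size < 6:
        raise ValueError("fish too short/occluded: centerline has < 6 points")
    return float(midpoints[:3].mean()), float(midpoints[-3:].mean())


def raw_deviation(upper_body_x: float, tail_end_x: float) -> float:
    """Signed tail-end deviation: positive when the tail is right of the upper body."""
    return tail_end_x - upper_body_x


def refine_movement(raw_dev: float, reference_mid: float, noise_threshold: float) -> float:
    """Soft-threshold the referenced deviation to suppress pixel noise.

    Let ``m = raw_dev - reference_mid``; returns ``sign(m) * max(|m| -
    noise_threshold, 0)``, preserving the left/right sign needed for the
    turn-direction rule.
    """
    if noise_threshold < 0:
        raise ValueError("noise_threshold must be non-negative")
    m = raw_dev - reference_mid
    return math.copysign(max(abs(m) - noise_threshold, 0.0), m) if m else 0.0


class ReferenceMid:
    """Trailing-window running mean of raw deviations.

    The window is defined in seconds; sample count = window_s * rate_hz.
    During warm-up (fewer samples than the window) the mean of the available
    samples is used.
    """

    def __init__(self, window_s: float = 10.0, rate_hz: float = 10.0):
        n = max(1, int(round(window_s * rate_hz)))
        self._buf: deque[float] = deque(maxlen=n)
        self._sum = 0.0

    def update(self, raw_dev: float) -> float:
        if len(self._buf) == self._buf.maxlen:
            self._sum -= self._buf[0]
        self._buf.append(raw_dev)
        self._sum += raw_dev
        return self.value

    @property
    def value(self) -> float:
        if not self._buf:
            return 0.0
        # re-sum occasionally would guard drift; window <= ~1e3 floats is benign
        return self._sum / len(self._buf)

    @property
    def filled(self) -> bool:
        return len(self._buf) == self._buf.maxlen


@dataclass
class DeviationSample:
    """One tick of the tail-deviation signal (all values in px)."""

    t: float
    raw_deviation: float
    reference_mid: float
    actual_movement: float


@dataclass
class DeviationSeries:
    """Tail-deviation time series; columns t_s, raw_px, reference_px, actual_px."""

    t: np.ndarray
    raw: np.ndarray
    reference: np.ndarray
    actual: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "raw_px": self.raw, "reference_px": self.reference, "actual_px": self.actual}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "DeviationSeries":
        df = pd.read_csv(path)
        return cls(
            t=df["t_s"].to_numpy(float),
            raw=df["raw_px"].to_numpy(float),
            reference=df["reference_px"].to_numpy(float),
            actual=df["actual_px"].to_numpy(float),
        )


class TailTracker:
    """Streaming tracker: frames (or raw deviations) in, DeviationSamples out."""

    def __init__(self, cfg=None):
        from .config import TailConfig

        self.cfg = cfg or TailConfig()
        self.reference = ReferenceMid(self.cfg.reference_window_s, self.cfg.rate_hz)
        self._t = 0.0

    def process_deviation(self, raw_dev: float, t: float | None = None) -> DeviationSample:
        """Advance the tracker by one pre-computed raw deviation sample."""
        if t is None:
            t = self._t
        ref = self.reference.update(raw_dev)
        act = refine_movement(raw_dev, ref, self.cfg.noise_threshold_px)
        self._t = t + 1.0 / self.cfg.rate_hz
        return DeviationSample(t=t, raw_deviation=raw_dev, reference_mid=ref, actual_movement=act)

    def process_frame(self, frame: np.ndarray, t: float | None = None) -> DeviationSample:
        _, mids = extract_centerline(frame, self.cfg.binarize_threshold, self.cfg.foreground)
        upper, tail = body_endpoints(mids)
        return self.process_deviation(raw_deviation(upper, tail), t)

    def process_series(self, raw_devs) -> DeviationSeries:
        """Run a whole raw-deviation array through the reference/threshold stages."""
        raw = np.asarray(raw_devs, dtype=float)
        dt = 1.0 / self.cfg.rate_hz
        t = self._t + dt * np.arange(raw.size)
        ref = np.empty_like(raw)
        act = np.empty_like(raw)
        for i, r in enumerate(raw):
            s = self.process_deviation(float(r))
            ref[i] = s.reference_mid
            act[i] = s.actual_movement
        return DeviationSeries(t=t, raw=raw, reference=ref, actual=act)
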