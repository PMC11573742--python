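"""Trajectory statistics for the VMWM task.

* Straightness index SI = D/L: endpoint displacement over path length,
  in [0, 1]; 1 for a straight monotone path, 0 for a closed loop.
* Cumulative distance: per-frame distance to the safe-zone center summed
  until the success condition is met.
* Success conversion rate: successes / trials with at least one safe-zone
  entry (how often an entry is converted into a success).
* Moving success rate: mean success of the last ten trials, per trial.
* Persistence maps over a lattice of point places inside the arena.  Two
  definitions: mean distance reduction toward a place per moving frame
  (P(A) = sum_t (D_A(t-1) - D_A(t)) / N_mov), and the baseline-corrected
  fraction of moves toward the place (P = (G/N - R)/(1 - R), R = 0.5, in
  [-1, 1]).  Frames where the distance to the place does not change are
  excluded from both.
* Goal headedness: the fraction of frames whose forward head-direction ray
  intersects the safe zone, split into GH_static (frames where the position
  did not change from the previous frame) and GH_move (frames where it did).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import ranksums


# ---------------------------------------------------------------------------
# scalar trajectory statistics
# ---------------------------------------------------------------------------

def straightness_index(positions: np.ndarray) -> float:
    """SI = D/L for a (T, 2) position array; a zero-length path returns 0."""
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("positions must be (T, 2)")
    if p.shape[0] < 2:
        return float("nan")
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    L = steps.sum()
    if L == 0.0:
        return 0.0
    D = float(np.linalg.norm(p[-1] - p[0]))
    return min(D / L, 1.0)


def cumulative_distance(
    positions: np.ndarray, safe_center, success_index: Optional[int] = None
) -> float:
    """Sum of per-frame distances to the safe-zone center over frames
    [0, success_index] (whole trajectory when success_index is None)."""
    p = np.asarray(positions, dtype=float)
    if success_index is not None:
        p = p[: success_index + 1]
    d = np.linalg.norm(p - np.asarray(safe_center, dtype=float), axis=1)
    return float(d.sum())


def success_conversion_rate(successes: Sequence[bool], entries: Sequence[bool]) -> float:
    """successes / trials-with-entry; NaN when no trial entered the zone."""
    successes = np.asarray(successes, dtype=bool)
    entries = np.asarray(entries, dtype=bool)
    if successes.shape != entries.shape:
        raise ValueError("successes and entries must align")
    if np.any(successes & ~entries):
        raise ValueError("a success without a safe-zone entry is impossible")
    n_entries = int(entries.sum())
    if n_entries == 0:
        return float("nan")
    return float(successes.sum() / n_entries)


def moving_success_rate(successes: Sequence[bool], window: int = 10) -> np.ndarray:
    """Per-trial mean success of the trailing ``window`` trials (the
    available prefix before the window fills)."""
    s = np.asarray(successes, dtype=float)
    out = np.empty_like(s)
    c = np.concatenate([[0.0], np.cumsum(s)])
    for i in range(s.size):
        lo = max(0, i + 1 - window)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


# ---------------------------------------------------------------------------
# point grids and persistence maps
# ---------------------------------------------------------------------------

@dataclass
class PointGrid:
    """Axis-aligned square lattice of point places strictly inside the arena."""

    points: np.ndarray  # (G, 2)
    spacing: float
    arena_radius: float

    def __len__(self) -> int:
        return self.points.shape[0]


def build_point_grid(arena_radius: float, spacing: float = 10.0) -> PointGrid:
    """Origin-centered lattice; points with distance < arena_radius kept.

    Spacing 10 on the 335-unit arena gives 3521 point places.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if arena_radius <= 0:
        return PointGrid(points=np.empty((0, 2)), spacing=spacing, arena_radius=arena_radius)
    n = int(math.floor(arena_radius / spacing))
    axis = spacing * np.arange(-n, n + 1)
    xx, zz = np.meshgrid(axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), zz.ravel()])
    keep = (pts**2).sum(axis=1) < arena_radius**2
    return PointGrid(points=pts[keep], spacing=spacing, arena_radius=arena_radius)


@dataclass
class PersistenceMap:
    """Per-point-place persistence values with the defining method tag."""

    grid: PointGrid
    values: np.ndarray  # (G,)
    method: str  # "mean_reduction" | "fraction"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.grid.points[:, 0], "z": self.grid.points[:, 1], "value": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def to_raster(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (x_axis, z_axis, raster) with NaN outside the arena."""
        pts, sp = self.grid.points, self.grid.spacing
        xs = np.unique(pts[:, 0])
        zs = np.unique(pts[:, 1])
        raster = np.full((xs.size, zs.size), np.nan)
        ix = np.searchsorted(xs, pts[:, 0])
        iz = np.searchsorted(zs, pts[:, 1])
        raster[ix, iz] = self.values
        return xs, zs, raster


def _distance_diffs(positions: np.ndarray, grid_points: np.ndarray) -> np.ndarray:
    """(T-1, G) matrix of D_A(t-1) - D_A(t) for every point place A."""
    d = cdist(np.asarray(positions, dtype=float), grid_points)
    return d[:-1] - d[1:]


def persistence_map_meanreduction(positions: np.ndarray, grid: PointGrid) -> PersistenceMap:
    """Mean distance reduction toward each place per moving frame.

    N_mov counts frames where the distance to the place changed; places the
    trajectory never moved relative to (e.g. a fully stationary trial) get 0.
    """
    p = np.asarray(positions, dtype=float)
    if p.shape[0] < 2 or len(grid) == 0:
        return PersistenceMap(grid, np.zeros(len(grid)), "mean_reduction")
    red = _distance_diffs(p, grid.points)
    moved = red != 0.0
    n_mov = moved.sum(axis=0)
    total = np.where(moved, red, 0.0).sum(axis=0)
    values = np.divide(total, n_mov, out=np.zeros(len(grid)), where=n_mov > 0)
    return PersistenceMap(grid, values, "mean_reduction")


def persistence_map_fraction(
    positions: np.ndarray, grid: PointGrid, random_move_prob: float = 0.5
) -> PersistenceMap:
    """Baseline-corrected fraction of moves toward each place:
    P = (G/N - R)/(1 - R) with R the probability of a random move being
    toward the place (0.5); in [-1, 1] at R = 0.5.  Moves with no distance
    change are excluded from both G and N."""
    if random_move_prob >= 1.0:
        raise ValueError("random_move_prob must be < 1")
    p = np.asarray(positions, dtype=float)
    if p.shape[0] < 2 or len(grid) == 0:
        return PersistenceMap(grid, np.zeros(len(grid)), "fraction")
    red = _distance_diffs(p, grid.points)
    toward = (red > 0.0).sum(axis=0)
    n = (red != 0.0).sum(axis=0)
    frac = np.divide(toward, n, out=np.zeros(len(grid)), where=n > 0)
    values = np.where(n > 0, (frac - random_move_prob) / (1.0 - random_move_prob), 0.0)
    return PersistenceMap(grid, values, "fraction")


def average_maps(maps: Sequence[PersistenceMap]) -> PersistenceMap:
    """Pointwise mean of per-trial maps (the group-average map)."""
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0]
    for m in maps[1:]:
        if m.method != ref.method or not np.array_equal(m.grid.points, ref.grid.points):
            raise ValueError("maps must share grid and method")
    values = np.mean([m.values for m in maps], axis=0)
    return PersistenceMap(ref.grid, values, ref.method)


def persistence_pvalue_map(
    maps_a: Sequence[PersistenceMap], maps_b: Sequence[PersistenceMap]
) -> np.ndarray:
    """Per-point-place two-sample Wilcoxon rank-sum p-values between two
    groups of per-trial maps (no multiplicity correction)."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    a = np.stack([m.values for m in maps_a])
    b = np.stack([m.values for m in maps_b])
    return ranksums(a, b, axis=0).pvalue


def quadrant_means(pmap: PersistenceMap) -> dict[str, float]:
    """Mean persistence per quadrant (UR = x>0,z>0; axis points excluded)."""
    x, z = pmap.grid.points[:, 0], pmap.grid.points[:, 1]
    v = pmap.values
    return {
        "upper_right": float(v[(x > 0) & (z > 0)].mean()),
        "upper_left": float(v[(x < 0) & (z > 0)].mean()),
        "lower_left": float(v[(x < 0) & (z < 0)].mean()),
        "lower_right": float(v[(x > 0) & (z < 0)].mean()),
    }


def upper_right_bias(pmap: PersistenceMap) -> float:
    """Upper-right-quadrant mean minus the mean of the other three quadrants."""
    q = quadrant_means(pmap)
    others = (q["upper_left"] + q["lower_left"] + q["lower_right"]) / 3.0
    return q["upper_right"] - others


# ---------------------------------------------------------------------------
# goal headedness
# ---------------------------------------------------------------------------

def goal_directed(position, heading_deg, safe_center, safe_radius: float) -> bool:
    """True iff the forward ray from the position along the heading
    intersects the closed safe-zone disk (always true from inside it)."""
    px, pz = position
    cx, cz = safe_center
    wx, wz = cx - px, cz - pz
    if wx * wx + wz * wz <= safe_radius * safe_radius:
        return True
    h = math.radians(heading_deg)
    ux, uz = math.sin(h), math.cos(h)
    s = wx * ux + wz * uz  # projection of the center onto the ray
    if s <= 0.0:
        return False
    perp2 = wx * wx + wz * wz - s * s
    return perp2 <= safe_radius * safe_radius


def _goal_directed_mask(x, z, heading_deg, safe_center, safe_radius) -> np.ndarray:
    cx, cz = safe_center
    wx, wz = cx - np.asarray(x, float), cz - np.asarray(z, float)
    w2 = wx**2 + wz**2
    h = np.radians(np.asarray(heading_deg, float))
    s = wx * np.sin(h) + wz * np.cos(h)
    r2 = safe_radius**2
    return (w2 <= r2) | ((s > 0) & (w2 - s**2 <= r2))


@dataclass
class GHResult:
    """Goal-headedness split into static and moving frames (NaN for an
    empty class)."""

    gh_static: float
    gh_move: float
    n_static: int
    n_move: int
    n_static_goal: int
    n_move_goal: int


def gh_metrics(
    x,
    z,
    heading_deg,
    safe_center,
    safe_radius: float,
    static_eps: float = 0.0,
) -> GHResult:
    """Classify frames 1..T-1 as static (position unchanged from the
    previous frame, within ``static_eps``) or moving, and compute the
    goal-directed fraction of each class.  Frame 0 has no previous frame
    and is excluded."""
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    heading_deg = np.asarray(heading_deg, float)
    if x.size < 2:
        return GHResult(float("nan"), float("nan"), 0, 0, 0, 0)
    dx = np.abs(np.diff(x))
    dz = np.abs(np.diff(z))
    static = (dx <= static_eps) & (dz <= static_eps)
    goal = _goal_directed_mask(x[1:], z[1:], heading_deg[1:], safe_center, safe_radius)
    n_static = int(static.sum())
    n_move = int((~static).sum())
    n_static_goal = int((goal & static).sum())
    n_move_goal = int((goal & ~static).sum())
    gh_s = n_static_goal / n_static if n_static else float("nan")
    gh_m = n_move_goal / n_move if n_move else float("nan")
    return GHResult(gh_s, gh_m, n_static, n_move, n_static_goal, n_move_goal)
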