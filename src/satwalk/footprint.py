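"""Footprint-field kinematics for 1D cell tracks.

The footprint field ``phi(x, t)`` is the cumulative time the cell body
has covered position ``x`` up to time ``t`` — a proxy for any deposited
physicochemical signal.  Correlating the centre-of-mass acceleration
with the field values at the two cell ends (``phi_l``, ``phi_r``) reveals
whether the cell is pushed back when it reaches the frontier of its own
footprint: an inward acceleration where the field is strongly asymmetric
(``delta_phi = phi_r - phi_l`` large) and none in the interior.

Units: time in hours, positions in micrometres, acceleration in um/h^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binned_statistic_2d

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "CellTrack",
    "FootprintField",
    "EdgeSampleSeries",
    "AccelHeatmap",
    "compute_footprint_field",
    "sample_edge_footprints",
    "centroid_acceleration",
    "acceleration_heatmap",
]

_TOL = 1e-9


@dataclass
class CellTrack:
    """A continuous-space, continuous-time single-cell record.

    1D tracks carry the centroid ``x`` and optionally the cell-edge
    positions ``x_left <= x <= x_right``; 2D tracks carry ``x`` and ``y``.
    Times are in hours and strictly increasing, positions in um.
    """

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    x_left: np.ndarray | None = None
    x_right: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValidationError(f"cell {self.cell_id}: empty or non-1D time axis")
        if self.x.shape != self.t.shape:
            raise ValidationError(f"cell {self.cell_id}: x and t shapes differ")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.x)):
            raise ValidationError(f"cell {self.cell_id}: non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(
                f"cell {self.cell_id}: time not strictly increasing at row {row}")
        for name in ("x_left", "x_right", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != self.t.shape or not np.all(np.isfinite(v)):
                    raise ValidationError(
                        f"cell {self.cell_id}: bad column {name}")
                setattr(self, name, v)
        if (self.x_left is None) != (self.x_right is None):
            raise ValidationError(
                f"cell {self.cell_id}: x_left and x_right must come together")
        if self.has_edges:
            bad = self.x_left > self.x_right + _TOL
            if np.any(bad):
                row = int(np.argmax(bad))
                raise ValidationError(
                    f"cell {self.cell_id}: x_left > x_right at row {row}")
            out = (self.x < self.x_left - _TOL) | (self.x > self.x_right + _TOL)
            if np.any(out):
                row = int(np.argmax(out))
                raise ValidationError(
                    f"cell {self.cell_id}: centroid outside cell at row {row}")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def has_edges(self) -> bool:
        return self.x_left is not None

    @property
    def is_2d(self) -> bool:
        return self.y is not None

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def length(self) -> np.ndarray:
        """Instantaneous cell length x_right - x_left, um."""
        if not self.has_edges:
            raise ValidationError(f"cell {self.cell_id}: no edge columns")
        return self.x_right - self.x_left

    def mirrored(self) -> "CellTrack":
        """The track reflected through x = 0 (left/right swapped)."""
        return CellTrack(
            cell_id=f"{self.cell_id}~mirror",
            t=self.t.copy(),
            x=-self.x,
            x_left=None if self.x_right is None else -self.x_right,
            x_right=None if self.x_left is None else -self.x_left,
            y=None if self.y is None else self.y.copy(),
        )


@dataclass
class FootprintField:
    """Cumulative occupancy phi(x, t) on a uniform spatial grid.

    ``phi`` has shape (n_frames, n_bins), units hours; ``grid`` holds the
    bin centres (um) with uniform spacing ``dx``.  phi is non-negative
    and non-decreasing in time at every bin, and conserves occupancy:
    sum_x phi(x, t) * dx equals the running time-integral of cell length.
    """

    grid: np.ndarray
    times: np.ndarray
    phi: np.ndarray
    dx: float

    def value_at(self, frame: int, position: float) -> float:
        """Nearest-bin field value at ``position`` using the field accumulated
        up to (and including) ``frame``; 0 outside the grid or for frame < 0."""
        if frame < 0:
            return 0.0
        i = int(round((position - self.grid[0]) / self.dx))
        if i < 0 or i >= self.grid.size:
            return 0.0
        return float(self.phi[frame, i])


@dataclass
class EdgeSampleSeries:
    """Per-frame (phi_l, phi_r, acceleration) samples for one cell."""

    cell_id: str
    t: np.ndarray
    phi_l: np.ndarray
    phi_r: np.ndarray
    accel: np.ndarray

    @property
    def delta_phi(self) -> np.ndarray:
        return self.phi_r - self.phi_l


@dataclass
class AccelHeatmap:
    """Mean centroid acceleration binned over (phi_l, phi_r)."""

    phi_l_edges: np.ndarray
    phi_r_edges: np.ndarray
    mean_accel: np.ndarray  # (n_l, n_r); NaN where empty
    counts: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def compute_footprint_field(track: CellTrack, dx: float = 2.0) -> FootprintField:
    """Accumulate the footprint field of a 1D edge-resolved track.

    phi(x, t_n) = sum_{m <= n} dt_m * [x in [x_left(t_m), x_right(t_m)]],
    with dt_m = t_m - t_(m-1) and partial bin coverage counted
    fractionally, which makes the occupancy conservation identity exact
    up to float round-off.
    """
    if dx <= 0 or not np.isfinite(dx):
        raise ValidationError("dx must be positive and finite")
    if track.is_2d:
        raise ValidationError("footprint fields are 1D only")
    if not track.has_edges:
        raise ValidationError(f"cell {track.cell_id}: edge columns required")
    if track.n_frames < 2:
        raise InsufficientDataError(
            f"cell {track.cell_id}: need >= 2 frames to accumulate a field")
    lo = np.floor(track.x_left.min() / dx) * dx
    hi = np.ceil(track.x_right.max() / dx) * dx
    n_bins = max(int(round((hi - lo) / dx)), 1)
    edges = lo + dx * np.arange(n_bins + 1)
    centers = edges[:-1] + dx / 2.0

    dt = np.diff(track.t)
    # fractional overlap of [l, r] with each bin, per frame (vectorised)
    l = track.x_left[1:, None]
    r = track.x_right[1:, None]
    overlap = np.clip(np.minimum(r, edges[None, 1:]) -
                      np.maximum(l, edges[None, :-1]), 0.0, None) / dx
    dep = np.zeros((track.n_frames, n_bins))
    dep[1:] = dt[:, None] * overlap
    phi = np.cumsum(dep, axis=0)
    return FootprintField(grid=centers, times=track.t.copy(), phi=phi, dx=float(dx))


def centroid_acceleration(track: CellTrack, smooth_window: int = 3) -> np.ndarray:
    """Second central finite difference of the (smoothed) centroid, um/h^2.

    The centroid is moving-average smoothed over ``smooth_window`` frames
    (1 = no smoothing) before differentiating; the two endpoints are
    undefined and returned as NaN.
    """
    if track.n_frames < 3:
        raise InsufficientDataError(
            f"cell {track.cell_id}: need >= 3 frames for an acceleration")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValidationError("smooth_window must be a positive odd integer")
    xs = _moving_average(track.x, smooth_window)
    t = track.t
    a = np.full(t.size, np.nan)
    # three-point second difference on a possibly non-uniform grid;
    # exact for quadratics, endpoints stay undefined
    h1 = t[1:-1] - t[:-2]
    h2 = t[2:] - t[1:-1]
    a[1:-1] = 2.0 * (h1 * xs[2:] - (h1 + h2) * xs[1:-1] + h2 * xs[:-2]) \
        / (h1 * h2 * (h1 + h2))
    return a


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return x.astype(float)
    half = window // 2
    c = np.cumsum(np.concatenate(([0.0], x)))
    n = x.size
    idx_hi = np.minimum(np.arange(n) + half + 1, n)
    idx_lo = np.maximum(np.arange(n) - half, 0)
    return (c[idx_hi] - c[idx_lo]) / (idx_hi - idx_lo)


def sample_edge_footprints(field: FootprintField, track: CellTrack,
                           smooth_window: int = 3) -> EdgeSampleSeries:
    """Sample phi at the two cell ends, per frame, with the acceleration.

    The field is evaluated with the occupancy accumulated *strictly
    before* each frame (a frame's own occupancy cannot causally enter its
    acceleration reading), nearest-bin; positions outside the grid read 0.
    """
    if field.times.shape != track.t.shape or not np.allclose(field.times, track.t):
        raise ValidationError("field and track must share the time axis")
    if not track.has_edges:
        raise ValidationError(f"cell {track.cell_id}: edge columns required")
    n = track.n_frames
    phi_l = np.empty(n)
    phi_r = np.empty(n)
    for i in range(n):
        phi_l[i] = field.value_at(i - 1, track.x_left[i])
        phi_r[i] = field.value_at(i - 1, track.x_right[i])
    accel = centroid_acceleration(track, smooth_window=smooth_window)
    return EdgeSampleSeries(cell_id=track.cell_id, t=track.t.copy(),
                            phi_l=phi_l, phi_r=phi_r, accel=accel)


def acceleration_heatmap(samples, bin_width: float = 2.0,
                         max_phi: float | None = None) -> AccelHeatmap:
    """Pool edge samples from many cells into a mean-acceleration heatmap.

    Linear bins of ``bin_width`` hours on both phi axes, capped at the
    largest observed phi (or ``max_phi``); bins with no samples are NaN.
    """
    series = list(samples)
    if not series:
        raise InsufficientDataError("no edge-sample series supplied")
    phi_l = np.concatenate([s.phi_l for s in series])
    phi_r = np.concatenate([s.phi_r for s in series])
    a = np.concatenate([s.accel for s in series])
    ok = np.isfinite(a)
    phi_l, phi_r, a = phi_l[ok], phi_r[ok], a[ok]
    top = max_phi if max_phi is not None else max(phi_l.max(), phi_r.max())
    top = max(top, bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    mean, le, re, _ = binned_statistic_2d(phi_l, phi_r, a, statistic="mean",
                                          bins=[edges, edges])
    cnt, _, _, _ = binned_statistic_2d(phi_l, phi_r, a, statistic="count",
                                       bins=[edges, edges])
    return AccelHeatmap(phi_l_edges=le, phi_r_edges=re,
                        mean_accel=mean, counts=cnt.astype(int))
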