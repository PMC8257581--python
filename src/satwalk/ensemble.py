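"""Ensemble statistics: ageing increments, MSD, first passage, oscillations.

The central observable is the mean squared increment

    I(T, t) = < [x(t + t0) - x(t0)]^2 >,   t0 sliding in [T, T + window],

whose dependence on the age ``T`` (ageing) is the statistical signature
of long-lived spatial memory: a memoryless walk gives age-independent
increments, a self-attracting walk does not.  First-passage statistics
to a single target at distance ``r`` are summarised by the survival
probability S(t), whose power-law tail S ~ t^-theta defines the
persistence exponent; the PSATW prediction is theta = e^-beta / 2
(the universal memoryless value 1/2 at beta = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import FitError, InsufficientDataError, ParameterError
from .footprint import CellTrack, _moving_average
from .walks import WalkParams, first_passage_times

__all__ = [
    "IncrementCurve",
    "SurvivalCurve",
    "ExponentFit",
    "OscillationSummary",
    "increments",
    "increments_from_tracks",
    "msd",
    "survival_probability",
    "survival_exponent",
    "fit_power_exponent",
    "theta_theory",
    "detect_oscillations",
    "effective_diffusion",
    "ageing_z",
]


@dataclass
class IncrementCurve:
    """Mean squared increments I(T, t) per (age, lag) with their SEM."""

    ages: np.ndarray       # measurement start times T (time units)
    lags: np.ndarray       # lag grid t
    values: np.ndarray     # (n_ages, n_lags)
    sem: np.ndarray        # (n_ages, n_lags), across walkers
    n_walkers: int
    dt: float = 1.0


@dataclass
class SurvivalCurve:
    """Fraction of walkers that have not yet hit the target site +r."""

    times: np.ndarray
    S: np.ndarray
    sem: np.ndarray
    r: int
    n_walkers: int
    hit_times: np.ndarray  # censored at t_max + 1


@dataclass
class ExponentFit:
    """A log-log power-law fit with its diagnostics.

    ``good_fit`` is False when a quadratic term in log-time is detected
    at more than 3 of its standard errors (model mismatch, e.g. an
    exponential rather than a power law).
    """

    exponent: float
    stderr: float
    window: tuple
    n_points: int
    r_squared: float
    curvature: float
    curvature_stderr: float

    @property
    def good_fit(self) -> bool:
        # absolute floor guards against float round-off on exact power laws
        return abs(self.curvature) <= 3.0 * self.curvature_stderr + 1e-9


@dataclass
class OscillationSummary:
    """Turning-point decomposition of an oscillatory 1D track."""

    cell_id: str
    times: np.ndarray       # turning-point times, h
    positions: np.ndarray   # centroid at the turning points, um
    amplitudes: np.ndarray  # |dx| between consecutive turning points, um
    periods: np.ndarray     # time between successive same-sign reversals, h
    ratios: np.ndarray      # amplitude / period, um/h

    @property
    def n_reversals(self) -> int:
        return self.times.size


def _sq_disp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # upcast the (small) difference slices only; avoids a float copy of
    # the full ensemble when positions are stored as integers
    d = np.asarray(a - b, dtype=np.float64)
    if d.ndim == 3:
        return np.sum(d * d, axis=-1)
    return d * d


def default_lags(window: int) -> np.ndarray:
    """Log-spaced integer lags from 1 up to window // 3."""
    top = max(window // 3, 1)
    lags = np.unique(np.round(np.geomspace(1, top, 30)).astype(int))
    return lags


def increments(paths: np.ndarray, ages, window: int, lags=None,
               dt: float = 1.0) -> IncrementCurve:
    """Aged mean squared increments of an ensemble of trajectories.

    ``paths`` has shape (n_walkers, n_frames) in 1D or (..., 2) in 2D,
    on a regular grid of spacing ``dt``.  Ages, window and lags are in
    frames.  For each age T, I(T, t) averages over all walkers and all
    start frames t0 in [T, T + window]; the SEM is across walkers (the
    sliding average is taken within each walker first).  Lags default to
    a log grid up to window // 3.
    """
    paths = np.asarray(paths)
    if paths.ndim == 2:
        n_w, n_t = paths.shape
    elif paths.ndim == 3 and paths.shape[2] == 2:
        n_w, n_t = paths.shape[:2]
    else:
        raise ParameterError("paths must be (n_walkers, n_frames[, 2])")
    ages = np.asarray(ages, int)
    if lags is None:
        lags = default_lags(window)
    lags = np.asarray(lags, int)
    if np.any(lags < 1):
        raise ParameterError("lags must be >= 1 frame")
    if window < 0:
        raise ParameterError("window must be >= 0")
    needed = int(ages.max()) + window + int(lags.max())
    if needed > n_t - 1:
        raise InsufficientDataError(
            f"trajectories have {n_t - 1} steps; need {needed} "
            "(age + window + max lag)")
    vals = np.empty((ages.size, lags.size))
    sems = np.empty_like(vals)
    for a, T in enumerate(ages):
        base = paths[:, T:T + window + 1]
        for j, lag in enumerate(lags):
            shifted = paths[:, T + lag:T + window + lag + 1]
            per_walker = _sq_disp(shifted, base).mean(axis=1)
            vals[a, j] = per_walker.mean()
            sems[a, j] = per_walker.std(ddof=1) / math.sqrt(n_w) if n_w > 1 else np.nan
    return IncrementCurve(ages=ages * dt, lags=lags * dt, values=vals,
                          sem=sems, n_walkers=n_w, dt=dt)


def increments_from_tracks(tracks, ages_h=(0.0, 6.0, 12.0, 18.0, 24.0),
                           window_h: float = 12.0, lags_h=None) -> IncrementCurve:
    """Increment curves from CellTracks sampled on a common regular grid.

    Follows the standard windowing protocol for cell tracks: pieces of
    ``window_h`` (default 12 h) starting at the requested ages, lags cut
    at window/3 (default 4 h).  Tracks are truncated to the shortest one.
    """
    tracks = list(tracks)
    if not tracks:
        raise InsufficientDataError("no tracks supplied")
    dts = [np.diff(tr.t) for tr in tracks]
    dt = float(np.median(np.concatenate(dts)))
    for tr, d in zip(tracks, dts):
        if not np.allclose(d, dt, rtol=1e-6, atol=1e-9):
            raise ParameterError(
                f"cell {tr.cell_id}: tracks must share one regular frame grid")
    n_t = min(tr.n_frames for tr in tracks)
    if tracks[0].is_2d:
        paths = np.stack([np.column_stack([tr.x[:n_t], tr.y[:n_t]]) for tr in tracks])
    else:
        paths = np.stack([tr.x[:n_t] for tr in tracks])
    ages = np.round(np.asarray(ages_h, float) / dt).astype(int)
    window = int(round(window_h / dt))
    lags = (None if lags_h is None
            else np.round(np.asarray(lags_h, float) / dt).astype(int))
    return increments(paths, ages, window, lags=lags, dt=dt)


def msd(paths: np.ndarray, dt: float = 1.0, squared: bool = True):
    """Ensemble displacement from the origin.

    Returns (times, values, sem).  ``squared=True`` (default) gives the
    mean squared displacement <||x(t) - x(0)||^2>; ``squared=False`` the
    mean norm <||x(t) - x(0)||>.
    """
    paths = np.asarray(paths)
    if paths.ndim == 2:
        per = _sq_disp(paths, paths[:, :1])
    else:
        per = _sq_disp(paths, paths[:, :1, :])
    if not squared:
        per = np.sqrt(per)
    n_w = per.shape[0]
    times = dt * np.arange(per.shape[1])
    sem = (per.std(axis=0, ddof=1) / math.sqrt(n_w)) if n_w > 1 else np.full(per.shape[1], np.nan)
    return times, per.mean(axis=0), sem


def survival_probability(params: WalkParams, r: int, n_walkers: int, t_max: int,
                         seed: int, initial_direction: int | None = None) -> SurvivalCurve:
    """Monte-Carlo survival probability of a single target at site +r (1D).

    S(t) is the fraction of independent walkers that have not yet
    visited +r by step t; the binomial SEM sqrt(S(1-S)/n) is attached.
    """
    hits = first_passage_times(params, r, n_walkers, t_max, seed,
                               initial_direction=initial_direction)
    times = np.arange(t_max + 1)
    # S(t) = P(hit > t); hits are censored at t_max + 1
    order = np.sort(hits)
    S = 1.0 - np.searchsorted(order, times, side="right") / n_walkers
    sem = np.sqrt(np.clip(S * (1.0 - S), 0.0, None) / n_walkers)
    return SurvivalCurve(times=times, S=S, sem=sem, r=int(r),
                         n_walkers=int(n_walkers), hit_times=hits)


def fit_power_exponent(x: np.ndarray, y: np.ndarray, window: tuple) -> ExponentFit:
    """Least-squares log-log slope of y(x) over the window (x_lo, x_hi).

    Refuses windows containing non-positive values and windows with
    fewer than 5 usable points.  The standard error is the OLS slope
    error; the quadratic-curvature diagnostic flags non-power-law decay.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo, hi = window
    m = (x >= lo) & (x <= hi) & np.isfinite(y) & (x > 0)
    if np.any(m & (y <= 0)):
        raise FitError("window contains non-positive values; shrink it")
    if m.sum() < 5:
        raise FitError(f"need >= 5 usable points in window, got {int(m.sum())}")
    lx = np.log(x[m])
    ly = np.log(y[m])
    n = lx.size
    (c1, c0), cov = np.polyfit(lx, ly, 1, cov=True)
    resid = ly - (c0 + c1 * lx)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    if n >= 4:
        coef2, cov2 = np.polyfit(lx, ly, 2, cov=True)
        curv, curv_se = coef2[0], math.sqrt(max(cov2[0, 0], 0.0))
    else:  # pragma: no cover - guarded by the n >= 5 check
        curv, curv_se = 0.0, math.inf
    return ExponentFit(exponent=float(c1), stderr=float(math.sqrt(max(cov[0, 0], 0.0))),
                       window=(float(lo), float(hi)), n_points=int(n),
                       r_squared=float(r2), curvature=float(curv),
                       curvature_stderr=float(curv_se) if curv_se > 0 else 1e-30)


def survival_exponent(curve: SurvivalCurve, s_window=(1e-3, 1e-1),
                      t_window=None, n_points: int = 50, n_boot: int = 200,
                      seed: int = 0) -> ExponentFit:
    """Persistence exponent theta from the survival tail.

    Fits -d log S / d log t on the time range where S lies inside
    ``s_window`` (default [1e-3, 1e-1]), sampled at log-spaced times;
    the standard error is a walker bootstrap (the OLS error on a step
    curve would be badly miscalibrated).  ``t_window=(t_lo, t_hi)``
    overrides the S-based selection with an explicit time range — the
    natural choice when the local exponent is still converging and only
    the latest simulated decade is asymptotic.
    """
    if t_window is not None:
        t_lo, t_hi = max(int(t_window[0]), 1), int(t_window[1])
    else:
        s_lo, s_hi = s_window
        below_hi = np.nonzero(curve.S <= s_hi)[0]
        if below_hi.size == 0:
            raise FitError(
                f"survival never drops to {s_hi}; increase t_max or walkers")
        t_lo = max(int(curve.times[below_hi[0]]), 1)
        below_lo = np.nonzero(curve.S < s_lo)[0]
        t_hi = (int(curve.times[below_lo[0]]) if below_lo.size
                else int(curve.times[-1]))
    if t_hi <= t_lo:
        raise FitError("empty survival fit window")
    grid = np.unique(np.round(np.geomspace(t_lo, t_hi, n_points)).astype(int))

    def _theta(hits):
        order = np.sort(hits)
        S = 1.0 - np.searchsorted(order, grid, side="right") / hits.size
        ok = S > 0
        fit = fit_power_exponent(grid[ok], S[ok], (grid[0], grid[-1]))
        return fit, -fit.exponent

    fit, theta = _theta(curve.hit_times)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = curve.hit_times.size
    for b in range(n_boot):
        resampled = curve.hit_times[rng.integers(0, n, n)]
        try:
            boot[b] = _theta(resampled)[1]
        except FitError:
            boot[b] = np.nan
    stderr = float(np.nanstd(boot, ddof=1))
    return ExponentFit(exponent=float(theta), stderr=stderr,
                       window=(float(grid[0]), float(grid[-1])),
                       n_points=fit.n_points, r_squared=fit.r_squared,
                       curvature=fit.curvature,
                       curvature_stderr=fit.curvature_stderr)


def theta_theory(beta: float) -> float:
    """PSATW persistence exponent theta = e^-beta / 2 (1/2 at beta = 0)."""
    if not math.isfinite(beta):
        raise ParameterError("beta must be finite")
    return math.exp(-beta) / 2.0


def detect_oscillations(track: CellTrack, min_excursion: float = 10.0,
                        smooth_window: int = 3) -> OscillationSummary:
    """Turning-point analysis of an oscillatory 1D centroid track.

    Turning points are sign changes of the smoothed centroid velocity
    whose excursion reaches ``min_excursion`` um (peak prominence);
    amplitudes are read between consecutive turning points on the raw
    centroid, periods between successive same-sign reversals.  A track
    with no turning points yields an empty summary.
    """
    xs = _moving_average(track.x, smooth_window) if smooth_window > 1 else track.x
    peaks_hi, _ = find_peaks(xs, prominence=min_excursion)
    peaks_lo, _ = find_peaks(-xs, prominence=min_excursion)
    idx = np.sort(np.concatenate([peaks_hi, peaks_lo]))
    kind = np.isin(idx, peaks_hi)  # True = maximum
    # enforce alternation: among consecutive same-kind turns keep the extreme one
    keep = []
    for i, (j, hi) in enumerate(zip(idx, kind)):
        if keep and kind[keep[-1]] == hi:
            prev = idx[keep[-1]]
            better = (track.x[j] > track.x[prev]) if hi else (track.x[j] < track.x[prev])
            if better:
                keep[-1] = i
        else:
            keep.append(i)
    idx = idx[keep]
    times = track.t[idx]
    pos = track.x[idx]
    amplitudes = np.abs(np.diff(pos))
    periods = times[2:] - times[:-2]
    n_ratio = min(amplitudes.size, periods.size)
    ratios = amplitudes[:n_ratio] / periods[:n_ratio]
    return OscillationSummary(cell_id=track.cell_id, times=times, positions=pos,
                              amplitudes=amplitudes, periods=periods, ratios=ratios)


def effective_diffusion(times: np.ndarray, msd_values: np.ndarray,
                        window: tuple, dim: int) -> float:
    """Effective diffusion constant from a linear MSD fit: D = slope / (2 dim)."""
    if dim not in (1, 2):
        raise ParameterError("dim must be 1 or 2")
    times = np.asarray(times, float)
    msd_values = np.asarray(msd_values, float)
    lo, hi = window
    m = (times >= lo) & (times <= hi) & np.isfinite(msd_values)
    if m.sum() < 2:
        raise FitError("need >= 2 points in the MSD fit window")
    slope = np.polyfit(times[m], msd_values[m], 1)[0]
    return float(slope / (2.0 * dim))


def ageing_z(curve: IncrementCurve) -> float:
    """Largest between-age discrepancy of I(T, t), in combined SEM units.

    z < 3 across all lags is consistent with no ageing; systematically
    larger values indicate age-dependent increments.
    """
    n_ages = curve.ages.size
    z = 0.0
    for a in range(n_ages):
        for b in range(a + 1, n_ages):
            denom = np.sqrt(curve.sem[a] ** 2 + curve.sem[b] ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                zz = np.abs(curve.values[a] - curve.values[b]) / denom
            z = max(z, float(np.nanmax(zz)))
    return z
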