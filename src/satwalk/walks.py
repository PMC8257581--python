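"""Lattice models of self-attracting random walks.

Two minimal models of cells that deposit long-lived footprints along
their path and preferentially stay on previously visited ground:

* the 1D **persistent self-attracting walk** (PSATW): a nearest-neighbour
  walk with directional persistence set by ``k >= 0`` and an inward bias
  at the frontier of the visited domain set by ``beta`` (negative values
  mean self-attraction).  Within the visited domain the walker reverses
  with probability ``p_ri = e^-k / (e^-k + e^k)``; when the site ahead has
  never been visited it reverses with ``p_re = e^(-k-b) / (e^(-k-b) + e^k)``.
  The persistence length (and, at unit speed, time) is ``l_p = e^(2k)``.

* the 2D **self-attracting walk** (SATW) on the square lattice: each jump
  to one of the 4 neighbours is weighted by ``exp(-beta * f(n))`` where
  ``n`` is the neighbour's visit count and ``f`` is the saturating memory
  ``f(0) = 0, f(n > 0) = 1``.  No persistence term.

Walkers start at the origin (counted as visited once) with a uniformly
random initial direction, so the very first step applies the edge rule
symmetrically.  Visit counts are incremented on arrival, before the next
step is classified.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _kernels
from .exceptions import ParameterError

__all__ = [
    "WalkParams",
    "WalkerState",
    "LatticeTrajectory",
    "reversal_prob_interior",
    "reversal_prob_edge",
    "satw_jump_weights",
    "simulate_psatw_1d",
    "simulate_satw_2d",
    "simulate_ensemble",
    "first_passage_times",
    "child_seeds",
]

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent per-walker seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence`; the rule is deterministic, so
    ensembles are reproducible and independent of execution order.
    """
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) & _SEED_MASK).astype(np.int64)


@dataclass(frozen=True)
class WalkParams:
    """Governing parameters (k, beta) of the PSATW/SATW models.

    Parameters
    ----------
    k : float
        Persistence parameter, dimensionless, >= 0.  Sets the persistence
        length ``l_p = e^(2k)`` in lattice units.
    beta : float
        Footprint-coupling parameter, dimensionless; negative values bias
        the walker towards previously visited sites (self-attraction).
    dim : int
        Spatial dimension, 1 (PSATW) or 2 (SATW).
    """

    k: float
    beta: float = 0.0
    dim: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and math.isfinite(self.beta)):
            raise ParameterError("k and beta must be finite")
        if self.k < 0:
            raise ParameterError(f"k must be >= 0, got {self.k}")
        if self.dim not in (1, 2):
            raise ParameterError(f"dim must be 1 or 2, got {self.dim}")

    @property
    def persistence_length(self) -> float:
        """l_p = e^(2k), in lattice units."""
        return math.exp(2.0 * self.k)

    @property
    def persistence_time(self) -> float:
        """t_p = e^(2k) steps (unit walker speed)."""
        return math.exp(2.0 * self.k)


@dataclass
class WalkerState:
    """Instantaneous state of a lattice walker (for inspection/tests).

    ``visits`` maps site -> visit count n_i; absent sites have n_i = 0.
    """

    site: object
    direction: object
    step_index: int
    visits: dict = field(default_factory=dict)

    @property
    def total_visits(self) -> int:
        return sum(self.visits.values())


@dataclass(frozen=True)
class LatticeTrajectory:
    """A simulated lattice path together with its generating parameters.

    ``sites`` has shape (n_steps+1,) in 1D or (n_steps+1, 2) in 2D;
    consecutive sites differ by exactly one lattice unit.
    """

    sites: np.ndarray
    params: WalkParams
    seed: int

    @property
    def n_steps(self) -> int:
        return self.sites.shape[0] - 1

    def span(self) -> np.ndarray:
        """Extent of the visited domain after each step.

        1D: width (in sites) of the visited interval.  2D: number of
        distinct visited sites.  Non-decreasing by construction.
        """
        if self.params.dim == 1:
            hi = np.maximum.accumulate(self.sites)
            lo = np.minimum.accumulate(self.sites)
            return hi - lo + 1
        seen: set = set()
        out = np.empty(self.sites.shape[0], np.int64)
        for i, xy in enumerate(map(tuple, self.sites)):
            seen.add(xy)
            out[i] = len(seen)
        return out

    def visit_counts(self) -> Counter:
        """Final per-site visit counts n_i."""
        if self.params.dim == 1:
            return Counter(self.sites.tolist())
        return Counter(map(tuple, self.sites))

    def states(self):
        """Yield :class:`WalkerState` after each arrival (for invariants)."""
        visits: Counter = Counter()
        prev = None
        for i in range(self.sites.shape[0]):
            cur = self.sites[i] if self.params.dim == 1 else tuple(self.sites[i])
            visits[cur] += 1
            direction = None if prev is None else np.subtract(cur, prev)
            yield WalkerState(site=cur, direction=direction, step_index=i,
                              visits=dict(visits))
            prev = cur

    def to_frame(self, walker_id: int = 0):
        """Export as a tidy table (walker_id, step, x[, y])."""
        import pandas as pd

        n = self.sites.shape[0]
        cols = {"walker_id": np.full(n, walker_id), "step": np.arange(n)}
        if self.params.dim == 1:
            cols["x"] = self.sites
        else:
            cols["x"] = self.sites[:, 0]
            cols["y"] = self.sites[:, 1]
        return pd.DataFrame(cols)


def _check_finite(**kwargs) -> None:
    for name, val in kwargs.items():
        if not math.isfinite(val):
            raise ParameterError(f"{name} must be finite, got {val}")


def reversal_prob_interior(k: float) -> float:
    """Reversal probability p_ri = e^-k / (e^-k + e^k) inside the visited domain."""
    _check_finite(k=k)
    return float(expit(-2.0 * k))


def reversal_prob_edge(k: float, beta: float) -> float:
    """Reversal probability p_re = e^(-k-b) / (e^(-k-b) + e^k) at the frontier.

    For beta < 0 this exceeds the interior probability: the walker is
    biased back into the visited domain.
    """
    _check_finite(k=k, beta=beta)
    return float(expit(-(2.0 * k + beta)))


def satw_jump_weights(neighbor_visits, beta: float) -> np.ndarray:
    """Normalised SATW jump probabilities over a set of neighbours.

    Weight of neighbour j is proportional to ``exp(-beta * f(n_j))`` with
    the saturating memory f(0)=0, f(n>0)=1.
    """
    _check_finite(beta=beta)
    counts = np.asarray(neighbor_visits)
    if counts.size == 0:
        raise ParameterError("need at least one neighbour")
    if np.any(counts < 0):
        raise ParameterError("visit counts must be >= 0")
    w = np.exp(-beta * (counts > 0).astype(float))
    return w / w.sum()


def _init_dirs(n: int, initial_direction) -> np.ndarray:
    if initial_direction is None:
        return np.zeros(n, np.int64)  # kernel draws uniformly
    if initial_direction not in (-1, 1):
        raise ParameterError("initial_direction must be -1, +1 or None")
    return np.full(n, initial_direction, np.int64)


def simulate_psatw_1d(params: WalkParams, n_steps: int, seed: int,
                      initial_direction: int | None = None) -> LatticeTrajectory:
    """Simulate one 1D PSATW path of ``n_steps`` unit hops.

    At each step, the edge rule (p_re) applies iff the site ahead in the
    current direction is unvisited, otherwise the interior rule (p_ri);
    the arrival site's visit count is incremented on arrival.  Identical
    (params, n_steps, seed) give bit-identical trajectories.
    """
    if params.dim != 1:
        raise ParameterError("simulate_psatw_1d requires dim=1 parameters")
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    seeds = child_seeds(seed, 1)
    dirs = _init_dirs(1, initial_direction)
    sites = _kernels.psatw_paths_1d(params.k, params.beta, int(n_steps), seeds, dirs)[0]
    return LatticeTrajectory(sites=sites, params=params, seed=int(seed))


def simulate_satw_2d(params: WalkParams, n_steps: int, seed: int) -> LatticeTrajectory:
    """Simulate one 2D SATW path on the square lattice (no persistence)."""
    if params.dim != 2:
        raise ParameterError("simulate_satw_2d requires dim=2 parameters")
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    seeds = child_seeds(seed, 1)
    sites = _kernels.satw_paths_2d(params.beta, int(n_steps), seeds)[0]
    return LatticeTrajectory(sites=sites, params=params, seed=int(seed))


def simulate_ensemble(params: WalkParams, n_steps: int, n_walkers: int, seed: int,
                      initial_direction: int | None = None) -> np.ndarray:
    """Simulate an ensemble of independent walkers from one master seed.

    Returns positions with shape (n_walkers, n_steps+1) in 1D and
    (n_walkers, n_steps+1, 2) in 2D.
    """
    if n_steps < 1 or n_walkers < 1:
        raise ParameterError("n_steps and n_walkers must be >= 1")
    seeds = child_seeds(seed, n_walkers)
    if params.dim == 1:
        dirs = _init_dirs(n_walkers, initial_direction)
        return _kernels.psatw_paths_1d(params.k, params.beta, int(n_steps), seeds, dirs)
    return _kernels.satw_paths_2d(params.beta, int(n_steps), seeds)


def first_passage_times(params: WalkParams, r: int, n_walkers: int, t_max: int,
                        seed: int, initial_direction: int | None = None) -> np.ndarray:
    """First-passage steps of 1D PSATW walkers to the single target site +r.

    Walkers start at the origin on an infinite line; entries equal
    ``t_max + 1`` for walkers that never reach the target (censored).
    """
    if params.dim != 1:
        raise ParameterError("first-passage simulation is 1D only")
    if r < 1:
        raise ParameterError("target distance r must be >= 1")
    if t_max < 1 or n_walkers < 1:
        raise ParameterError("t_max and n_walkers must be >= 1")
    seeds = child_seeds(seed, n_walkers)
    dirs = _init_dirs(n_walkers, initial_direction)
    return _kernels.psatw_fpt_1d(params.k, params.beta, int(r), int(t_max), seeds, dirs)
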