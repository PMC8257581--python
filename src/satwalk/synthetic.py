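"""Synthetic single-cell track generator.

Produces continuous-space, continuous-time 1D cell tracks with the
statistical structure the rest of the pipeline assumes, so every stage
is testable without microscopy data: sawtooth oscillatory centroids
whose amplitude grows slowly, roughly constant run speed, a
bi-exponential hop-duration distribution (mean 0.6 h), cell-to-cell
variability of (k, beta) and of the cell scale, transient elongation
during polarity reversals, and frame-level positional noise.

Two presets mirror the two experimental conditions:

* ``control`` — pristine substrate: strongly negative mean beta, so
  cells oscillate within and slowly extend their own footprint;
* ``conditioned`` — substrate pre-covered by a previous cell
  population's footprints: no frontier left to sense, modelled as
  beta ~= 0 with the *same* persistence k as the control.

Every dataset records the generating truth per cell and a manifest from
which it can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import _kernels
from .exceptions import ParameterError
from .footprint import CellTrack
from .walks import WalkParams, child_seeds

__all__ = [
    "PopulationModel",
    "CellSpec",
    "SyntheticDataset",
    "PRESETS",
    "sample_population",
    "render_continuous_track",
    "generate_dataset",
    "dataset_from_manifest",
]


@dataclass(frozen=True)
class PopulationModel:
    """Hyperparameters of the synthetic cell population.

    ``k`` is drawn per cell from a normal truncated to k >= 0, ``beta``
    from an untruncated normal.  The per-cell spatial scale L_ref (um)
    is log-normal with median ``L_ref_um`` and log-sd ``L_ref_cv``; the
    cell length at rest equals its L_ref.  Hop durations are a
    bi-exponential mixture (weight ``jump_mix_weight`` on the fast
    component) whose overall mean is 0.6 h at the defaults.  During a
    polarity reversal the cell transiently elongates by up to
    ``reversal_elongation_um`` (triangular ramp over the reversal hop).
    Frames are 6 min apart (the 1D time-lapse rate) and positions carry
    a shared Gaussian jitter of ``noise_sigma_um``.
    """

    k_mean: float = 1.0
    k_std: float = 0.3
    beta_mean: float = -2.0
    beta_std: float = 0.5
    L_ref_um: float = 20.0
    L_ref_cv: float = 0.1
    jump_mix_weight: float = 0.7
    jump_mean_fast_h: float = 0.3
    jump_mean_slow_h: float = 1.3
    reversal_elongation_um: float = 30.0
    frame_dt_h: float = 0.1
    noise_sigma_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_std", "beta_std", "L_ref_cv", "noise_sigma_um",
                     "reversal_elongation_um"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("L_ref_um", "jump_mean_fast_h", "jump_mean_slow_h",
                     "frame_dt_h"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.jump_mix_weight <= 1.0:
            raise ParameterError("jump_mix_weight must lie in [0, 1]")
        if self.k_mean < 0:
            raise ParameterError("k_mean must be >= 0")

    @property
    def mean_jump_h(self) -> float:
        """Mean hop duration of the bi-exponential mixture, hours."""
        w = self.jump_mix_weight
        return w * self.jump_mean_fast_h + (1.0 - w) * self.jump_mean_slow_h


PRESETS: dict[str, PopulationModel] = {
    "control": PopulationModel(),
    "conditioned": replace(PopulationModel(), beta_mean=0.0, beta_std=0.2),
}


@dataclass(frozen=True)
class CellSpec:
    """Generating truth for one synthetic cell."""

    cell_id: str
    params: WalkParams
    L_ref: float


@dataclass
class SyntheticDataset:
    """Synthetic tracks plus the generating truth and a manifest."""

    tracks: list
    truth: pd.DataFrame
    manifest: dict


def sample_population(model: PopulationModel, n_cells: int, seed: int) -> list[CellSpec]:
    """Draw per-cell (k, beta, L_ref) from the population hyperparameters."""
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if model.k_std == 0:
        ks = np.full(n_cells, model.k_mean)
    else:
        a = (0.0 - model.k_mean) / model.k_std
        ks = truncnorm.rvs(a, np.inf, loc=model.k_mean, scale=model.k_std,
                           size=n_cells, random_state=rng)
    betas = model.beta_mean + model.beta_std * rng.standard_normal(n_cells)
    lrefs = model.L_ref_um * np.exp(model.L_ref_cv * rng.standard_normal(n_cells))
    return [CellSpec(cell_id=f"cell{str(i).zfill(4)}",
                     params=WalkParams(k=float(ks[i]), beta=float(betas[i]), dim=1),
                     L_ref=float(lrefs[i]))
            for i in range(n_cells)]


def render_continuous_track(sites: np.ndarray, L_ref: float, model: PopulationModel,
                            seed: int, cell_id: str = "cell",
                            min_duration_h: float | None = None,
                            include_hop_frames: bool = False,
                            noise_sigma_um: float | None = None) -> CellTrack:
    """Dress a lattice site sequence into a continuous 1D cell track.

    The centroid moves linearly between site centres ``X * L_ref``, with
    hop durations drawn from the bi-exponential model, and is resampled
    on a regular frame grid (``model.frame_dt_h``); cell edges are
    centroid +/- length/2 with transient elongation during reversal
    hops, and the whole cell carries a shared per-frame Gaussian jitter.
    ``include_hop_frames`` adds the exact hop times to the frame grid so
    that no excursion can fall between frames (used for round-trip
    checks).  A zero-hop path yields a stationary track covering
    ``min_duration_h``.
    """
    sites = np.asarray(sites, np.int64)
    if sites.ndim != 1 or sites.size < 1:
        raise ParameterError("sites must be a non-empty 1D integer sequence")
    n_hops = sites.size - 1
    if n_hops > 0 and np.any(np.abs(np.diff(sites)) != 1):
        raise ParameterError("consecutive sites must differ by exactly 1")
    sigma = model.noise_sigma_um if noise_sigma_um is None else noise_sigma_um
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    fast = rng.random(n_hops) < model.jump_mix_weight
    durations = np.where(fast,
                         rng.exponential(model.jump_mean_fast_h, n_hops),
                         rng.exponential(model.jump_mean_slow_h, n_hops))
    node_t = np.concatenate([[0.0], np.cumsum(durations)])
    node_x = sites.astype(float) * L_ref

    t_end = node_t[-1]
    if min_duration_h is not None:
        t_end = max(t_end, min_duration_h)
    if t_end <= 0:
        raise ParameterError("zero-hop paths require min_duration_h > 0")
    frames = model.frame_dt_h * np.arange(int(np.floor(t_end / model.frame_dt_h)) + 1)
    if include_hop_frames and n_hops > 0:
        frames = np.unique(np.concatenate([frames, node_t]))
        frames = frames[np.concatenate([[True], np.diff(frames) > 1e-9])]
    x = np.interp(frames, node_t, node_x)

    length = np.full(frames.size, L_ref)
    if n_hops >= 2 and model.reversal_elongation_um > 0:
        d = np.diff(sites)
        rev_hops = np.nonzero(d[1:] == -d[:-1])[0] + 1
        for i in rev_hops:
            t0, t1 = node_t[i], node_t[i + 1]
            if t1 <= t0:
                continue
            mid = 0.5 * (t0 + t1)
            tent = 1.0 - np.abs(frames - mid) / (0.5 * (t1 - t0))
            length += model.reversal_elongation_um * np.clip(tent, 0.0, None)

    jitter = sigma * rng.standard_normal(frames.size) if sigma > 0 else 0.0
    xc = x + jitter
    return CellTrack(cell_id=cell_id, t=frames, x=xc,
                     x_left=xc - length / 2.0, x_right=xc + length / 2.0)


def generate_dataset(preset: str, n_cells: int, duration_h: float | None = None,
                     seed: int = 0, n_hops: int | None = None,
                     model: PopulationModel | None = None,
                     include_hop_frames: bool = False) -> SyntheticDataset:
    """Generate a synthetic population of 1D cell tracks.

    Either ``duration_h`` (tracks cropped to a fixed duration) or
    ``n_hops`` (a fixed number of lattice hops per cell) must be given.
    The PSATW lattice path of each cell and its continuous dressing use
    separate seeded streams derived from the master seed, so the same
    path can be re-dressed independently.
    """
    if model is None:
        if preset not in PRESETS:
            raise ParameterError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        model = PRESETS[preset]
    if duration_h is None and n_hops is None:
        raise ParameterError("give duration_h or n_hops")
    ss = np.random.SeedSequence(seed)
    pop_seed, paths_seed, dress_seed = [
        int(s) for s in (ss.generate_state(3, dtype=np.uint32) & 0x7FFFFFFF)]
    cells = sample_population(model, n_cells, pop_seed)
    path_seeds = child_seeds(paths_seed, n_cells)
    dress_seeds = child_seeds(dress_seed, n_cells)

    if n_hops is not None:
        steps = int(n_hops)
    else:
        steps = int(np.ceil(duration_h / model.mean_jump_h * 1.6)) + 20
    if steps < 1:
        raise ParameterError("need at least one hop")

    tracks = []
    rows = []
    for i, cell in enumerate(cells):
        dirs = np.zeros(1, np.int64)
        sites = _kernels.psatw_paths_1d(cell.params.k, cell.params.beta, steps,
                                        path_seeds[i:i + 1], dirs)[0]
        track = render_continuous_track(
            sites, cell.L_ref, model, int(dress_seeds[i]), cell_id=cell.cell_id,
            min_duration_h=duration_h, include_hop_frames=include_hop_frames)
        if duration_h is not None:
            keep = track.t <= duration_h + 1e-9
            track = CellTrack(cell_id=track.cell_id, t=track.t[keep],
                              x=track.x[keep], x_left=track.x_left[keep],
                              x_right=track.x_right[keep])
        tracks.append(track)
        rows.append({"cell_id": cell.cell_id, "k": cell.params.k,
                     "beta": cell.params.beta, "L_ref": cell.L_ref,
                     "path_seed": int(path_seeds[i]),
                     "dress_seed": int(dress_seeds[i])})
    manifest = {
        "preset": preset,
        "n_cells": int(n_cells),
        "duration_h": duration_h,
        "n_hops": n_hops,
        "seed": int(seed),
        "include_hop_frames": bool(include_hop_frames),
        "model": asdict(model),
    }
    return SyntheticDataset(tracks=tracks, truth=pd.DataFrame(rows),
                            manifest=manifest)


def dataset_from_manifest(manifest: dict) -> SyntheticDataset:
    """Regenerate a dataset bit-identically from its manifest."""
    model = PopulationModel(**manifest["model"])
    return generate_dataset(
        preset=manifest["preset"], n_cells=manifest["n_cells"],
        duration_h=manifest["duration_h"], seed=manifest["seed"],
        n_hops=manifest["n_hops"], model=model,
        include_hop_frames=manifest.get("include_hop_frames", False))
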