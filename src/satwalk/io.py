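"""Track tables, configuration and manifests.

The track format is a plain CSV with a header; required columns are
``cell_id, t_h, x_um`` (1D) or ``cell_id, t_h, x_um, y_um`` (2D), with
optional cell-edge columns ``x_left_um, x_right_um``.  Units are fixed
by the column names (hours, micrometres).  Floats are written with 9
significant digits, which makes write/read round trips stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .footprint import CellTrack

__all__ = [
    "read_tracks",
    "write_tracks",
    "tracks_to_dataframe",
    "RunConfig",
    "load_config",
    "save_manifest",
]

_COLUMN_ORDER = ["cell_id", "t_h", "x_um", "y_um", "x_left_um", "x_right_um"]
_FLOAT_FORMAT = "%.9g"


def tracks_to_dataframe(tracks) -> pd.DataFrame:
    """Concatenate tracks into one tidy table in the canonical column order."""
    frames = []
    for tr in tracks:
        cols = {"cell_id": tr.cell_id, "t_h": tr.t, "x_um": tr.x}
        if tr.y is not None:
            cols["y_um"] = tr.y
        if tr.x_left is not None:
            cols["x_left_um"] = tr.x_left
            cols["x_right_um"] = tr.x_right
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(columns=["cell_id", "t_h", "x_um"])
    df = pd.concat(frames, ignore_index=True)
    return df[[c for c in _COLUMN_ORDER if c in df.columns]]


def write_tracks(tracks, path) -> None:
    """Write tracks as a TrackTable CSV (header-only file for no tracks)."""
    tracks_to_dataframe(tracks).to_csv(path, index=False,
                                       float_format=_FLOAT_FORMAT)


def read_tracks(path) -> list[CellTrack]:
    """Read and validate a TrackTable CSV, one CellTrack per cell_id.

    Rows of each cell are sorted by time; validation failures raise
    :class:`ValidationError` naming the offending cell and row.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"track file not found: {path}")
    df = pd.read_csv(path)
    missing = {"cell_id", "t_h", "x_um"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    has_edges = "x_left_um" in df.columns
    if has_edges and "x_right_um" not in df.columns:
        raise ValidationError(f"{path}: x_left_um present without x_right_um")
    has_y = "y_um" in df.columns
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_h", kind="stable")
        try:
            tracks.append(CellTrack(
                cell_id=str(cell_id),
                t=grp["t_h"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                x_left=grp["x_left_um"].to_numpy(float) if has_edges else None,
                x_right=grp["x_right_um"].to_numpy(float) if has_edges else None,
                y=grp["y_um"].to_numpy(float) if has_y else None,
            ))
        except ValidationError as err:
            raise ValidationError(f"{path}: {err}") from err
    return tracks


_KNOWN_KEYS = {
    "model": {"k", "beta", "dim", "n_steps", "n_walkers"},
    "discretisation": {"L_ref", "hysteresis"},
    "statistics": {"ages_h", "window_h", "max_lag_h", "min_excursion_um",
                   "smooth_window", "s_window"},
    "synthesis": {"preset", "n_cells", "duration_h", "n_hops"} | {
        "k_mean", "k_std", "beta_mean", "beta_std", "L_ref_um", "L_ref_cv",
        "jump_mix_weight", "jump_mean_fast_h", "jump_mean_slow_h",
        "reversal_elongation_um", "frame_dt_h", "noise_sigma_um"},
}


@dataclass
class RunConfig:
    """Nested run configuration with explicit seeding.

    Unknown sections or keys are rejected on load; :meth:`resolved`
    returns the fully explicit dictionary that runs emit alongside
    their outputs so any result is reproducible from it alone.
    """

    seed: int = 0
    model: dict = dc_field(default_factory=dict)
    discretisation: dict = dc_field(default_factory=dict)
    statistics: dict = dc_field(default_factory=dict)
    synthesis: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, keys in _KNOWN_KEYS.items():
            unknown = set(getattr(self, section)) - keys
            if unknown:
                raise ValidationError(
                    f"unknown keys in [{section}]: {sorted(unknown)}")

    def resolved(self) -> dict:
        from . import __version__

        return {
            "seed": int(self.seed),
            "model": dict(self.model),
            "discretisation": dict(self.discretisation),
            "statistics": dict(self.statistics),
            "synthesis": dict(self.synthesis),
            "package_version": __version__,
        }


def load_config(path) -> RunConfig:
    """Load a YAML RunConfig, rejecting unknown sections and keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - ({"seed"} | set(_KNOWN_KEYS))
    if unknown:
        raise ValidationError(f"{path}: unknown sections {sorted(unknown)}")
    return RunConfig(seed=int(raw.get("seed", 0)),
                     **{k: raw.get(k, {}) for k in _KNOWN_KEYS})


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_manifest(manifest: dict, path) -> None:
    """Write a JSON manifest (numpy scalars/arrays converted)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
        fh.write("\n")
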