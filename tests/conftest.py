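"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import satwalk as sw

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def enumerate_psatw_paths(k: float, beta: float, n_steps: int) -> dict:
    """Exact PSATW path distribution by exhaustive enumeration.

    Independent reference implementation: explicit visited-set state,
    literal evaluation of the reversal formulas, recursion over every
    reverse/continue decision and both initial directions.  Returns a
    map from the site-sequence tuple to its exact probability.
    """
    p_ri = math.exp(-k) / (math.exp(-k) + math.exp(k))
    p_re = math.exp(-k - beta) / (math.exp(-k - beta) + math.exp(k))
    out: dict = {}

    def rec(pos, d, visited, path, prob, left):
        if left == 0:
            out[path] = out.get(path, 0.0) + prob
            return
        p_rev = p_re if (pos + d) not in visited else p_ri
        for nd, pr in ((-d, p_rev), (d, 1.0 - p_rev)):
            if pr == 0.0:
                continue
            npos = pos + nd
            rec(npos, nd, visited | {npos}, path + (npos,), prob * pr, left - 1)

    for d0 in (-1, 1):
        rec(0, d0, frozenset({0}), (0,), 0.5, n_steps)
    return out


def make_track(t, x, length=None, cell_id="c0"):
    """Build a 1D CellTrack with symmetric edges of the given length."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if length is None:
        return sw.CellTrack(cell_id=cell_id, t=t, x=x)
    half = np.broadcast_to(np.asarray(length, float) / 2.0, x.shape)
    return sw.CellTrack(cell_id=cell_id, t=t, x=x, x_left=x - half,
                        x_right=x + half)


def triangle_track(amplitude=40.0, period=8.0, n_periods=4, dt=0.1,
                   cell_id="tri"):
    """Triangle-wave centroid (peak-to-trough ``amplitude``), edges 20 um."""
    t = np.arange(0.0, n_periods * period + dt / 2, dt)
    phase = (t / period) % 1.0
    x = amplitude * (np.abs(2.0 * phase - 1.0) - 0.5)
    return make_track(t, x, length=20.0, cell_id=cell_id)


@pytest.fixture(scope="session")
def control_dataset():
    """A small synthetic control population (oscillatory, beta < 0)."""
    return sw.generate_dataset("control", 12, duration_h=48.0, seed=3)


@pytest.fixture(scope="session")
def control_edge_samples(control_dataset):
    samples = []
    for tr in control_dataset.tracks:
        fld = sw.compute_footprint_field(tr, dx=2.0)
        samples.append(sw.sample_edge_footprints(fld, tr))
    return samples
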