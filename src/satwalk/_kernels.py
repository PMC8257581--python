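"""Numba Monte-Carlo kernels for the lattice walks.

The 1D kernels use the fact that the visited set of a nearest-neighbour
walk on Z is always a contiguous interval, so the full memory state is
(position, lowest visited site, highest visited site).  With the
saturating memory f(0)=0, f(n>0)=1 this is exactly equivalent to keeping
per-site visit counts.  The 2D kernel keeps a boolean visited grid that
is grown geometrically when the walker approaches its boundary.

Each walker consumes its own seed so ensembles are reproducible and
order-independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def psatw_paths_1d(k, beta, n_steps, seeds, init_dirs):
    """Simulate 1D PSATW paths; returns int64 array (n_walkers, n_steps+1)."""
    n_w = seeds.shape[0]
    out = np.empty((n_w, n_steps + 1), np.int64)
    p_ri = 1.0 / (1.0 + np.exp(2.0 * k))
    p_re = 1.0 / (1.0 + np.exp(2.0 * k + beta))
    for w in range(n_w):
        np.random.seed(seeds[w])
        pos = 0
        lo = 0
        hi = 0
        d = init_dirs[w]
        if d == 0:
            d = 1 if np.random.random() < 0.5 else -1
        out[w, 0] = 0
        for s in range(1, n_steps + 1):
            ahead = pos + d
            p = p_re if (ahead > hi or ahead < lo) else p_ri
            if np.random.random() < p:
                d = -d
            pos += d
            if pos > hi:
                hi = pos
            elif pos < lo:
                lo = pos
            out[w, s] = pos
    return out


@njit(cache=True)
def psatw_fpt_1d(k, beta, r, t_max, seeds, init_dirs):
    """First-passage step to site +r for independent 1D PSATW walkers.

    Returns int64 array of hitting steps; walkers that never reach +r
    within t_max are censored at t_max + 1.
    """
    n_w = seeds.shape[0]
    hits = np.empty(n_w, np.int64)
    p_ri = 1.0 / (1.0 + np.exp(2.0 * k))
    p_re = 1.0 / (1.0 + np.exp(2.0 * k + beta))
    for w in range(n_w):
        np.random.seed(seeds[w])
        pos = 0
        lo = 0
        hi = 0
        d = init_dirs[w]
        if d == 0:
            d = 1 if np.random.random() < 0.5 else -1
        hit = t_max + 1
        for s in range(1, t_max + 1):
            ahead = pos + d
            p = p_re if (ahead > hi or ahead < lo) else p_ri
            if np.random.random() < p:
                d = -d
            pos += d
            if pos > hi:
                hi = pos
            elif pos < lo:
                lo = pos
            if pos == r:
                hit = s
                break
        hits[w] = hit
    return hits


@njit(cache=True)
def satw_paths_2d(beta, n_steps, seeds):
    """Simulate 2D SATW paths on the square lattice (4 neighbours).

    Jump weight to a neighbour is exp(-beta) if it was ever visited and
    1 otherwise.  Returns int32 array (n_walkers, n_steps+1, 2) — int32
    keeps long large ensembles within memory, and positions are bounded
    by the step count.
    """
    n_w = seeds.shape[0]
    out = np.empty((n_w, n_steps + 1, 2), np.int32)
    w_vis = np.exp(-beta)
    for w in range(n_w):
        np.random.seed(seeds[w])
        half = 128
        side = 2 * half + 1
        vis = np.zeros((side, side), np.uint8)
        x = 0
        y = 0
        vis[half, half] = 1
        out[w, 0, 0] = 0
        out[w, 0, 1] = 0
        for s in range(1, n_steps + 1):
            cx = x + half
            cy = y + half
            if cx <= 0 or cx >= side - 1 or cy <= 0 or cy >= side - 1:
                nhalf = 2 * half
                nside = 2 * nhalf + 1
                nvis = np.zeros((nside, nside), np.uint8)
                off = nhalf - half
                nvis[off:off + side, off:off + side] = vis
                vis = nvis
                half = nhalf
                side = nside
                cx = x + half
                cy = y + half
            w0 = w_vis if vis[cx + 1, cy] else 1.0
            w1 = w_vis if vis[cx - 1, cy] else 1.0
            w2 = w_vis if vis[cx, cy + 1] else 1.0
            w3 = w_vis if vis[cx, cy - 1] else 1.0
            u = np.random.random() * (w0 + w1 + w2 + w3)
            if u < w0:
                x += 1
            elif u < w0 + w1:
                x -= 1
            elif u < w0 + w1 + w2:
                y += 1
            else:
                y -= 1
            vis[x + half, y + half] = 1
            out[w, s, 0] = x
            out[w, s, 1] = y
    return out
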