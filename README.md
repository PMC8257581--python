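# satwalk

Stochastic models and trajectory analysis for **cell migration with
spatial memory**: migrating cells deposit long-lived physicochemical
footprints (ECM components such as fibronectin and laminin) along their
path and are attracted back to previously visited ground, which turns
their trajectories into *self-attracting random walks*. `satwalk` is
aimed at biophysicists analysing single-cell tracks on 1D micropatterns
or 2D substrates who want to simulate these walks, quantify the
footprint feedback kinematically, and infer the model parameters from
experimental tracks.

## The models

**1D persistent self-attracting walk (PSATW).** A nearest-neighbour
lattice walk that remembers every visited site. Inside the visited
domain it is a classical persistent random walk, reversing with

    p_ri = e^-k / (e^-k + e^k),

where k ≥ 0 sets the persistence length l_p = e^(2k) (and, at unit
speed, the persistence time t_p). At an **edge** of the visited domain
— when the site ahead has never been visited — the reversal probability
becomes

    p_re = e^(-k-β) / (e^(-k-β) + e^k),

so β < 0 biases the walker back inward. With k > 0 and β < 0 the walk
produces noisy sawtooth oscillations whose amplitude grows slowly, the
signature pattern of isolated cells on 1D lines.

**2D self-attracting walk (SATW).** On the square lattice, each jump to
a neighbour i is weighted by exp(−β·f(n_i)) with the saturating memory
f(0) = 0, f(n > 0) = 1 (n_i = visit count). No persistence term.

Consequences implemented and measured here:

* **Footprint kinematics** — the field φ(x, t) (cumulative time the cell
  body covered position x before t) sampled at both cell ends
  (φ_l, φ_r), correlated with the centre-of-mass acceleration: inward
  acceleration at the footprint frontier, none in the interior.
* **Inference** — tracks are discretised on a cell-specific mesh L_ref
  via X = ⌊x/L_ref + 0.5⌋; conditional reversal frequencies in the
  interior/edge classes invert exactly to one (k, β) per cell.
* **Ageing** — increments I(T, t) = ⟨[x(t+T) − x(T)]²⟩ depend on the
  age T whenever β < 0 (long-lived memory); they do not for β = 0.
* **First passage** — the survival probability of a target decays as
  S(t) ∝ t^−θ with θ = e^−β / 2 (the universal 1/2 at β = 0).
* **Synthetic cells** — a generator producing continuous 1D tracks
  (bi-exponential hop durations with mean 0.6 h, cell-to-cell (k, β)
  variability, transient spreading during reversals, frame noise) with
  recorded ground truth, plus `control` (oscillatory, β ≈ −2) and
  `conditioned` (persistent, β ≈ 0) presets mimicking pristine versus
  footprint-saturated substrates.

## Worked example

Generate a synthetic control population with known parameters, then
recover them by discretisation and reversal-frequency inversion:

```python
import numpy as np
import satwalk as sw

ds = sw.generate_dataset("control", n_cells=20, n_hops=150, seed=1)
table = sw.fit_population(ds.tracks)
merged = ds.truth.merge(table, on="cell_id")
print(merged[["cell_id", "k", "k_hat", "beta", "beta_hat"]].head(4).to_string(index=False))
print("median |k error|   :", round(float(np.nanmedian(abs(merged.k_hat - merged.k))), 3))
print("median |beta error|:", round(float(np.nanmedian(abs(merged.beta_hat - merged.beta))), 3))
```

```
 cell_id        k    k_hat      beta  beta_hat
cell0000 1.192533 1.395144 -2.682004 -2.320285
cell0001 0.676802 0.733169 -1.594704 -0.996333
cell0002 0.940195 0.988032 -1.461986 -1.388277
cell0003 0.785131 0.760735 -1.956494 -2.620081
median |k error|   : 0.137
median |beta error|: 0.305
```

At the experimental track length (~150 hops) the persistence parameter
k is recovered to ~0.1; β is noisier (~0.3) because only the few dozen
edge steps per track inform it. The persistence exponent of first
passage follows the exponential law in β:

```python
curve = sw.survival_probability(sw.WalkParams(k=0.5, beta=-1.0), r=10,
                                n_walkers=10_000, t_max=30_000, seed=2)
fit = sw.survival_exponent(curve, t_window=(3_000, 30_000))
print(f"theta_hat = {fit.exponent:.3f} +/- {fit.stderr:.3f}  "
      f"(theory e^-beta/2 = {sw.theta_theory(-1.0):.3f})")
```

```
theta_hat = 1.267 +/- 0.100  (theory e^-beta/2 = 1.359)
```

θ > 1/2 means memory favours local over large-scale exploration.

A CLI wraps the same functionality (`satwalk simulate | synth |
footprint | fit | stats | fpt`); every run writes a manifest with the
resolved parameters and seeds so results are reproducible from it
alone. Tracks travel as plain CSV (`cell_id, t_h, x_um[, y_um]
[, x_left_um, x_right_um]`, hours and micrometres).

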