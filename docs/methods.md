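# Methods

## Model definitions and conventions

The 1D persistent self-attracting walk (PSATW) and 2D self-attracting
walk (SATW) are nearest-neighbour lattice walks with the saturating
site memory f(0) = 0, f(n > 0) = 1: only *whether* a site was ever
visited matters, which models a deposited footprint signal that
saturates quickly. Reversal probabilities are
p_ri = 1/(1 + e^{2k}) in the interior and p_re = 1/(1 + e^{2k+β}) at
an edge of the visited domain; the persistence length/time is
l_p = t_p = e^{2k} (unit speed). The 2D walk is the classical SATW on
the 4-neighbour square lattice with jump weights exp(−β f(n_i)) and no
persistence term, appropriate when the persistence length is
comparable to the cell size.

Choices the model statement leaves open, fixed here:

* **Initialisation.** The walker starts at the origin (visited once)
  with a uniformly random direction; the first step therefore applies
  the edge rule symmetrically. Both-neighbours-unvisited occurs only at
  this first step.
* **Edge classification.** A step uses the edge rule iff the site ahead
  *in the current direction* is unvisited; only this reading produces
  an inward bias. Under these dynamics a walker standing on a boundary
  site always faces outward, so the "edge site, facing inward" state is
  unreachable.
* **Bookkeeping.** Visit counts increment on arrival, before the next
  step is classified. One step is one time unit; the mapping to
  hours/μm is owned entirely by the synthetic-track generator.
* **Seeding.** Every walker consumes its own seed derived from a master
  seed through `numpy.random.SeedSequence` (masked below 2³¹), so
  ensembles are bit-reproducible and order-independent. In 1D the
  visited set is always a contiguous interval, which the Monte-Carlo
  kernels exploit — the full memory state is (position, min, max); the
  test suite checks the kernels against an exhaustive enumeration of
  all step sequences with their exact probabilities.

## Footprint kinematics

φ(x, t) accumulates, per frame, the previous frame interval Δt over the
spatial bins covered by [x_left, x_right], with partial bins counted
fractionally; this makes the conservation identity
Σ_x φ(x, t)·Δx = Σ_m Δt_m·L_m exact to round-off. The default bin is
Δx = 2 μm, well below a 20 μm cell. Edge values (φ_l, φ_r) are read
nearest-bin from the field accumulated *strictly before* the current
frame, so a frame's own occupancy cannot enter its own acceleration
reading. The centroid acceleration is a three-point second difference
(exact on quadratics, endpoints undefined) of a centroid smoothed over
3 frames by default; heatmap bins over (φ_l, φ_r) are 2 h wide and
empty bins are reported as missing, not zero.

## Discretisation and (k, β) inference

The centroid is mapped to sites X = ⌊x/L_ref + 0.5⌋ with
L_ref = median instantaneous cell length by default (a cell-specific
typical length). Site-boundary crossings are linearly interpolated in
time; multi-site frame jumps split into unit hops. Crossings carry a
**hysteresis margin** of 0.25·L_ref (configurable, 0 recovers the bare
flooring rule): with ~1 μm frame noise on a ~20 μm mesh, bare flooring
generates spurious one-frame site bounces exactly at boundary
crossings, which masquerade as reversals and corrupt the inferred
parameters. Any margin below half a mesh preserves every true
centre-to-centre hop, so discretising a noiseless rendering of a known
lattice path returns that path exactly (a round-trip identity the
tests enforce).

Each hop after the first is classified interior/edge by whether the
site ahead (in the incoming direction) already appears earlier in the
discrete path — the history observable from plating onward — and
reversal frequencies per class invert algebraically:
k = ½·ln((1−p_ri)/p_ri), β = ln((1−p_re)/p_re) − 2k. Degenerate
frequencies (0 or 1) are regularised with a Laplace +½ pseudocount and
flagged; an empty class yields a flagged NaN estimate.

**Precision floor.** At the experimental track length (~150 hops) a
track contributes ~115 interior but only ~35 edge steps, so
sd(β̂) ≈ √(1/(n_e·p_re(1−p_re)) + 1/(n_i·p_ri(1−p_ri))) ≈ 0.45 and the
population-median |β̂ − β| sits near 0.30–0.33 even when the true
lattice path is classified directly; k̂ is ~3× more precise. Both
medians shrink roughly as expected with track length (≈0.03 for k and
≈0.16 for β at 1500 hops). Estimates at the 150-hop scale should be
interpreted population-wise, not per cell.

## Ensemble statistics

Increments I(T, t) average [x(t+t₀) − x(t₀)]² over walkers and over t₀
sliding in [T, T + window]; the SEM is across walkers after the
within-walker sliding average. For cell tracks the defaults follow the
standard protocol: windows of 12 h starting at T ∈ {0, 6, 12, 18, 24} h
with lags cut at window/3 = 4 h. The ageing diagnostic `ageing_z` is
the largest between-age discrepancy in combined-SEM units; < 3 is
consistent with no ageing.

First-passage survival S(t) is the fraction of walkers that have not
yet reached a single absorbing site at +r on the infinite line (the
one-sided target convention; walkers start at the origin with random
orientation). Exponents are least-squares log-log slopes; the survival
exponent's standard error is a walker bootstrap, since OLS errors on a
step curve are miscalibrated. The default fit range is where
S ∈ [10⁻³, 10⁻¹], but θ is an *asymptotic* exponent whose local value
converges slowly from below (exploratory runs to t = 10⁶ show the
local slope for β = −1, k = 0.5 rising 0.99 → 1.18 → 1.29 → ≈1.36
across successive decades), so exponent measurements here simulate
deep in time and fit the latest decade via `t_window`. The same
slow-crossover caveat applies more strongly to the 2D subdiffusion law
I(0, t) ~ t^{2/3}: with β = −2.5 the effective exponent measured at
lags up to 10⁵ steps saturates near 0.57–0.59 (cross-checked against
an independent visited-set implementation), consistent with the
asymptotic 2/3 only through slow, plausibly logarithmic, corrections;
the acceptance suite records this gap rather than papering over it.

Oscillations are decomposed at turning points (prominence-filtered
sign changes of the smoothed velocity, default minimum excursion 10 μm
≈ half a run length); amplitudes are |Δx| between consecutive turning
points, periods the time between successive same-sign reversals, and
A/T their ratio, ≈ v/2 for a runner bouncing at speed v. Effective
diffusion is the linear MSD slope divided by 2·dim. MSD is squared by
default with an unsquared option.

## Synthetic cell tracks

The generator dresses simulated PSATW lattice paths into continuous
tracks: per-cell (k, β) from a truncated-normal/normal population
(defaults k = 1.0 ± 0.3, β = −2.0 ± 0.5 for `control`; β = 0.0 ± 0.2
with the same k for `conditioned`, emulating a substrate already
saturated with footprints, where the fitted k of real cells is
unchanged but β is not), per-cell mesh L_ref log-normal around 20 μm,
hop durations bi-exponential (weights 0.7/0.3, means 0.3/1.3 h, mean
0.6 h), frames every 6 min, shared Gaussian frame jitter σ = 1 μm, and
a phenomenological triangular elongation of up to 30 μm during
reversal hops (cells transiently spread while repolarising). With
k = 1 the persistence length e² ≈ 7 sites ≈ 150 μm and the control
span growth (~17 sites per 200 hops) reproduce the observed sawtooth
amplitudes (tens to hundreds of μm over 48–96 h) and the ~3-fold
larger 16 h displacement on conditioned substrates.

What the generator does *not* emulate: cell divisions and deaths,
static-spreading (non-motile) phenotypes, track gaps and segmentation
errors, heavy-tailed speed fluctuations, footprint decay, or any 2D
dressing beyond the raw SATW lattice output. Passing tests therefore
demonstrate internal consistency of the pipeline under the model's own
assumptions, not robustness to every artefact of real microscopy data.

## Problem sizes

Defaults used by the test and acceptance computations: 10⁴ walkers to
t = 10⁵ for the memoryless survival law, 10⁴ walkers to t = 3·10⁴ for
the θ(β) law, 500 walkers × 10⁴ steps (2D) and 2000 walkers × 1.1·10⁴
steps (1D aged) for increment exponents, and 100 cells × 150/1500 hops
for parameter recovery — sizes at which every quantity reported is
stable to its quoted uncertainty while a full run stays in the minutes
range on one core.
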