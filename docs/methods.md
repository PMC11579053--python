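# Methods

## The perceptual model

`respercept` implements a Bayesian-observer account of breathlessness in
hypercapnic rebreathing experiments.  A participant breathes room air for
60 s, rebreathes from a closed bag (initially 5 % CO₂ / 95 % O₂) for
150 s so inhaled CO₂ climbs steadily, then returns to room air for 150 s.
End-tidal CO₂ (the maximum exhaled concentration per breath, a proxy for
arterial CO₂) is averaged over 10 s bins, and the participant rates
breathlessness 0–100 every 10 s.  The puzzle the model addresses is that
the same CO₂ stimulus produces wildly different rating time courses across
individuals — including ratings that stay high long after CO₂ has
normalised.

The model assumes the brain estimates a single latent *respiratory state*
and perceives breathlessness as a linear readout of that estimate.  Per
10 s bin *t*:

1. **Internal CO₂ estimate** — a scalar Kalman filter with random-walk
   dynamics tracks the noisy end-tidal measurement *y‌ₜ*:

   Mₜ = Pₜ₋₁ + q,  Kₜ = Mₜ/(Mₜ + r),
   ĉₜ = ĉₜ₋₁ + Kₜ(yₜ − ĉₜ₋₁),  Pₜ = (1 − Kₜ)Mₜ,

   with q ≡ 1 so only the noise ratio ρ = r/q is identifiable from the
   filter's behaviour.  The steady-state gain is
   K∞ = M/(M + ρ) with M = (1 + √(1 + 4ρ))/2, strictly decreasing in ρ:
   small ρ means a trusted sensor (perception tracks CO₂), large ρ a
   distrusted one (perception leans on prediction).

2. **Activity effect** — a constant activity context A (the expected
   respiratory demand of the current situation) acts through a first-order
   relaxation aₜ = A(1 − (1 − Δ/τₐ)ᵗ) with Δ = 10 s; with τₐ = 40 s the
   effect passes 95 % of its plateau shortly after two minutes.

3. **Respiratory state** — the state carries over from the previous breath
   and is driven by the CO₂ estimate (as deviation from a reference
   c_ref) and the activity effect:

   xₜ = α xₜ₋₁ + w_c (ĉₜ − c_ref) + (1 − α) aₜ,  x before the first
   bin = 0.

   The (1 − α) scaling makes the saturated activity contribution equal A
   in state units regardless of α.

4. **Readout** — bₜ = clip(gain · xₜ + offset, 0, 100); the clip encodes
   the hard limits of the visual-analog scale.

Five parameters are free per individual — ρ, w_c, A, gain, offset — and
three are structural constants shared across individuals: α = 0.8 per
10 s bin (state memory ≈ 45 s), τₐ = 40 s, c_ref = 5.0 % CO₂ (the bag's
initial concentration, as a set-point proxy).  All three are configurable;
their defaults were chosen once, on physiologic plausibility, and the
reference-deviation form for the CO₂ drive avoids near-collinearity
between w_c and the readout offset.

The filter starts from a diffuse prior (mean = first observation,
variance = 10³ q, treated as the posterior of a virtual step −1), so the
first-bin estimate equals the first observation.

### Model variants

* **full** — as above (5 free parameters).
* **no_activity** — A pinned to 0 (4 free parameters); an exact parameter
  restriction of the full model.
* **no_memory** — α pinned to 0, removing the carry-over from the previous
  breath; the activity scale (1 − α) becomes 1, so the memoryless recursion
  equals the full recursion evaluated at α = 0 (5 free parameters).  Note
  this is *not* a parameter restriction of the full model, because α is a
  structural constant rather than a fitted parameter.
* **linear_regression** — b = β₀ + β₁ · y, the baseline claim that
  breathlessness is a scaled, shifted copy of the stimulus (2 free
  parameters, closed-form OLS).

## Fitting

Free parameters are estimated by bounded nonlinear least squares on the
rating residuals (`scipy.optimize.least_squares`, trust-region reflective),
with ρ searched in log₁₀ space for conditioning.  Default bounds:
log₁₀ ρ ∈ [−3, 4], w_c ∈ [0, 50], A ∈ [−100, 100], gain ∈ [0, 50],
offset ∈ [−100, 100] — wide enough for any behaviour expressible on the
rating scale.  Because the objective surface is multimodal, fitting
restarts from 20 Latin-hypercube start points (seeded, so fits are
bit-reproducible) and keeps the best restart.  Missing ratings are dropped
from the objective, never imputed.  In the four-way comparison the full
model additionally warm-starts from the fitted no-activity solution, which
guarantees rss(full) ≤ rss(no_activity) up to optimizer polish.

Convergence tolerances (`ftol = xtol = gtol = 1e-10`) are tight because
the noiseless self-consistency checks require residuals at machine-noise
level; each 36-bin fit costs well under a second.

### Identifiability — a structural limit

The recursion above is exactly linear-homogeneous in (w_c, A), and the
readout multiplies the state by `gain`, so predictions are invariant under

  gain → gain/s,  w_c → s·w_c,  A → s·A   (any s > 0).

Only ρ, offset and the products gain·w_c and gain·A are determined by the
data.  Noiseless synthetic fits reach RSS ≈ 10⁻²⁷ with the products
matching the generating values to machine precision while the individual
factors land anywhere on the flat manifold.  Consequently the package's
recovery reports always include the identifiable combinations alongside
the raw parameters, and any scientific interpretation of fitted w_c, A or
gain in isolation should be treated as convention-dependent.  An
identifiable model would require the CO₂ weight to enter nonlinearly
(e.g. as an innovation weight on the state itself); that is a different
model, not implemented here.

## Model comparison

Variants are compared by the least-squares Akaike Information Criterion,
AIC = n ln(RSS/n) + 2(k + 1), with the residual variance counted
uniformly (+1) across variants so the convention cannot affect rankings.
All variants are scored on the identical set of non-missing bins.  Ties
break toward fewer parameters.  A perfect fit (RSS = 0) yields −∞ with a
warning.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes, not
gas-exchange physiology.  Per-bin end-tidal CO₂ follows the protocol:
baseline plateau (default 5.2 %), linear rebreathing ramp
(0.9 %/min, reaching ≈ 7.45 % after 150 s), exponential recovery
(τ = 30 s, so ≈ 0.7 % of the excursion remains after 150 s), plus
additive Gaussian noise (SD 0.08 %) clipped at 0.  Ratings are the forward
model's own prediction under known parameters plus Gaussian noise
(default SD 2) clipped to [0, 100]; the generator and the fitted model
share one forward implementation, so recovery experiments probe
estimation, not model drift.

Named profiles encode the heterogeneity classes seen in real cohorts:

| profile            | variant     | ρ   | w_c | A  | gain | offset |
|--------------------|-------------|-----|-----|----|------|--------|
| sensory_dominated  | no_activity | 0.1 | 2   | 0  | 3    | 5      |
| persistent         | full        | 100 | 2   | 60 | 1    | 5      |
| low_responder      | full        | 1   | 0.5 | 5  | 1    | 2      |
| memoryless         | no_memory   | 1   | 3   | 20 | 2    | 5      |

`persistent` reproduces the decoupling phenomenon: an unreliable CO₂
sensor (K∞ ≈ 0.095) plus a strong activity context keeps ratings above
95 % of their peak through the final minute even though generated CO₂ is
back within ~0.26 % of baseline.  `sensory_dominated` peaks within one
bin of the CO₂ peak.

A raw-capnogram generator produces 50 Hz trapezoid waves whose per-cycle
plateaus are the requested end-tidal values, for exercising the breath
segmentation path.  Its inspiratory trough is 0 % in room-air phases and
rises during rebreathing only to 40 % of the plateau — a deliberately wide
inspired/end-tidal gap; real rebreathing narrows that gap further than the
default trough-crossing detector tolerates.

## Numerical and design choices

* **Breath segmentation** delimits a breath where the signal falls below
  `trough_frac` (default 0.5) of the running cycle peak, with two noise
  guards: a cycle must reach `min_amplitude` (default 1 % CO₂) before it
  can close, and after a crossing the next cycle only arms once the signal
  rises `hysteresis` (default 0.3 %) above the running trough.  No device
  formats, artifact rejection or drift correction are handled.
* **Binning** uses half-open [start, end) bins; a bin's value is the mean
  end-tidal CO₂ of breaths ending in it; an empty bin inherits the
  previous bin's value (the first bin must be occupied).  Carry-forward
  avoids interpolation assumptions while preserving grid length.
* **CSV round-trips** are bit-exact: floats are written with 17
  significant digits and parsed with the round-trip parser.
* **Riccati convergence** is geometric at rate (1 − K∞)² per step, so a
  diffuse start needs O(1/K∞) steps at large ρ; tests scale the step count
  accordingly rather than assuming a fixed budget.
* **Grid-filter oracle** (tests): the Kalman means are validated against a
  brute-force discretized Bayesian filter (4801-point grid, ±12 % padding,
  dense Gaussian transition, posterior mean by quadrature) to
  < 10⁻³ % CO₂; the comparison passes a moderate initial variance so the
  discretized prior fits the grid.

## Problem sizes

Recovery and selection experiments in the test suite and the acceptance
script use 36-bin traces (the default protocol), 10 noiseless or 50 noisy
replicates per condition, and 20 optimizer restarts per fit — sizes at
which every experiment completes in minutes on one core while leaving
selection frequencies stable to a few percent.

## What passing tests do and do not show

The synthetic cohorts share the exact generative family with the fitted
model; tests therefore validate the estimation and comparison machinery,
not the model's adequacy for real participants.  Real data add inter-breath
variability, rating quantisation, drifts and artifacts that the generator
idealises away.  Known limitations: the three structural constants are
conventions, not estimates; the scale degeneracy above; CO₂ is the only
sensory channel (no flow or proprioceptive input); and no group-level or
hierarchical inference is provided — fitting is strictly per participant.
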