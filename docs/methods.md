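# Methods

This note documents the model, the estimation machinery, the synthetic
study conditions used for validation, and the design choices that were
genuinely open — with enough detail to re-derive every default.

## Model

The worm's sensory state is s = (T, dT): the temperature at its location on
a linear-gradient plate and that temperature's time derivative. The state
space is a regular mesh (`GridSpec`): by default 24 T-bins spanning
14–26 °C (the union of the 17/20/23 °C-centered assay gradients) × 15
dT-bins spanning ±0.02 °C/s. The dT range follows from locomotion physics:
crawl speeds up to ~0.3 mm/s on a 0.45 °C/cm (0.045 °C/mm) gradient give
|dT| ≲ 0.014 °C/s. `n_dT` is odd so dT = 0 is a bin center — the identified
strategies peak there. Bins are half-open with a closed top bin, so the
rectangle is covered exactly once and a value on a shared edge belongs to
the right-hand bin.

Passive dynamics are Gaussian and inertial: T′ ~ N(T + dT·Δt, σ_T²),
dT′ ~ N(dT, σ_dT²). The kernel is discretized by CDF differences over
destination-bin edges (exact bin mass, not density at centers) with each
row renormalized, which absorbs the Gaussian mass truncated beyond the grid
boundary. σ_T and σ_dT are written as standard deviations throughout.

The behavioral strategy is the optimal policy of the linearly-solvable MDP,
π* ∝ p·exp(v). Because π* is invariant under v → v + c, the gauge is fixed
as max(v) = 0 (desirability peaks at 1). All policy and likelihood algebra
is done in log space with log-sum-exp; exp(v) across hundreds of states
underflows otherwise. Value and reward interconvert through Bellman
self-consistency; `value_from_reward` is a power iteration on the
desirability, z ← exp(r) ∘ (P z), renormalized to max 1 each sweep, with a
residual-based stop (default max|Δv| < 1e-10) and a hard iteration cap that
raises `NumericalError` with the residual if reached.

## Estimation

The penalized log-likelihood is concave in v, so the maximizer is global.
The smoothness penalty sums |v(s) − v(s′)|² over s and its 4-neighborhood
χ(s); this counts every unordered neighbor pair twice, a factor deliberately
kept (it is absorbed into λ) so the written objective matches its
definition literally. In matrix form the penalty is 2 vᵀLv for the
neighbor-graph Laplacian L, giving the analytic gradient 4λLv; the
likelihood gradient per state is in-counts minus visit-weighted policy
expectations. Optimization is L-BFGS-B from v = 0 (deterministic — the
start is immaterial by convexity, fixed for reproducibility) with a lower
bound on v (default −30) so states the data never touch cannot run away;
such states are additionally reported in the fit metadata, since their
values are shaped by the penalty alone. Observed transitions whose passive
probability is below 1e-12 are excluded and counted rather than allowed to
contribute −∞ (finite-grid Gaussian tails underflow).

Hyperparameters (λ, σ_T, σ_dT) are selected by k-fold cross-validation
(nine folds by default) over an exhaustive product grid, maximizing the
mean held-out transition log-likelihood. Folds are *contiguous blocks* of
the time-ordered transition sequence, not shuffled singletons, to respect
temporal dependence. Ties are broken deterministically toward the first
combination in ascending (λ, σ_T, σ_dT) order. CV fits use a slightly
looser optimizer tolerance (1e-7 versus 1e-9 for final fits): model
selection compares differences of order 10–100 nats and does not need
final-fit precision.

### 1-D versus 2-D state models

To test whether the derivative carries strategy information, a
temperature-only model is fitted on the same data: a 1-D grid over T
(single dT bin) with passive dynamics N(T′|T, σ_T). The two models'
likelihoods live on different event spaces, so the 1-D value is *lifted* to
the 2-D grid as v(T, dT) := v1(T) and both models are scored on identical
held-out 2-D transitions under the shared 2-D kernel. Per-fold held-out
log-likelihoods are compared with a two-sided Mann–Whitney U test. The test
is unpaired, so it only separates the models when the model gap exceeds
between-fold variability — which sets the sample sizes below.

## Preprocessing

Centroid tracks are mapped to temperature through the affine gradient map
(positions in mm, slope in °C/cm), split into segments at tracking gaps
longer than 2Δt, linearly interpolated onto a uniform Δt time base
(default Δt = 1 s, down from the ~13.5 Hz recording rate: consecutive-frame
temperature changes are far below any sensible bin width, so 1 s makes
transitions informative), then Savitzky–Golay smoothed and differentiated
(window 7 samples, order 2; endpoints use the filter's one-sided
polynomial fits). Segments shorter than the smoothing window are dropped
and counted. Transition pairs are formed only within segments; out-of-range
samples are clipped to boundary bins and tallied (or rejected, on request).

## Synthetic study conditions

The generator's defaults define the validation conditions; they were fixed
once, before the protocols were scored, except where noted.

**Ground-truth strategies** are log-mixtures of ridges in (T, dT):
a diagonal Gaussian ridge through (T*, 0) along dT = −slope·(T − T*)
(directed migration; slope in (°C/s)/°C, default 1/300 so the ridge spans
T* ± 6 °C across the ±0.02 °C/s range; width 0.005 °C/s, amplitude 1), a
horizontal ridge at dT = 0 (isothermal migration; width 0.003 °C/s,
amplitude 0.5), and a baseline (0.05) that keeps the log finite. Variants:
`pd_diagonal` (both ridges — proportional-derivative-like control toward
T* = 20 °C), `bang_bang` (saturating preference for extreme dT, switching
sign at T*), `p_only` (temperature-only Gaussian bump, width 2 °C), and
`starved_p` (the bump inverted: desirability depressed near T*).

**Passive-noise scales.** σ_T = 0.3 °C and σ_dT = 0.0015 °C/s per 1-s step
on the default grids. These are *chain-mobility* scales, commensurate with
the bin widths (0.5–0.6 °C, 0.0027 °C/s) so the discrete chain can actually
move between bins; they are deliberately not the (much smaller) physical
per-second fluctuations of a crawling worm, which would freeze a chain
living on 0.5 °C bins. What the simulations emulate is the *decision
structure* (a policy tilting Gaussian passive dynamics), not worm-scale
kinematics; conclusions about recovery and calibration transfer at the
level of the estimator's contract, not of physical units.

**Protocols** (all in `thermirl.validate`, all seeded through
`SeedSequence` spawning):

- *Parameter recovery*: `pd_diagonal` on a 20×15 grid over 14–26 °C,
  100 worms × 1001 steps (1e5 transitions) started from 12 temperatures
  spread across the gradient; CV over λ ∈ {0, 0.01, 0.1, 1} ×
  σ_T ∈ {0.2, 0.3, 0.45} × σ_dT ∈ {0.001, 0.0015, 0.00225}; pass at
  Pearson r ≥ 0.95 against the stored truth and desirability peak in the
  bin containing (T*, 0) (tested with a half-bin tolerance because T* = 20
  sits exactly on a bin edge of this mesh).
- *Regularization benefit*: five replicates of 4 worms × 501 steps
  (2e3 transitions — scarce for 300 states); λ searched over
  {0} ∪ 10^{−3..2}, σ fixed at generating values; pass when the selected
  λ > 0 strictly beats λ = 0 in mean held-out log-likelihood in ≥ 4 of 5.
- *2-D vs 1-D*: 400 worms × 501 steps (~2e5 transitions), every worm
  started at T* as on the real plate (homogeneous starts keep the
  contiguous folds comparable); λ = 1 both models. Pass when 2-D wins ≥ 8
  of 9 folds with Mann–Whitney p < 0.05. Smaller samples give 9/9 fold
  wins but an insignificant unpaired test — the model gap must exceed
  whole-worm fold variance, which it does at this (assay-realistic) size.
- *Forward simulation*: 100 worms from {T*−5, T*, T*+5} °C, dT₀ = 0,
  3600 steps. Pass when the final median temperature (overall and per
  start) is within 1 °C of T*. "No mode under a flat value" is
  operationalized as the fraction of final temperatures within 1 °C of T*
  staying below twice the uniform-occupancy expectation — the *median* is
  uninformative under the null because the symmetric starts and
  range-filling diffusion also center it near T*.

### Surrogate-test protocol

The IAAFT surrogate test runs on its own small regime:
grid 12×7 over [17, 23] °C × ±0.015 °C/s with Δt = 10 s, σ_T = 0.15 °C,
σ_dT = 0.0025 °C/s, fit λ = 1. Three constraints force this design:
(i) the Savitzky–Golay derivative of a simulated series carries
≈ 0.3·σ_T/Δt of step noise, which must fit inside the dT range (hence the
long Δt); (ii) σ_dT must be of order half a dT bin or π* ∝ p·e^v cannot
express any strategy along dT at all (absolute continuity); (iii) dT·Δt
must stay below a T bin or worms saturate at the grid boundary.

The region statistics sum the fitted desirability over a diagonal (DM)
band of ±1 dT-bin around dT = −0.005·(T − 20) and the dT = 0 row (IM) —
after rescaling z to unit grid mean. The rescaling matters: with the
max-gauge alone, a diffuse surrogate fit outsums a concentrated observed
ridge, inverting the test. A flat desirability of any height still scores
exactly the region's state count. `normalize=False` restores the raw sum.

Calibration data (the type-I protocol) are sampled from the v = 0 chain
*at stationarity* (900-step burn-in): an un-burned random walk is
nonstationary while IAAFT surrogates are stationary by construction, and
that mismatch alone biases the DM statistic. Power data use a
strong-contrast diagonal truth (baseline 0.01, ridge width 0.004 °C/s)
with 20 worms started 2.7 °C off target over a 25-minute window, so the
approach transient — where directed migration expresses — dominates.
Empirical p-values use the add-one rule, p = (1 + #{null ≥ obs})/(1 + N),
never zero; surrogates are generated per worm (per segment) and the test
is invariant to worm ordering.

Two honest caveats. First, the DM test is mildly conservative: with 99
surrogates and 20 null datasets its rejection rate at α = 0.05 is ~0–0.05
depending on seed. Second, the IM statistic is *anti-conservative under
this chain null*: IAAFT destroys genuine dT-persistence (dwell near
dT = 0), which the IM row responds to, so IM significance against an IAAFT
null partly reflects temperature persistence rather than strategy. The
package therefore calibrates and interprets the DM component only; IM
p-values are reported but should be read with this in mind. More broadly,
an LMDP with a broad PD ridge is close to a linear Gaussian process, whose
structure IAAFT preserves — surrogate tests of such data detect only the
*nonlinear* part of a strategy.

## Numerical choices

- Log-sum-exp everywhere a sum of exp(v) appears; policy rows renormalized
  in log space.
- Kernel rows validated to sum to 1 within 1e-9; zero-support rows raise.
- L-BFGS-B tolerances: ftol 1e-9 (final) / 1e-7 (CV), projected-gradient
  1e-7; non-convergence with a projected gradient above 1e-3 raises.
- TSV grid files print 17 significant digits so round trips are bit-exact.
- IAAFT iterates until the rank permutation stabilizes (or 100 sweeps);
  constant series are returned unchanged with a warning.
- Degenerate 1-D grids (n_dT = 1 with a collapsed dT range) give the single
  dT bin a nominal ±0.5 °C/s extent so edge/center arithmetic stays defined;
  clip-mode discretization then collects every dT sample into it.

## Known limitations

- The tabular state space cannot represent sub-bin temperature motion; the
  simulated chain's mobility therefore depends on noise scales being
  commensurate with bin widths (see above), and physical per-second worm
  kinematics cannot be simulated on coarse default bins.
- The framework captures run-scale (shallow-turn) steering only; sharp-turn
  (omega/reversal) statistics are outside the model, and no relationship
  between the desirability function and sharp-turn rates is claimed.
- Passing synthetic validation shows the estimator recovers strategies of
  the model class under the stated conditions; real trajectories add
  tracker noise, plate-boundary artifacts, inter-worm variability, and
  non-Gaussian locomotion that the generator does not emulate.
- Never-visited grid states take penalty-determined values; they are
  flagged, and downstream statistics over such regions reflect the
  smoothness prior, not data.
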