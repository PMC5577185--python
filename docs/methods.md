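# Methods

## The rupture model

A tip-tethered ligand bound to a mineral surface is pulled with a force
that grows linearly in time, `f(t) = r t`.  The bond is modelled as a
single barrier along the pulling coordinate: bound state, transition state
at distance `x_t`, intrinsic unbinding rate `k_u` at zero force.  Under
load the unbinding rate is accelerated in the Bell form
`k_u(f) = k_u exp(f x_t / k_B T)`; the thermal force scale
`f_β = k_B T / x_t` is the slope of the Bell–Evans (kinetic-regime) force
versus log loading rate.  With rebinding, the system stays near
equilibrium until the force passes the equilibrium force `f_eq` where on-
and off-rates balance; beyond `f_eq` escape is effectively irreversible.
The resulting single-bond survival under a ramp is

    S(f) = exp(-(1/R) (e^{(f - f_eq)/f_β} - 1)),   f ≥ f_eq,

with reduced loading rate `R = r / (k_u(f_eq) f_β)`, and the mean rupture
force has the exact closed form

    ⟨f⟩ = f_eq + f_β e^{1/R} E₁(1/R)

(`E₁` the first exponential integral).  For `N` identical load-sharing
bonds the same expression is used with `a = N/R(f_eq/N)` and prefactor
`N f_β`.  Two limits orient intuition and are enforced by tests: for
`R → 0` (slow pulling) `⟨f⟩ → f_eq` with excess bounded by `f_β R`
(near-equilibrium plateau); for `R ≫ 1` the slope `d⟨f⟩/d ln r → f_β`
(Bell–Evans).  The sandwich `f_β R/(R+1) < ⟨f⟩ − f_eq < f_β R · e^a E₁(a)
· a`-equivalent bound `1/(z+1) < e^z E₁(z) < 1/z` brackets the kinetic
term everywhere.

The binding free energy of the bound state follows from the fitted
landscape as

    ΔG_b = k_B T ln(f_eq x_t / (k_B T)) + f_eq x_t + k_B T.

The logarithm's argument is nondimensionalised by `k_B T`; this convention
makes the argument dimensionless and yields the exact identity
`ΔG_b = 2 k_B T` when `f_eq x_t = k_B T`.  The divisor is isolated in one
place (`model_core._log_divisor`) so the alternative convention can be
compared if desired.  `ΔG_b` maps to a Langmuir surface coverage
`θ = Kc/(1+Kc)` with `K = exp(+ΔG_b/k_B T)` at reference activity `c = 1`
(positive ΔG_b = favourable binding); at 90% coverage and unit activity
`ΔG_b = k_B T ln 9 ≈ 2.20 k_B T`.

## Numerical choices

* All internal computation is SI (N, m, s, J, K); `k_B = 1.380649e-23 J/K`
  exactly, default temperature 298.15 K (25 °C acquisition).  Reporting
  layers convert to pN, nm and k_B T.
* `e^z E₁(z)` is evaluated as a single scaled function: the direct product
  with `scipy.special.exp1` below `z = 700` (where `exp1` is still a
  normal float) and the truncated asymptotic series
  `(1/z) Σ (-1)^k k!/z^k` above, so the deep near-equilibrium regime
  (`z = N/R` large) never overflows.
* The fit optimises `[f_eq in pN, x_t in nm, log10 k_u]` — a
  well-conditioned parametrisation — with `scipy.optimize.least_squares`
  under bounds `f_eq ∈ [0, max mean force]`, `x_t ∈ [0.01, 10] nm`,
  `k_u ∈ [1e-6, 1e9] /s`.  Weights are `1/SE²` with an automatic fallback
  to unweighted when any SE is zero (noiseless or single-event points).
* The objective is multimodal in `(k_u, x_t)`, so the fit is multi-start:
  `f_eq₀ ∈ {0.5, 0.8} × min(mean force)`, `x_t₀` from the Bell–Evans slope
  of the top decade of loading rates, `k_u₀ ∈ {1e-2, 1, 1e2} /s`; the best
  start by objective wins.  Non-convergence from all starts returns a
  results object with `converged=False`, never a silent fallback.
* `N` is held fixed (default 1).  `n_bonds="scan"` fits `N ∈ {1..4}` and
  breaks ties (RSS within 1e-6 relative) toward the smallest `N`
  (parsimony).
* Parameter standard errors come from the linearised covariance scaled by
  reduced chi-square; ΔG_b confidence intervals use a stratified
  percentile bootstrap (resampling events within each loading-rate group,
  refitting from the full-data solution, default B = 200), which is more
  trustworthy than linearised errors with only ~5 rate groups.  Intervals
  are flagged unreliable when >20% of resamples fail.
* Detection limit: when the fitted `f_eq`'s 95% interval includes zero,
  ΔG_b is reported as an upper bound (`< 0.5 k_B T` by default) and the
  condition is excluded from rankings.

## Synthetic data

The generator emulates the standard acquisition design: at least five
retraction velocities log-spaced over 10–3000 nm/s, at least 50 curves per
velocity (≥250 events per condition), approach at 100 nm/s, 1 s dwell,
nominal cantilever spring constant 0.06 N/m.  Loading rates are nominal,
`r = k · v`; the detector also offers a measured mode (least-squares slope
of force versus time just before rupture) since real instruments report
either.

Three generative layers:

1. **Inverse-transform sampler** — exact draws from the model survival,
   `f = f_eq + f_β ln(1 − R ln U)`; every draw is ≥ `f_eq` and the sample
   mean converges to the closed form.  This is the workhorse for
   parameter-recovery experiments.
2. **Two-state Gillespie chain** — an independent oracle that never uses
   the closed form: bound/unbound states under the ramp with unbinding
   rate `k_u(f)` and rebinding rate
   `k_on(f) = s·k_u(f_eq)·exp(−s(f−f_eq) x_t/k_B T)` (`s` the rebinding
   scale).  The on-rate dwarfs the off-rate below `f_eq` and dies off just
   above it, with the crossover pinned at `f_eq` and width `f_β/s`; the
   exponential decay makes the total rebinding opportunity after each
   unbinding finite, playing the role of the retracting tip's finite
   capture range without an extra parameter.  As `s → ∞` the
   final-rupture survival converges to the model survival; a fixed-decay
   rebinding law (decay scale `f_β` independent of `s`) was rejected
   because its on/off crossover drifts as `f_eq + (f_β/2) ln s`, so its
   mean rupture force diverges logarithmically in the rebinding strength
   instead of converging.  Event times are drawn exactly by
   integrated-hazard inversion (no time discretisation).  `s = 0` gives
   the pure Bell–Evans first passage.
3. **Force-curve synthesis** — approach/retract traces with a repulsive
   contact ramp, an adhesion well deepening at the cantilever spring
   constant, an instantaneous rupture step, optional linear baseline
   drift, and per-sample Gaussian force noise (default SD 5 pN, a typical
   soft-cantilever noise floor; 1200 samples per segment).  Ground truth
   is embedded in curve metadata for detector round-trip tests.

What the generator does **not** emulate: cantilever hydrodynamics and
thermal position-noise spectra, polymer-linker (worm-like-chain)
stretching, tip-shape convolution, multiple tethered ligands with
heterogeneous chemistry, drifting spring constants.  Passing tests
therefore demonstrate correctness of the analysis chain under the model's
own assumptions — they show the estimator is unbiased and well-calibrated
on data generated by the stated physics, not that real AFM artifacts are
handled.

The per-condition presets (`condition_presets`) are synthetic stand-ins:
`x_t` is fixed at 0.30 nm and `f_eq` solved so the true ΔG_b equals the
reported headline values for each ligand–mineral pair (5.8 k_B T for
COO⁻/mica down to 0.4 k_B T for CH₃/goethite); weak bonds are given faster
`k_u` so the default velocity range still brackets their near-equilibrium
crossover.  The true per-pair landscape parameters were never published.

## Rupture detection

The retract baseline and its noise SD are estimated robustly (median and
scaled MAD) from the final 25% of the trace — immune to drift near
contact.  Candidate events are contiguous excursions of a lightly
boxcar-smoothed trace below `baseline − k·SD` (k = 5) that return to
baseline within the trace; candidates whose minimum lies inside the
contact exclusion zone are dropped.  Among multiple candidates the default
choice is the **last** (final tip–surface detachment, the convention for
tip-surface pulling); "deepest" is available.  The rupture force is
measured by locating the step (largest forward jump of the raw trace near
the smoothed minimum) and extrapolating a short linear fit of the pre-step
ramp to the step sample — both the raw minimum (extreme-value bias) and
the smoothed minimum (ramp-averaging bias) are biased estimators, while
the extrapolation is unbiased under white noise and exact on noiseless
traces.  Curves with no detected event are excluded from means rather than
counted as zero force.  QC drops low-SNR detections and forces outside
1 pN–100 nN; multiple-event curves are retained.

## Near-equilibrium estimator

Below a loading-rate ceiling (default 1e-8 N/s) the plateau makes the
pooled rupture force an approximate measure of relative binding strength
without a model fit.  `near_equilibrium_force` returns the event-weighted
mean and pooled SD (within- plus between-group variance) over all points
below the ceiling, and errors out — pointing at the full fit — when the
dataset has no coverage there.

## Problem sizes

Default test and acceptance problem sizes are chosen so the full suite
runs in minutes on one core while keeping Monte-Carlo standard errors well
below the tolerances being asserted: 1e5 draws for sampler-vs-closed-form
means, 2e4 for the Gillespie oracle (rebinding scale 1000), 500 curves for
detector round trips, 100 replicates × 200 bootstrap resamples for the
recovery/coverage experiment, 40 replicates in the acceptance script's
recovery block.

## Known limitations

* The mean-force fit uses binned means only; fitting full rupture-force
  histograms (maximum likelihood on the distribution) is out of scope.
* Heterogeneous bond mixtures, catch bonds and multi-well landscapes are
  not modelled.
* The weak-bond pipeline (forces within a few noise SD of threshold) shows
  the expected detection-truncation bias: sub-threshold ruptures are
  censored, biasing the low-rate mean upward.  The event-table route
  (fitting supplied rupture tables directly) avoids this; for curve data
  near the detection limit, report ΔG_b as a bound.
* Spring-constant calibration and deflection-to-force conversion are taken
  as given (manifest inputs), as is instrument-specific (vendor binary)
  file reading.
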