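# Methods

This note records the models, numerical choices and limitations behind
tyrspec's analyses, in enough detail to judge what a passing test suite does
and does not demonstrate.

## Synthetic data: what is emulated

All analyses are validated on synthetic data because no raw measurements are
deposited for the 33-mer gliadin system.  The generators emulate the
statistical structure of each measurement, parameterized by the published
values collected in `tyrspec.reference`:

* **TCSPC decays.** The noiseless curve is the discrete causal convolution
  of an area-normalized IRF with `Σ_i A_i exp(−t/τ_i)` evaluated at channel
  start times, scaled so the maximum channel equals the target peak count
  (default 10⁴).  The default time base is 2048 channels over 200 ns
  (0.0977 ns/channel), matching a 5 MHz excitation repetition period.  The
  IRF is Gaussian with FWHM 600 ps (the excitation pulse width), centered at
  5×FWHM from the window start so its rising edge is fully sampled; an exact
  delta IRF is available for analytic tests (convolution reduces to an
  index shift, so closed-form identities hold to machine precision in the
  far tail, where FFT round-off would dominate).  Noise is per-channel
  Poisson on the expected counts; no dark counts, afterpulsing, pile-up or
  dead-time, so real instrument backgrounds are *not* represented — see the
  χ² discussion below for where that matters.  The recorded IRF is returned
  noiseless.  Lifetime tables report fractional intensities f, so fixture
  amplitudes are derived as `A_i ∝ f_i/τ_i`.
* **Titrations.** Anisotropy follows the hyperbolic one-to-one model with
  optional Gaussian noise; surface tension is a continuous two-segment
  piecewise-linear curve in log10(C) (descending to the breakpoint, flat
  above).
* **Dihedral ensembles.** Per-state frame counts are largest-remainder
  rounded so they match the requested fractions exactly; angles are drawn
  around the canonical χ1 centers (60°/180°/300°) with a Gaussian spread
  truncated to ±60° of the center, so every frame classifies back into its
  generating state — occupancy recovery is exact *by construction*, which
  validates the classifier chain, not the MD physics.  The published
  dimer/decamer occupancies sum to 102–103% as printed; fixtures renormalize
  to 100% preserving the headline state (t for the dimer, g− for the
  decamer) and rescaling the other two proportionally.
* **SASA samples.** Gaussian mixtures truncated at zero (redrawn, not
  clipped, to avoid an artificial atom at 0).

Every generator is a pure function of its parameter set and one integer
seed (`numpy.random.default_rng`).

## NLLS reconvolution fitting

The n-exponential model (n ≤ 4) is fitted by variable projection: the
optimizer searches only over log-lifetimes (positivity for free), while
amplitudes and a constant baseline are solved at every step by non-negative
weighted linear least squares.  Multi-start uses all combinations of a
6-point log-spaced lifetime grid spanning channel-width/5 to half the
window; the 4 best starts after a projected-cost screen are refined with
`scipy.optimize.least_squares` at tight (1e-15) tolerances, which is what
makes noiseless self-generated data recover parameters to ~1e-14 relative.
Ties are broken by lowest reduced χ², then by the largest minimum lifetime
separation; two recovered lifetimes within 5% of each other set an
identifiability warning on the result.

**Weighting and fit window.** Residuals are weighted by the Poisson variance
taken from the *model*, `1/max(expected, 1)`, iterated to self-consistency
(2–3 passes), rather than from the observed counts.  With zero-background
synthetic data the observed-count (Neyman) weights are badly behaved: the
many tail channels with expectation below one count dilute the reduced χ²
to ≈0.6, while windows restricted to moderate counts inflate it to ≈1.2–1.3
(downward fluctuations get overweighted).  Model-based variances give the
statistic unit expectation per channel, so a correct model lands in the
conventional 0.8–1.2 acceptance band.  The fit window runs from the first
channel at 90% of the rising edge to the last channel whose 33-channel
moving-average count is at least one — the moving average keeps isolated
stray photons from dragging the window into the empty tail.  Reduced χ²
uses `dof = n_window − (2n + 1)` (lifetimes, amplitudes, baseline).  There
is no IRF time-shift ("color shift") nuisance parameter: synthetic decay
and IRF share one grid; fitting real data with a shifted IRF is a
documented extension point.

## Maximum-entropy lifetime distributions

The decay is modelled as `I(t) = D0 · IRF ⊛ Σ_j g_j exp(−t/τ_j)` on a
log-spaced lifetime grid (default 150 points over 0.01–20 ns, spanning the
tabulated lifetimes 0.02–7.76 ns with margin).  g maximizes `Q = S − λC`
with S the Shannon–Jaynes entropy against a flat prior and C the Poisson
χ² of the reconvolved model.  Numerics:

* The stationarity condition `g_j = F_j exp(−λ ∂C/∂g_j)` is iterated as a
  damped multiplicative update in log space, so g stays positive at every
  iteration.  The raw fixed point diverges at large λ, so each step is
  capped at 4 log-units and backtracked until Q does not decrease.
* The overall scale D0 is re-estimated analytically (weighted least-squares
  optimum) at each iteration, which is the stationary point of the explicit
  normalization Lagrange term and avoids carrying it as a parameter.
* The χ² weights are refreshed from the current model each iteration
  (IRLS), for the same reason as in the NLLS fit.
* λ follows the discrepancy principle: geometric bracketing from 1e-12
  upward (χ²(λ) is non-increasing along the warm-started path), then
  bisection in log λ until reduced χ² ∈ [0.98, 1.05].  If even the largest
  λ cannot reach 1.05 the fit *fails* with the achieved χ² — note that for
  an unlucky Poisson realization the unregularized minimum χ² itself can
  exceed 1.05, in which case this error is the correct answer, not a
  solver defect.

Two consequences of the discrepancy stopping rule are worth stating
plainly.  First, on noiseless data χ² ≈ 1 still allows count-sized
residuals, and the entropy term spreads as much mass as those residuals
permit: a single-lifetime decay yields a *band* around the true lifetime
(peak within one grid spacing; the dominant band carries the bulk of the
mass), not a one-point spike.  Second, g is an amplitude density — band
mass percentages (`100·Σ_band g / Σ g`) are amplitude shares, not intensity
shares, so a short-lifetime component with a small intensity fraction can
dominate the band weights.  For the same reasons the fuzzy entropy
`H = −(1/log N)·Σ w'_i log w'_i` (w' = g/Σg over all N grid points) depends
on the grid size and on how hard the data constrain g; H values are
comparable only at a fixed grid, and tyrspec asserts only its structural
properties (H(uniform)=1, H(delta)=0, concentration decreases H), never a
specific published H.

Band extraction reports maximal runs of grid points with
`g ≥ 0.01·max(g)`; each band carries its peak lifetime, bounds and mass
percentage.  A distribution putting ≥5% of its mass on a grid edge point
sets an edge-saturation warning (grid too narrow).

## Binding isotherm and CAC

The binding fit profiles (r_free, r_bound) linearly over a 25-point log
grid of K_D starts spanning [min(C)/10, max(C)·10], refines each with full
nonlinear least squares, and keeps the best — making the result independent
of any initial guess.  Standard errors come from the Gauss–Newton
covariance; weighted fitting (1/sd²) engages automatically when the
titration carries per-point uncertainties.  A flat titration is returned
flagged `kd_identifiable=False` rather than raising, since the model
degenerates smoothly.

The CAC fit enumerates every partition of the log-sorted points with at
least two points per side, fits the descending line and plateau by
(weighted) least squares, and takes the breakpoint as their intersection —
kept when it falls between the two segments, with an in-range fallback for
noisy data where the best split's intersection lands slightly outside its
gap.  Enumerating partitions (rather than testing fixed candidate midpoint
positions) is what lets noiseless two-segment data return the breakpoint
exactly; it is still an exhaustive global search at small n.  An optional
seeded residual bootstrap gives a 95% interval.  A flat or rising titration
(no surface activity) raises a no-CAC error.

## Rotamers and SASA

χ1 angles are wrapped into [0, 360°) and classified into thirds of the
circle; the boundaries (0°, 120°, 240°) are assigned to the upper state by
half-open intervals — a measure-zero convention made explicit because the
usual strict-inequality definitions leave them unassigned.  χ2 is read and
stored but not used for classification (the state-discriminating coordinate
is χ1).  SASA mode analysis evaluates a Gaussian KDE (kernel sd = bandwidth,
default 0.05 nm², about one histogram bin) on a fixed grid from 0 to
max + 3 bandwidths; modes are local maxima above 5% of the global maximum,
and each mode's "relative difference" is its height deficit versus the
highest mode on the normalized density.  All-identical samples short-circuit
to a single mode at that value.

## Pipeline

`run_concentration_series` simulates (or loads) a decay per concentration,
runs NLLS and optionally MEM, and writes a summary table (τ_i, f_i, χ² from
NLLS; band peaks, band weights, H from MEM), per-concentration CSVs, JSON
sidecars and a manifest (config hash, seed, version).  Per-concentration
seeds are derived as `seed + 1000·index`, so identical config + seed
reproduces byte-identical outputs.  A failure in one concentration is
logged and recorded without aborting the others.

## Problem sizes and limitations

Recovery tests use the defaults above (2048 channels, peak 10⁴ counts,
20-seed replicate sets, 10⁴-frame dihedral ensembles, 150-point MEM grids);
these sizes were chosen so the whole suite exercises every path in well
under a minute per module while keeping Poisson-limited statistics
realistic for a benchtop TCSPC experiment.  What passing tests show is that
the estimators recover the parameters of data generated by the stated
models; they do not validate instrument-specific effects absent from the
generators (background, IRF drift, pile-up), ligand-depletion corrections
to the binding model, non-flat MEM priors, or any MD-derived quantity
beyond the classification arithmetic itself.
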