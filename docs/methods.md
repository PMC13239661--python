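# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `trackdesign`, at the level of detail a user needs to
judge what the package's outputs do and do not mean.

## Movement processes

All processes are stationary, isotropic, planar Gaussians; the two axes are
independent copies shifted by a home-range center μ = (μx, μy).

| kind | parameters | position ACF per axis |
|------|------------|------------------------|
| IID  | σ | σ·1{t=0} |
| OU   | σ, τp | σ e^(−t/τp) |
| OUF  | σ, τp > τv | σ(τp e^(−t/τp) − τv e^(−t/τv))/(τp − τv) |

σ is the per-axis stationary positional variance (m²); τp is the
home-range crossing time; τv the directional-persistence time. OU is the
τv→0 limit of OUF; |τp−τv| < 10⁻⁶τp switches to the repeated-root limit
σe^(−t/τ)(1+t/τ) for numerical stability. The OUF velocity variance is
σ/(τpτv) per axis, so the mean speed (Rayleigh mean of an isotropic
Gaussian velocity) is √(πσ/(2τpτv)), and the 95% home-range area is
πq₀.₉₅σ with q₀.₉₅ the χ²(2) quantile.

**Isotropy.** The spatial covariance is a scalar σ per axis. Anisotropic
(2×2) covariances, non-stationary behavior (migration, dispersal), and
behavioral-state mixtures are out of scope; data suspected of
non-stationarity should be segmented before fitting (a documented
pre-processing responsibility, not a package feature).

**Exact simulation.** Each axis of an OUF is the 2-d Markov state
(position, velocity) with companion drift eigenvalues −1/τp, −1/τv;
transitions use the closed-form matrix exponential and process noise
Q = P∞ − ΦP∞Φᵀ from stationarity, so tracks are exact draws of the
continuous-time law at the sampled times — there is no discretisation
error, and uneven times (post-corruption) are handled per step. Equality
of the recursive and dense-covariance laws is tested by whitening
simulated tracks with the dense Cholesky factor.

**Population model.** Individuals vary by a multivariate log-normal law on
(log τp, log τv, log σ) with mean `mean_log` and covariance `cov_log`
(diagonal in practice); `cov_log = 0` is the prototype mode (every animal
identical). Draws violating the kind's invariants (e.g. τv ≥ τp) are
rejection-resampled. Units are SI internally; user-facing duration strings
use 1 month = 30.4375 d and 1 year = 365.25 d.

## Likelihood, REML, and model selection

The likelihood of a track under a candidate model is the exact Gaussian
density of the coordinates, computed per axis by the innovations (Kalman)
filter on the Markov state; per-fix location-error variance adds to the
measurement equation. The home-range center is profiled out exactly by
filtering the constant regressor alongside the data (the GLS estimate,
identical to joint ML over μ).

Point estimates maximise the REML criterion — profile likelihood plus
−½log(1ᵀC⁻¹1) per axis — because plain ML's O(1/N) downward bias in σ̂ and
τ̂p propagates directly into area underestimates and inflated effective
sample sizes. Optimization is Nelder–Mead over log parameters (tolerance
10⁻⁸ on the objective) from four variogram-informed starts; the OUF
likelihood is symmetric in its two timescales, so the search is
unconstrained and the labels τp = max, τv = min are applied afterwards.
Timescales are capped at 20× the track span: beyond the span the OU family
degenerates into a Brownian ridge (σ, τp → ∞ at fixed diffusion rate), and
a fit at the cap is reported with zero effective sample size rather than a
pretend-precise area. Reported `loglik` and the AICc table use the plain
likelihood at the REML estimates; AICc parameter counts are 3/4/5 for
IID/OU/OUF (center ×2 plus scale parameters) and near-ties (<10⁻⁶) break
toward the simpler model.

**Effective sample sizes.** From the observed information of the full
two-axis fit (finite-difference Hessian of the REML criterion on the log
scale): N_area = 1/Var(log σ̂), reported with χ² degrees of freedom
ν = 2N_area; N_speed is the analogue for the velocity variance
log σ − log τp − log τv (zero unless OUF is selected). This convention
gives N_area ≈ n−1 for independent data and N_area ≈ T/τp for finely
sampled range-resident data (the exact expected-information value for the
OU worked example — τp = 1 d, T = 10 d, Δt = τp/50 — is 11.0; the mean
plug-in value across replicates is ≈ 8.5–9 because the observed information
is evaluated at the estimated parameters). Parameter CIs are Wald on the
log scale.

## Estimators

**AKDE area.** Gaussian KDE over the observed locations with the
reference bandwidth h² = σ̂·N_area^(−1/3) per axis (the 2-d Gaussian
reference rule with the effective sample size in place of n); the area is
the 95% highest-density region on a 151×151 grid spanning the data ±4
standard deviations (halving the cell size moves the area <1%). Two
finite-sample effects bias the raw region — kernel smoothing inflates it,
fringe density fluctuations deflate it — and their net ratio R(N) depends
only on N and the sampling density. R is computed by seeded, cached
Monte-Carlo on the estimator's own reference process (a unit OU track
spanning N crossing times at the track's points-per-crossing ratio) and
divided out; this plays the role of the area-corrected AKDE variants in
the wider ecosystem. Residual bias measured at T = 64τp is below 1%.
Autocorrelation-aware higher-order corrections and weighted AKDE for
irregular sampling remain out of scope, and small-N estimates (N_area < 2)
are flagged unreliable. If IID wins selection the classical KDE with n is
used (logged). The model-based alternative `gaussian_area` returns
πq₀.₉₅σ̂ directly. Both carry χ²_ν CIs with ν = 2N_area.

**Conditional-simulation speed.** Requires a selected OUF (correlated
velocities); otherwise the estimate *fails* with "data too coarse to
support a model with correlated velocity", and design evaluation counts
the failure instead of imputing. The estimator averages |v| over the
smoothing distribution of the fitted state space: for each of `n_draws`
(default 200; 64 in the design loop) draws, an unconditional path is
simulated, smoothed against pseudo-observations, and corrected against the
smoothed data (simulate–smooth–correct), giving exact conditional draws of
the velocity at the track times. The CI applies χ²_{2N_speed} scaling on
the squared-speed scale and widens by the Monte-Carlo standard error of
the draws. The naive straight-line-displacement estimator `sld_speed`
(Σ|Δr|/T) is provided as the reference foil: under uncorrelated location
error its expectation grows without bound as Δt shrinks.

## Population inference

Individual estimates are treated as χ²_ν scale quantities. On the log
scale the noise has known mean ψ(ν/2) − log(ν/2) (the log-χ² bias,
subtracted) and known variance ψ′(ν/2); speeds, being square roots of
scale quantities, use half the bias and a quarter of the variance. The
normal–normal model y_i ~ N(μ, s_i² + v) is fitted by ML with v ≥ 0 (the
boundary v = 0 is a legitimate homogeneous-population answer), weights
1/(s_i² + v̂) realize the downweighting of uncertain individuals, the 95%
CI for μ is profile-likelihood (χ²₁ cutoff 3.841 — robust at small m where
Wald misbehaves), and the natural-scale population mean is the log-normal
back-transform exp(μ̂ + v̂/2). Estimates are canonically sorted internally
so permuting individuals is bitwise irrelevant. A single estimate is
returned as-is, flagged "no between-individual information".

The univariate log treatment of each scale parameter replaces the full
matrix-logarithm machinery of the multivariate setting — the main
simplification of this package, consistent with its isotropic scope.

`pop_mean_ig` offers the inverse-Gaussian population law instead: the
marginal likelihood integrates the χ² kernel over the IG density by
per-individual Gauss–Legendre quadrature on log A (the integration window
adapts to both the kernel width and the population width, else a
near-degenerate population falls between nodes), with Nelder–Mead ML and a
Wald CI on the log mean. It falls back to the normal–normal fit, with a
warning, if the optimiser fails. `pop_average_model` applies the same
normal–normal machinery to each fitted log parameter (per-parameter
ν = 2/Var(log estimate) from the observed information) to build the
population model that seeds new simulations.

## Design evaluation

`evaluate_design` runs the outer loop: per replicate, sample m individuals
from the population law, simulate on the schedule, corrupt, fit, estimate
the targets, pool with `pop_mean`, and score against truth. Corruption
applies, in causal order: exponential failure-time truncation (the hazard
is user-specified; fixed-time truncation is the storage cap), storage cap,
Bernoulli fix-success thinning, and additive Gaussian location error
(recorded on the track and therefore seen by the fit). Deployments left
with <2 fixes are counted as failures. Truth is the closed-form population
mean of the target under the log-normal parameter law — exact, no
Monte-Carlo: E[πqσ] = πq·exp(μ_σ + v_σ/2) for area and
√(π/2)·exp(aᵀμ/2 + aᵀΣa/8), a = (−1,−1,1) on (log τp, log τv, log σ), for
speed (cross-checked against 40 000-draw Monte-Carlo in the tests).

Relative error is 100·(estimate − truth)/truth (negative =
underestimation). A design passes a target when |mean RE| ≤ threshold
*and* both confidence bounds of the mean RE lie within ±threshold
(default 5%); verdicts are recomputable from the stored per-replicate
errors. Everything is seeded through per-replicate `SeedSequence`
substreams, so identical (population, design, seed) triples give
bitwise-identical reports.

**Sensitivity.** `resample_combinations` enumerates all C(n, m)
combinations when there are ≤250 of them and otherwise samples exactly 250
distinct combinations (rejection on sorted index tuples); it reports
per-combination population means plus their mean and envelope.
`loo_correctness` recomputes the population mean with each individual left
out once and reports the percentage of leave-one-out estimates within the
threshold.

## Problem sizes and defaults

The test suite exercises the pipeline at desk scale: canonical prototypes
use τp = 4 h (OU/OUF) with τv = 1 h and σ = 1 km²; selection and coverage
experiments use 200 replicates at T = 20–50τp; speed recovery uses 100
replicates at Δt = τv/8, T = 30τp; the design-direction experiments use an
OU population with m ∈ {4, 10, 25}, T ∈ {2, 8, 32}τp and 10–30 replicates
per design. The acceptance script's worked example uses 100 replicates of
the 10-day OU deployment. The design loop defaults to 64 conditional
draws per speed estimate (the Monte-Carlo error of the mean modulus is
already far below parameter uncertainty there); standalone estimation
defaults to 200.

## What the simulations do and do not show

The generator produces exactly the stationary, isotropic Gaussian world
the estimators assume, plus the four deployment hazards. Passing tests
therefore demonstrate internal correctness and calibration — not
robustness to anisotropy, range shifts, behavioral switching, tag-induced
behavior change, or autocorrelated location error, none of which are
simulated. Real pilot data should be screened for range residency before
the fitted parameters are trusted as simulation inputs.

## Known limitations

- Wald CIs on log parameters are mildly conservative for τp (measured
  coverage ≈98% at nominal 95% in the canonical OUF experiment).
- The AKDE calibration assumes a Gaussian (OU-like) reference shape; for
  strongly non-Gaussian utilization distributions the debias is only
  first-order.
- `pop_mean_ig` reports a Wald CI (not profile) and treats the χ² kernel
  on the squared scale for speeds as exact, which is an approximation.
- The Movebank projection is a spherical azimuthal-equidistant about the
  centroid: adequate below a few hundred km of extent, not a geodetic CRS.
- Speed failures at coarse Δt are counted, never imputed, so population
  speed means at Δt ≳ 3τv condition on the detectable subset — exactly the
  caveat the workflow is designed to surface.
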