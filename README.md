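# trackdesign

Sample-size and study-design evaluation for animal tracking projects, built
on continuous-time movement models.

## The problem

Planning a GPS tracking study means committing scarce collars to three
budgets at once: how long to track each animal (duration *T*), how often to
record a fix (interval *Δt*), and how many animals to tag (population
sample size *m*). Whether the resulting data can support reliable
population-level inferences of **home-range area** and **mean movement
speed** depends not on the raw number of locations but on how the design
relates to the species' movement timescales:

- *τ<sub>p</sub>* — the position autocorrelation timescale (home-range
  crossing time). Area information accrues roughly once per crossing, so
  the effective sample size for area is N<sub>area</sub> ≈ T/τ<sub>p</sub>,
  no matter how densely you sample.
- *τ<sub>v</sub>* — the velocity autocorrelation timescale (directional
  persistence). Speed is estimable only while Δt < τ<sub>v</sub>; beyond
  Δt ≈ 3τ<sub>v</sub> the data retain no detectable velocity signature.

`trackdesign` simulates the stationary Gaussian movement processes used in
movement ecology (IID, Ornstein–Uhlenbeck, and OUF — OU with foraging,
which adds correlated velocities), fits them to tracks with an exact
Kalman-filter likelihood (REML point estimates, AICc selection), estimates
home-range areas by autocorrelated kernel density estimation (AKDE) and
mean speeds by conditional simulation of the fitted state space, pools
individuals into population means through a log-χ² bias-corrected
normal–normal hierarchical model (an inverse-Gaussian population law is
available as an alternative), and finally scores whole candidate designs —
including deployment hazards such as fix failure, premature device death,
storage caps, and location error — against closed-form truth with relative
errors and a ±5% reliability threshold, plus resampling and leave-one-out
sensitivity analyses.

## The model in brief

Each axis of an OUF animal is a Gaussian Markov state (position, velocity)
with drift eigenvalues −1/τ<sub>p</sub>, −1/τ<sub>v</sub> and stationary
position autocovariance

    C(t) = σ (τ_p e^{−t/τ_p} − τ_v e^{−t/τ_v}) / (τ_p − τ_v),

so `simulate_track` draws exact finite-dimensional realizations and
`kalman_loglik` evaluates the exact Gaussian density in O(n). Closed forms
anchor every evaluation: the 95% home-range area is πq<sub>0.95</sub>σ and
the mean speed is √(πσ/(2τ<sub>p</sub>τ<sub>v</sub>)). Individual
estimates carry χ²<sub>ν</sub> sampling distributions with
ν = 2·(effective sample size), and the hierarchical population mean
debiases logs by E[log(χ²<sub>ν</sub>/ν)] = ψ(ν/2) − log(ν/2) before
fitting y<sub>i</sub> ~ N(μ, ψ′(ν<sub>i</sub>/2) + v) and back-transforming
exp(μ + v/2).

## A worked example

```bash
python examples/05_design_evaluation.py
```

prints (OU population, τ<sub>p</sub> = 4 h, σ = 1 km², m = 20 individuals,
Δt = τ<sub>p</sub>/8, 12 replicates per design):

```
truth: population mean area = 18.82 km^2
 T/tau_p  mean RE %    95% CI of mean RE  verdict
       2      -55.0       (-62.7, -47.3)     FAIL
       8       -4.3        (-14.1, +5.4)     FAIL
      32        0.6         (-2.2, +3.5)     pass
```

Reading it: with only two home-range crossings per animal the population
mean area is underestimated by half — and no number of extra animals
repairs that, because every individual's data carry the same deficit. At
eight crossings the mean error is inside ±5% but its confidence bounds are
not, so the design still fails the reliability threshold; at thirty-two
crossings both the error and its uncertainty sit inside the band. The
other examples (`examples/01…06`) walk through single-track fitting, AKDE
areas, conditional-simulation speeds (including why naive
straight-line-displacement speed diverges under GPS error), population
pooling, and the resampling/leave-one-out sensitivity tools.

A thin CLI mirrors the workflow stages for shell use:

```bash
trackdesign simulate --config study.yaml --seed 1 --out tracks.csv
trackdesign fit --tracks tracks.csv --out fits.json
trackdesign evaluate-design --config study.yaml --out reports.json
trackdesign report --reports reports.json --target area --out figure.png
```

Movebank-dialect CSV input (`timestamp,location-long,location-lat,
individual-local-identifier`, UTC timestamps) is projected to planar meters
about the dataset centroid; planar CSV (`individual,t,x,y[,error_sd]`)
bypasses projection.

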