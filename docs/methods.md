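# Methods

## The problem

A species inventory is a multiset of positive integer counts, one per
observed species at one site.  Ecologists routinely summarise such data
with diversity and "evenness" indices — Shannon's H, Simpson's D,
Pielou's J, Hill numbers, Hill ratios — and with richness estimators.
This package implements both families side by side so that the
reliability of the index approach can be tested against the
distribution-fitting approach: fit a two-parameter abundance model,
read total richness off its zero class, and treat the model's shape
parameter (not an evenness index) as the description of how counts vary.

## Models

### Poisson log normal (PLN)

Species i carries a latent rate Λᵢ = exp(Zᵢ), Zᵢ ~ Normal(μ, σ²), and
its count is Poisson(Λᵢ).  The marginal PMF

    P(x) = ∫ Pois(x; e^z) φ(z; μ, σ) dz

has no closed form and is evaluated by Gauss–Hermite quadrature
(default 200 nodes).  The integrand becomes extremely peaked when x is
large, so the quadrature is recentred at the mode of the log-integrand
(found by Newton iterations on its strictly concave logarithm) and
scaled by the local curvature; accumulation is log-sum-exp throughout.
This keeps the PMF accurate over the whole support — it matches an
independent adaptive-quadrature oracle to ~1e-13 relative error even at
x = 2000 and parameter combinations where the naive rule underflows.

σ = 0 is accepted by the PMF and sampler as the degenerate
Poisson(e^μ); fitting requires σ > 0.

### Compound exponential-geometric series (CEGS)

Species i draws Eᵢ ~ Exponential(1) (the negative log of a uniform) and
gets the Weibull-type latent abundance wᵢ = Eᵢ^γ / λ: γ ≥ 0 is a shape
parameter governing variation in counts, λ > 0 an inverse scale
governing their magnitude.  The count is geometric on {0, 1, 2, ...}
with per-species parameter p(E) = 1/(w + 1):

    P(x | E) = (1 − p)^x p,        P(x) = E_E[ P(x | E) ]

The mixture integral is evaluated by Gauss–Laguerre quadrature
(default 120 nodes).  Nodes and weights are generated by Golub–Welsch
(a symmetric tridiagonal eigenproblem), because the recurrence-based
generators in NumPy and SciPy overflow above roughly 200 nodes and the
rare-dominated variant of the model (below) needs denser rules at large
counts.  The zero class has closed forms at special points used as test
oracles: p₀ = λ/(1+λ) at γ = 0 (the model degenerates to a pure
geometric), p₀ = e·E₁(1) at γ = λ = 1, and
p₀ = Ci(1)sin(1) + (π/2 − Si(1))cos(1) at γ = 2, λ = 1.

#### The convention switch

Whether p(E) = 1/(w+1) is the geometric's *stopping* probability
(expected count w) or its *continuation* probability (stopping
probability w/(w+1), expected count 1/w) changes the model materially,
and both readings appear coherent with the defining formula.  The
package implements both behind a `convention` argument
(`"stopping"`/`"continuation"`) on every CEGS operation, with
`"stopping"` the library default for the PMF, zero class, fitting and
sampling.

For the fixed-community simulation experiment the two conventions were
arbitrated against the reference summary statistics at γ = 2, λ = 1,
pool 100, 10,000 trials:

| quantity          | reference | stopping | continuation |
|-------------------|-----------|----------|--------------|
| geometric mean S  | 59.4      | ~37.5    | ~62.0        |
| SD of ln S        | 0.082     | ~0.131   | ~0.079       |
| SD of H           | 0.220     | ~0.280   | ~0.78        |
| SD of ln(1/D)     | 0.387     | ~0.413   | ~0.64        |

The continuation convention reproduces the richness behaviour (within
~4%) and is therefore the convention used by the simulation experiment
and the acceptance script.  Neither convention reproduces the reference
index SDs; the corresponding checks are left failing rather than tuned,
and the honest computed values under the selected convention are the
ones reported.  (A geometric with mean 1/E reproduces the richness pair
to the printed precision but its index SDs are even further off; no
reading consistent with the defining formula reproduces all four.)

### Zero-truncated fitting and richness extrapolation

Zero-count species are invisible, so both fits maximise the
zero-truncated log-likelihood Σᵢ ln[P(xᵢ)/(1 − P(0))].  The fitted zero
class then extrapolates total pool richness as R̂ = S/(1 − p̂₀), reported
unrounded; R̂ ≥ S always since p̂₀ ∈ [0, 1).

* PLN: optimised in (μ, ln σ) by L-BFGS-B from three deterministic
  starts (log-count method of moments, and μ ± 1); requires ≥ 3 species
  and ≥ 2 distinct counts.  Ties in likelihood break toward smaller σ̂.
* CEGS: counts are first *compressed* — sorted, and the two largest
  replaced by the second-smallest distinct value (ties resolved by
  position in the sorted multiset; requires ≥ 5 species and ≥ 3
  distinct count classes).  Compression damps the outlier sensitivity
  that otherwise makes many (γ, λ) pairs near-equivalent in likelihood.
  The likelihood uses the compressed counts; S comes from the raw
  counts (compression never changes S).  Optimised in (ln γ, ln λ) by
  L-BFGS-B from four starts (γ ∈ {0.5, 2} × λ ∈ {moment-matched, 1}),
  bounds γ ∈ [1e-3, 50], λ ∈ [1e-6, 1e6]; ties break toward smaller γ̂.

Parameter recovery under the models' own samplers (pool 5000, 20
replicates) returns μ̂, σ̂ within 0.1 of (0, 2) on average for the PLN,
median γ̂, λ̂ within 20% of (2, 1) for CEGS, and median R̂ within 5% /
10% of the true pool — the acceptance suite re-runs exactly this check.

## Indices

Natural logarithms throughout.  Simpson's D is the plug-in Σpᵢ² (the
Hill-2 definition requires it; no small-sample correction).  Hill
numbers use (Σpᵢ^q)^(1/(1−q)) via log-sum-exp, with q = 0, 1, ±∞ as the
usual limits (S, e^H, 1/max pᵢ, 1/min pᵢ); negative orders are computed
by the same formula and are dominated by rare species.  Note that the
standard q → −∞ limit is 1/min pᵢ, which equals N only when the rarest
species is a singleton — the package implements the standard limit.
Fisher's α solves S = α ln(1 + N/α) by bracketed root finding (relative
tolerance 1e-10) and requires N > S; the log-series scale is
x = N/(N + α).  Undefined statistics (J at S < 2, α at S ≥ N) are NaN,
never 0.

## Simulation experiments

`run_abundance_experiment` holds a pool of 100 species and one
parameter pair fixed and repeats the sampling 10,000 times (defaults
chosen as the study conditions: PLN μ = 0 — "median abundance 1" — and
σ = 2; CEGS γ = 2, λ = 1).  Per trial it records observed S, e^H and
1/D on the nonzero counts; across trials it reports the geometric mean
of S and the sample SDs (n−1 denominator) of ln S, H and −ln D — the
logged species equivalents, computed without an exp/log round trip.
Trials observing < 2 species are excluded from index summaries and
counted; at the default parameters this never occurs.

`hill_ratio_artifact` is the minimal counter-example showing a logged
Hill ratio correlating with "richness" for pure noise: x, y ~
exp(N(0,1)), S = max, rD = min, eH = √(S·rD), ratio = ln(eH/rD) =
½ln(S/rD); Spearman ρ(S, ratio) > 0 by construction.

## Diagnostics

* Dominant removal deletes exactly one maximal-count species (first in
  stored order on ties).
* The bootstrap resamples the S counts with replacement, so S is fixed
  and E[N] preserved; on strongly uneven communities it systematically
  inflates e^H, 1/D and J (the resample often omits the dominant).
* Pair matching is nearest-neighbour on the reciprocal sum Σ1/nᵢ with
  reuse allowed and ties to the lower index; the reciprocal sum is a
  rare-species fingerprint that largely ignores dominants.
* Paired summaries report Spearman ρ (average ranks) and the fraction
  of manipulated values strictly above the originals, ties excluded
  from both numerator and denominator (NaN if all tied).
* The latitudinal summary reports the SD of logged metric values and a
  tricube-weighted local quadratic regression (span 0.75, evaluated on
  a 100-point grid).  The smooth is descriptive only.

## What the synthetic data do and do not show

All tests run on inventories generated by the package's own PLN and
CEGS samplers with known parameters.  That validates the estimators'
internal consistency (loop closure: fitting data generated at the
fitted model recovers it) and the qualitative index pathologies, under
exactly the stated study conditions.  Real inventories add features the
generators do not emulate — detection biases varying across taxa,
spatial aggregation, mixed or mis-specified abundance models — so
passing tests certify the machinery, not the claim that either model is
the right one for any particular community.

## Numerical choices and limitations

* Quadrature defaults (200 Hermite / 120 Laguerre nodes) give ≤ 1e-7
  relative PMF error over the tested parameter grids; the continuation
  CEGS convention concentrates near E = 0 at large counts and needs
  ~800 nodes there (`n_quad` is exposed everywhere).
* PMF normalisation is checked truncation-corrected: partial sums plus
  the analytic survival term E[(1−p)^(x+1)] for CEGS, and a far-tail
  cutoff chosen from the log normal quantiles for the PLN.
* Optimiser non-convergence is reported via the `converged` flag and a
  logged warning, never silently.
* All samplers take an explicit integer seed or NumPy `Generator` and
  never touch global RNG state.
* The latitudinal smoother is not an inferential tool; no standard
  errors are attached.
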