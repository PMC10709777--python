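# Methods

## The estimation problem

Preterm (<37 completed weeks) and early preterm (<34 weeks) birth counts,
tabulated by county, 5-year maternal age group (15-19 … 40-44; births
outside 15-44 are excluded for small numbers) and calendar year, are too
sparse in most counties for stable crude rates.  The package smooths them
by borrowing strength across neighboring counties, adjacent years and age
groups, then feeds the smoothed surface into standardization, disparity,
social-vulnerability and trend analyses.

## The space-time-age BYM model

Likelihood and linear predictor:

    Y_ikt ~ Poisson(n_ikt · λ_ikt / 100)
    log(λ_ikt / 100) = α_k + u_i + v_i + δ_ik + φ_it

A Poisson likelihood with a log-offset is the standard BYM formulation for
spatially referenced counts; the data-generating truth is binomial
(preterm births are a subset of live births), but at rates near 12 per 100
the Poisson approximation only mildly overstates the variance.  The
recovery tests quantify the consequence: credible intervals are slightly
conservative (empirical 95% coverage ≈ 0.97-0.98 against binomial truth,
inside the accepted 0.90-0.99 calibration band).

Latent structure and priors:

* `α_k` — age intercepts, flat prior.
* `u_i` — intrinsic CAR (ICAR): p(u|τ_u) ∝ τ_u^{(N−C)/2}
  exp(−τ_u/2 Σ_{i∼j}(u_i−u_j)²), C = number of graph components.
* `v_i` — iid N(0, 1/τ_v) (BYM convolution).
* `δ_ik` — ICAR in space within each age column, one shared precision
  across ages (exchangeable age columns).  This realizes cross-age
  correlation: ages share α-level information and spatially coherent
  deviations.
* `φ_it` — first-order random walk over years within each county,
  p(φ_i|τ_φ) ∝ exp(−τ_φ/2 Σ_t (φ_it−φ_i,t−1)²).  RW1 shrinks temporal
  curves toward flatness, the behavior wanted of smoothed county trends.
* Precisions τ ~ Gamma(shape 0.5, rate 0.0005), the conventional weakly
  informative disease-mapping choice; configurable.

The two outcomes (preterm, early preterm) are fit as separate models.

### Sampler

Metropolis-within-Gibbs: conjugate gamma draws for the four precisions
(ICAR blocks use rank N−C, the RW1 block rank N(T−1)); adaptive random-walk
Metropolis for every log-linear effect, with per-site step sizes adapted
during burn-in toward 0.44 acceptance (the scalar-update optimum) and
frozen afterwards.  Single-site updates are vectorized over proper-coloring
classes of the adjacency graph (a rook lattice is 2-colorable; general
graphs get a greedy coloring): sites within a class are conditionally
independent given the rest, so simultaneous accept/reject is a valid
parallel single-site sampler.  Each proposal changes the predictor by a
constant on a block of cells, so the likelihood delta reduces to
`d·ΣY − (e^d−1)·Σμ` over cached group sums — the whole sweep is a handful
of array operations.

Identifiability of the improper ICAR and RW1 directions is enforced by
recentering every sweep: u is centered per graph component with the
removed mean folded into v (predictor-preserving), δ columns are centered
with means folded into α_k, and φ rows (per county) are centered with
means folded into v_i.  On a disconnected graph the per-component residual
centering of δ has no exactly compensating free term; the projection is
then the standard approximate centering-on-the-fly used in disease-mapping
samplers.

Defaults: 5000 iterations, 2500 burn-in, thin 5 (500 saved draws),
deterministic given the seed.  Cells with n_ikt = 0 contribute nothing to
the likelihood; counties with zero births in *all* cells are dropped with
a warning before fitting (no information, undefined offset).  Posterior
summaries are medians and central 95% credible intervals of the saved
λ draws.

### Reliability rule

A county's estimates are mapped/reported as reliable only if, for every
study year, the 95% credible-interval width of its age-standardized rate
is smaller than the point estimate AND it recorded at least 100 births
(default, configurable) across age groups.

## Standardization and disparity

Direct standardization: weights w_k are the reference-year (default:
first study year) national shares of live births by age group; the
standardized county-year rate is Σ_k w_k λ_ikt, computed on posterior
draws so the standardized rate carries a credible interval.

Disparity across counties in a year: minimum, 10th/25th/50th/75th/90th
percentiles, maximum, the 90th−10th gap and ratio, and the max−min gap.
Percentiles use linear interpolation of order statistics (NumPy's default
continuous rule) so tabulated outputs are bit-reproducible on fixed input;
report tables round to one decimal, round-half-even.  At least 10 counties
are required — below that, percentile summaries are refused rather than
returned.

Gap/ratio intervals use a county-resampling percentile bootstrap (B = 1000
default, minimum 200, seeded).  Propagating posterior draws through the
percentile functionals would be a defensible alternative; the bootstrap
was chosen because it also applies to crude-rate inputs and isolates the
interval construction in one operation.

## SVI association

The SVI enters as an overall percentile and four theme percentiles on
(0, 1], with the time-varying release convention: 2010 release for
2007-2011, 2014 for 2012-2015, 2016 for 2016-2017, 2018 for 2018-2019
(nearest release, ties to the earlier one, for other spans).  Quartiles
are empirical quartiles of the overall percentile among included counties,
ties assigned downward; an all-tied column degenerates to quartile 1 with
a warning.

Rate ratios come from maximum-likelihood negative binomial (NB2)
regression of county outcome counts on quartile indicators (or continuous
SVI) with ln(births) as offset — one model per year across counties,
optionally per age stratum.  A per-county slope on a county-level
covariate is unidentifiable, so across-county fitting is the only reading
that yields quartile rate ratios.  Dispersion is estimated by ML
(statsmodels); Wald 95% intervals on e^β.

Variance explained: OLS of standardized rates on each theme (univariate),
on sequentially added themes, and on all four (fully adjusted), reporting
R² and coefficients; collinear columns are dropped with a flag.  Extreme
profiling groups counties at ≤10th / ≥90th percentile of standardized rate
and reports each group's median SVI percentiles (the synthetic SVI has no
raw theme values).

## Trends and aggregation

Per county (or aggregate unit): OLS of ln(rate) on the year index
t = 0 … T−1 using smoothed (posterior-median) rates; crude-rate input is a
caller choice.  Total percent change = 100·(e^{(T−1)β₁} − 1) (the exponent
is 12 for a 13-year panel).  The 95% CI transforms the t-based CI of
(T−1)β₁ (T−2 degrees of freedom) through the monotone map 100(e^x−1) — a
delta-method interval that is exact under log-normality.  Significant
increase/decrease flags are set iff that CI excludes 0; they are mutually
exclusive by construction.  Classification shares carry Wilson binomial
CIs.  Two-stage uncertainty (posterior spread of the smoothed rates) is
not propagated into trend CIs — a known limitation; the smoothing makes
the trend inputs serially dependent and the flags correspondingly
conservative in magnitude but nominal-size calculations in the tests use
independent noise.

Aggregation to nation/state/region sums crude, unsuppressed Y and n
preserving the age × year structure (totals conserved exactly); counties
outside any region form rest-of-state units.  Standardization and trend
operations are then reused unchanged on aggregated panels.

## Synthetic vital statistics

The generator emulates the tabulated inputs with the structure the
analysis assumes:

* log true rate = log(baseline) + log(age multiplier_k) + u_i + v_i +
  slope_i·(t − t₀), u an ICAR draw on a rook lattice (drawn in the
  Laplacian eigenbasis with pseudo-inverse covariance, centered, rescaled
  so sd(u) = `spatial_sd`), v iid normal, slope_i ~ N(0, trend_sd);
* births n_ikt Poisson around a per-cell size parameter uniform on
  `births_range` (floored at 1); Y_ikt binomial(n, rate/100); early
  preterm a binomial thinning of Y.

Default conditions: baseline 12.6 per 100 (the national preterm scale),
early-preterm fraction 3.6/12.6, U-shaped age multipliers
(1.09, 0.93, 0.90, 0.96, 1.10, 1.27, normalized to mean 1) reflecting
elevated risk at the youngest and oldest maternal ages, spatial_sd 0.15,
heterogeneity_sd 0.08 (county rate multipliers with sd ≈ 0.17, matching a
90/10 county ratio near 1.5-1.6), trend_sd 0.008 (total 13-year percent
changes mostly within ±20%), births 50-500 per cell.  exp(u+v) is
normalized to empirical mean 1 so the population-weighted crude rate in
the first year sits at the baseline scale exactly in expectation.

SVI: overall percentile ranks of ρ·z + √(1−ρ²)·ε where z is the
standardized county effect, ρ = `svi_correlation`; themes likewise with
couplings (0.56, 0.35, 0.25, 0.20), theme 1 strongest.  The defaults are
analytic calibrations to the observed association scale: ρ = 0.68 makes
the ambient quartile-4-vs-1 rate ratio ≈ exp(σ_w · 2·1.271 · ρ) ≈ 1.34
(σ_w = 0.17; ±1.271 are the conditional means of a standard normal's outer
quartiles), and the theme-1 coupling starts from √0.27/√(3/π) ≈ 0.53
(√(3/π) is the Pearson attenuation of rank-transforming a normal latent)
adjusted to 0.56 for measurement attenuation quantified by simulation, so
that the univariate theme-1 R² on reference-year standardized rates ≈
0.27.  The R² calibration is defined at the reference year because later
years add trend-driven rate variance uncorrelated with the (static) SVI
latent.

What the generator does **not** emulate: real US county geography and
adjacency (a rook lattice stands in), migration and demographic drift,
within-county heterogeneity, raw SVI theme values, medically indicated vs
spontaneous subtypes, or reporting artifacts.  Passing recovery tests
therefore demonstrate internal statistical validity of the estimators
under the assumed structure — not agreement with restricted national
microdata, which cannot be redistributed or re-analyzed here.

## Problem sizes and numerical choices

Recovery tests run at 10×10 counties × 6 ages × 13 years with 50-500
expected births per cell and 5000 MCMC iterations (a few seconds per fit);
negative binomial calibration uses 200-1000 counties and 200 null
replicates; trend size/power uses 500-2000 counties.  The acceptance
script uses a 30×30 lattice for the national-scale and SVI measurements.
Quantile rule, rounding, tie-breaks and degenerate-input behavior are as
stated above; adaptive steps freeze at burn-in so the retained chain is a
fixed-kernel Markov chain; all randomness flows from explicit seeds
(generator, sampler, bootstrap are independently seeded streams).

## Known limitations

* Poisson-for-binomial likelihood: mild credible-interval conservatism.
* Trend and OLS stages use posterior medians without propagating
  posterior uncertainty (two-stage design mirrored from practice).
* The exchangeable-across-age δ block is one of several defensible
  cross-age correlation structures; alternatives (age-structured
  precisions, joint outcome modeling) are out of scope.
* Hyperpriors and MCMC lengths are package defaults, not canonical
  values; both are configurable and should be sensitivity-checked on
  real applications.
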