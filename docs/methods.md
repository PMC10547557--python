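# Methods

## Growth and production

Individual somatic growth follows the von Bertalanffy model
`dL/dt = K_max (L∞ − L)` with the asymptotic length taken equal to the
species' maximum length `L_max` and `K_max` the standardized growth
coefficient (yr⁻¹) the species exhibits when parameterized at that size.
The one-day increment is evaluated in closed form,
`ΔL = (L∞ − L)(1 − e^(−K_max/365))`, which is the exact solution of the
linear ODE over 1/365 yr (verified against adaptive numerical integration
to 1e−6 relative). Mass increments come through the allometric
length-weight curve `W = a L^b` (grams, lengths in cm). Fish recorded at
or above `L_max` — possible when binned lengths resolve to midpoints —
receive zero growth rather than a negative age (documented clamp).
Natural and fishing mortality are excluded by construction: the quantity
is each fish's maximum potential daily production.

Equating `L∞` with `L_max` is the simplest faithful reading of the
standardized-coefficient convention; the equivalence is isolated in one
function so a regression-based `L_max → L∞` correction can be substituted.

## Fishery services

Per transect and trophic group we compute standing biomass (kg ha⁻¹),
production (g d⁻¹ ha⁻¹), turnover (production/biomass as a percentage;
annual basis by default, daily available), and six nutrient production
rates: production × edible fraction (default 0.87, the mean edible
portion of finfish) × tissue concentration per 100 g. Units follow the
concentrations: calcium, iron, zinc in mg d⁻¹ ha⁻¹; selenium and
vitamin A in µg d⁻¹ ha⁻¹; omega-3 in g d⁻¹ ha⁻¹. Transect estimates are
averaged (unweighted) to site level, then converted to relative
contributions (%) per trophic group. Sessile invertivores are excluded
from contributions (not fishery targets); "fishable biomass" is total
standing biomass after the ingest exclusions. Site turnover for the
merged herbivore group is recomputed from merged production and biomass
rather than summing two ratios.

Recommended nutrient intakes are configuration, not code: the shipped
default YAML holds WHO/FAO-based daily reference intakes for adult women
aged 18–65 (calcium 1000 mg, iron 29.4 mg at low bioavailability, zinc
4.9 mg, selenium 26 µg, vitamin A 500 µg RAE, omega-3 1.1 g), the
reference population used throughout the reef-fish nutrition literature;
users can replace the file or pass their own table. Nutrient density caps
each nutrient's contribution at 100% of its intake *before* summation, so
the score lies in [0, 600] and a single concentrated nutrient (selenium)
cannot dominate.

## Trophic pyramids

Compositions close the three fished groups (herbivores = scraping
detritivores + browsers, mobile invertivores, piscivores) to a simplex.
Exact zeros (piscivores can be absent on heavily fished reefs) are
replaced by `zero_adjust = 1e−4` and renormalized, moving each part by at
most twice that amount; Dirichlet responses require strictly positive
parts. Two classification rules are implemented because both definitions
are in common use: `herbivore_majority` (bottom-heavy iff herbivore share
> 0.5; ties top-heavy) and the default `herbivore_vs_piscivore`
(bottom-heavy iff herbivores exceed piscivores; exact ties flagged). The
rules agree wherever either the herbivore or the piscivore share holds an
outright majority — property-tested over the full 0.01-step simplex grid.

## Composition model

`y_i ~ Dirichlet(μ_i φ)` with softmax link, mobile invertivore as the
reference category (its linear predictor is fixed at 0), a single scalar
precision φ, fixed standardized covariates (fishable biomass, five
benthic covers, depth), country-varying biomass slopes and
management-nested-in-country intercepts. Covariates are centred and
scaled by their sample standard deviation (ddof = 1); the constants are
stored for back-transformation and out-of-sample prediction. All five
benthic covers enter despite their sum constraint (a `drop_cover` flag
breaks the collinearity if desired); the observed design is far from
singular because total hard-bottom cover varies across reefs.

Priors are weakly informative and configurable: Normal(0, 2.5) on
standardized-scale coefficients, half-Normal(1) on the group-effect
scales, half-Normal(100) on φ. Group effects are non-centred in the MAP
parameterization.

**MAP + Laplace** (default): L-BFGS with the analytic gradient of the log
posterior (the standard multinomial-logit/Dirichlet chain rule; verified
against finite differences to 1e−9), followed by a numerical Hessian at
the mode. Laplace draws provide credible intervals; their 90% intervals
cover generating values at close to nominal rate in simulation.

**Full MCMC**: Hamiltonian Monte Carlo within Gibbs, in *total-effect*
coordinates — country total slopes `s_c = β_biomass + b_c` and management
total intercepts `t_cm = intercept + b0_cm`. In these coordinates every
HMC dimension is directly pinned by the likelihood, which removes the two
geometries that defeat fixed-metric samplers in the raw parameterization:
the funnel between group effects and their scales, and the prior-wide
ridge between the global biomass slope and the three country slopes. The
global intercept and biomass slope have exact Gaussian full conditionals;
the group-effect scales have one-dimensional conditionals (they touch the
data only through the deviations) sampled by exact slice sampling, with
several inner sweeps per iteration. The HMC block uses the Laplace
covariance as initial metric, switches to the empirical warm-up
covariance halfway through warm-up (Stan-style windowed adaptation), and
adapts its step size by dual averaging to a 0.8 acceptance target, with
jittered trajectory lengths of 8–24 leapfrog steps. Trajectories with
non-finite states or energy errors beyond 1000 are rejected and counted
as divergences. Four independent chains of 5000 iterations (first half
warm-up) reach max rank-normalized split-Rhat ≈ 1.002 on the recovery
problem in about three minutes; convergence is declared only below 1.01.
Draws are reported in centred coordinates (`b = s − β`).

The parameter-recovery study simulates composition records directly from
the model at n = 300 sites in 3 countries. It uses a high-precision
regime (φ = 80) so that a ±0.15 absolute recovery band on standardized
coefficients corresponds to more than three posterior standard deviations
for every fixed effect — the check is then sensitive to estimator bias
rather than to the irreducible Monte Carlo noise of one simulated data
set (MAP errors are calibrated: z-scores against Laplace standard errors
are standard normal). Country-slope and management-intercept deviations
are drawn centred (sum-to-zero) so fixed effects remain exactly
identifiable with only three countries.

## Synthetic data generator

The generator defines the study conditions for all tests: four countries
by default, 80 sites each, a 541-species pool, fishable biomass log-
uniform over 10–6000 kg ha⁻¹, belt transects from the standard dimension
set (5×50 m at 79%, 10×50 m at 14%, 2×30 m at 7%), with replication
inversely coupled to transect area (5–8 replicates for 60 m² belts, 1–3
for 500 m², median 3 overall) as in real multi-country programs. Half the
countries record 5 cm length bins below a 40 cm cut; simulated fish in
those countries sit exactly at bin midpoints so the midpoint convention
reconstructs them. Site compositions are drawn from the same hierarchical
Dirichlet model the fitter assumes (an optional logistic-normal mode
provides a misspecification check).

Species traits: maximum length log-normal within trophic group (σ = 0.45);
growth coefficient `K_max = 0.6 · diet · (L_max/10)^(−1) · e^(0.3 ε)`
clipped to the observed global range [0.011, 16.43], where `diet` encodes
faster growth toward the asymptote for herbivores and planktivores than
for piscivores of the same maximum size (the standardized coefficient is
predicted from maximum length *and* diet group); calcium, iron and zinc
decline with body size, selenium increases, vitamin A (elevated in
piscivores) and omega-3 are size-independent. A configurable flag removes
all trait-nutrient links for null-association tests.

Counts are filled to each site's biomass target with naturally sized fish
(asymptote-skewed beta sizes over 0.4–0.98 of `L_max`): a bulk stage
draws species whose largest individuals stay below 30% of the remaining
biomass, a closing stage resolves the final fractional fish by stochastic
rounding (accept with probability remaining/weight — unbiased for the
target, so sparse groups are genuinely absent from some transects), each
group's residual carries across the site's transects, and a site-level
reconciliation pass trims or tops up so realized fishable biomass lands
within about 2% of the target. Site species pools follow a body-size
spectrum centred on a biomass-dependent reference length — heavily fished
low-biomass reefs are dominated by small-bodied species — which also
keeps per-fish granularity small relative to poor sites' targets. With
these conditions, site-level annual turnover spans roughly 5–40%,
matching the range observed on real reef biomass gradients.

What the generator does *not* emulate: real species identities or
phylogeny, observer/detectability error, size-estimation bias, spatial
autocorrelation among sites, temporal revisits, and any matching of real
data distributions beyond coarse ranges. Passing tests therefore show the
pipeline's internal correctness and the fitter's ability to recover the
generating process — not that the ecological conclusions transfer to any
particular real data set.

## Problem sizes

Test and acceptance runs use deliberately compact studies: shared
fixtures of 3 countries × 12 sites with 120-species pools; the end-to-end
pyramid-regime check uses 200 sites; recovery uses 20 replicates of 300
sites; one full MCMC fit (4 × 5000 iterations) runs per suite. These
sizes were chosen so the whole suite completes in minutes while every
statistical check retains its intended power.

## Known limitations

- Binned lengths use the midpoint convention by default; the true
  within-bin distribution is unknown, and the bin→length rule is
  pluggable (`lower`, `geometric`) for sensitivity analysis.
- Turnover's time basis is reported as annual by default; the basis is an
  explicit argument and is stamped into outputs.
- The Dirichlet model uses a single scalar precision; per-category
  precision is out of scope.
- MAP intervals are Gaussian (Laplace) approximations; for skewed
  posteriors (group-effect scales with few groups) use the MCMC fit.
- The site-averaging order (average services, then normalize to
  contributions) is one of two defensible choices; the alternative
  (normalize per transect, then average) is available via the
  transect-level service table.
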