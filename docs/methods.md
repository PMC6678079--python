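# Methods

## Model

For crash *i* the two drivers' injury severities are modelled jointly.
Equation *j* = 1 is the rear (striking) driver, *j* = 2 the front driver.
Each driver has a latent injury propensity

    y*_ij = β'_ij x_ij + ε_ij,      (ε_i1, ε_i2) ~ N(0, [[1, ρ], [ρ, 1]])

censored into K = 4 observed levels (the regrouped KABCO scale: L1 no
injury, L2 possible, L3 non-incapacitating, L4 incapacitating or fatal) by
strictly increasing thresholds μ_j = (μ_j0, μ_j1, μ_j2):

    y_ij = c   iff   μ_{j,c-1} < y*_ij ≤ μ_jc,

with μ_{j,-1} = −∞ and μ_{j,3} = +∞.  The cell probability
P(y_i1 = k, y_i2 = l) is the bivariate-normal mass of a rectangle,
a four-term combination of Φ₂ values.  Unobserved heterogeneity enters
through random coefficients

    β_ij = β_j + γ_ij,     γ_ij ~ N(0, diag(σ_j²)),

drawn once per crash and mutually independent within and across equations;
cross-equation dependence is carried solely by ρ.

Identification: both error variances are fixed at 1, and whenever an
equation estimates a constant its first interior threshold is pinned at 0,
leaving (constant, μ_1, μ_2) free per equation.  Censoring uses half-open
intervals (μ_{c-1} < y* ≤ μ_c); the boundary event has probability zero,
so this is a simulation tie-break, not a modelling choice.

## Estimation

The likelihood of a crash with random coefficients is an integral over γ;
it is approximated by the average of the conditional rectangle probability
over R quasi-random realisations β + σ·z (maximum simulated likelihood).
Draws are Halton sequences — one prime base per random coefficient,
first 50 points dropped, random-shift scrambled by the seed, mapped
through the inverse normal CDF — fixed once per fit so the simulated
objective is smooth and deterministic.

* **Starting values** come from two independent univariate ordered probit
  fits (statsmodels `OrderedModel`, probit link; intercept-only models use
  the closed form through empirical cumulative shares), with every random
  SD initialised at 0.1 and ρ at 0.
* **Parameterisation** is unconstrained: thresholds as log increments
  above the pinned cutoff, SDs as log σ (bounded to [−6, 2.5] as a
  numerical guard), correlation as atanh ρ — so |ρ̂| < 1 and μ ordering
  hold by construction.
* **Optimiser**: L-BFGS-B (memory 30) with forward-difference gradients on
  the per-crash mean log-likelihood; convergence is a gradient max-norm
  below 1e−5 on that scale, with at most 500 iterations.  A warm stage
  first optimises on the leading R = 20 draws of the same Halton set
  (a coarser approximation of the same integral), then the full-R stage
  polishes; any SD sitting at its bound after the warm stage is reset to
  the initial 0.1 so the full-draw stage re-evaluates it — coarse-draw
  noise can otherwise collapse a genuine σ prematurely.
* **Standard errors**: central-difference Hessian (step 1e−4·max(1,|θ|))
  of the total log-likelihood at the optimum, inverted and mapped to the
  natural scale (σ, μ, ρ) by a delta method with a numerical Jacobian.
  An SD at its lower bound leaves the likelihood flat in that direction
  (the model has degenerated to a fixed coefficient there); such SDs are
  excluded from the Hessian and reported with z = NaN, p = 1.
* **Pruning**: while any random-coefficient SD has a two-sided p above 5%,
  the least significant one is converted to a fixed coefficient and the
  model refitted (the screening stage for candidate covariates uses 10%;
  both levels are config keys).  Wald tests on a boundary parameter are
  conservative approximations; the p = 1 convention for bound-stuck SDs
  makes the pruning rule's intent explicit.

Default R = 200 draws per crash and random coefficient, a standard choice
for mixed models of this size; R, seeds, tolerances and iteration caps are
all `FitConfig` fields.

## Bivariate normal CDF

One objective evaluation at n = 10,000 crashes and R = 200 needs several
million Φ₂ values, so the CDF is a numba port of Genz's BVND
(Gauss–Legendre with 6/12/20 nodes by |ρ|, Taylor-corrected branch for
|ρ| ≥ 0.925).  Within one likelihood call ρ is constant, so the sine
nodes are precomputed once; the four rectangle corners share their
marginal Φ terms (the corner products telescope into a product of
marginal differences); and crashes whose random-coefficient covariates
are all zero have draw-invariant linear indices and are evaluated once
instead of R times.  Accuracy of the CDF is ~1e−15 over |ρ| ≤ 0.9999
against independent quadrature.  Cell probabilities are floored at 1e−300
before the log, with a clamp counter surfaced in diagnostics rather than a
silent −∞.

## Synthetic data

Real crash extracts of this kind cannot be redistributed, so the
generator reproduces the statistical skeleton the analysis relies on:
~15k crashes; 0/1 dummy covariates at the prevalences of the published
summary table (driver-specific ones as separate (rear, front) rates,
crash-shared ones — light, region, season, hour, road — drawn once per
crash); mutually exclusive dummy groups (age bands, model-year bins,
region, traffic-way class) drawn categorically; and paired outcomes drawn
from the latent model above via the Cholesky factor of the error
correlation.  Heterogeneity draws are generated for every coefficient and
scaled by σ (zero for fixed ones), so a zero-σ model reproduces the
fixed-parameter generator draw for draw.

Quantities the source only summarises graphically (season, weekday,
traffic-way class) use round field-plausible shares (summer 0.25, Monday
1/7, traffic-way bins 0.15/0.25/0.05/0.03).  The generator matches
marginal prevalences only: it does not reproduce the joint covariate
distribution of real data (no age×sex dependence, no regional seasonality),
nor survey design weights, regional clustering, or measurement error in
police-reported severity.  Passing tests therefore demonstrate that the
estimator recovers the model's own data-generating process at realistic
effect sizes and sample sizes — not that the published coefficient values
are recoverable from a different extract.

Two fixtures package the published tables: the 4×4 joint severity counts
(15,159 crashes) with margins and an expansion to per-crash outcome
pairs, and the published coefficient set (means, SDs, thresholds
(0, 0.5090, 1.3173)/(0, 0.6191, 1.4814), ρ = 0.2440) as simulation truth.
The compact recovery fixture keeps a constant plus the age≤24 and male
dummies per equation and makes one coefficient per equation random: rear
age≤24 (σ = 0.3615, prevalence .367) and front male (σ = 0.5292,
prevalence .441).  These are the best-identified random rows: an SD on a
binary covariate is identified by the excess latent variance of the x = 1
subgroup, and a probe showed that a large σ on a low-prevalence dummy
(e.g. front age, prevalence .21) admits a spurious σ̂ → 0 local optimum at
moderate n.

## Problem sizes

The recovery study runs at n = 10,000 crashes, R = 200, ρ = 0.25, five
replications (standard errors on the first); unit tests use n between
1,200 and 4,000 with R = 25–50, and the pruning power study uses σ = 1.0
at n = 4,000 where the decision is near-deterministic (5/5 in a probe).
The draw-doubling monotonicity check runs on a 400-crash toy at R = 25/50.

## Known limitations

* Wald z on a variance-component boundary is not uniformly valid; a
  likelihood-ratio mixture test would be sharper but is not what the
  pruning rule in the source workflow uses.
* Random coefficients are uncorrelated (no Cholesky mixing), as specified;
  correlated mixing, marginal effects, and panel/temporal correlation are
  out of scope.
* The ML estimate of a mixing SD on a binary covariate is identified only
  through the excess latent dispersion of the x = 1 subgroup; its profile
  likelihood is flat and right-skewed at moderate σ, so σ̂ tends to sit
  above the truth in any one sample even at n = 10,000 (the recovery study
  reports the error in reported SEs for exactly this reason).  This is a
  finite-sample property of the estimand, not of the implementation: the
  generator's conditional cell frequencies match quadrature-integrated
  model probabilities to Monte-Carlo accuracy.
* The simulated likelihood is biased for finite R (log of an average);
  R = 200 Halton draws keeps this well below sampling noise at these
  sample sizes, and the optimum's log-likelihood is non-decreasing in R on
  the toy fixture (a property test).
* statsmodels emits convergence chatter for the starting fits on extreme
  data; starting values only need to be rough.
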