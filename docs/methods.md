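# Methods

This note documents the statistical models implemented in `dismap`, the
defaults of the synthetic-data generator, and the numerical choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design being modelled

The target design is an ecological small-area mortality study: yearly
cardiovascular death counts in ~190 municipalities over a six-year window,
a fixed reference population stratified by gender and twenty age classes,
an annual-mean PM2.5 exposure per municipality, and a three-level
degree-of-urbanisation label. Populations are heavy-tailed (one provincial
capital holds ~12–13% of residents), most municipalities are rural, and the
exposure surface is very strongly spatially autocorrelated (sample Moran's
I near 0.95), which makes exposure effects and spatially structured random
effects partially collinear — the central statistical difficulty this
pipeline is built around.

## Indirect standardisation

Expected counts use internal (indirect) standardisation: stratum risks
`risk_j = Σ_i deaths_ij / Σ_i pop_ij` over the 40 gender × age strata,
computed province-wide, then `e_i = Σ_j pop_ij · risk_j`. By construction
`Σ_i e_i = Σ_i y_i` within each risk-estimation window, which the code
asserts to 1e-9. Risks are re-estimated **per year** by default against the
fixed reference population (a `pooled` mode shares one risk set across
years); per-year estimation also absorbs any province-wide temporal trend
into the offset, so the regression models estimate purely cross-sectional
contrasts unless the pooled mode is chosen. The SMR is the Poisson MLE
`y/e`; its 95% interval is the exact chi-square (Garwood) interval with the
conventional lower bound 0 at `y = 0`. Rounding (e.g. rates per 1000 at two
decimals) is applied for display only.

## Moran's I and its permutation test

Spatial weights are the dichotomous symmetric contiguity matrix (row
standardisation available behind a flag, matching common practice but not
the default). `I = (n/S0) Σ w_ij z_i z_j / Σ z_i²` with `z = x − x̄`;
constant vectors are rejected. Significance uses random relabelling of the
values over areas with the plus-one estimator
`p = (1 + #{I* ≥ I}) / (n_sims + 1)` (one-sided for positive
autocorrelation by default, two-sided behind a flag), 10,000 permutations
by default. Under relabelling `E(I) = −1/(n−1)`.

## Descriptive Bayesian models

**Gender share.** Male deaths per year follow `y ~ Binomial(π, n)` with the
conjugate prior `π ~ Beta(1, 3)`; posteriors are closed form, and yearly
differences are summarised by pairwise `P(π_t > π_u)` from independent
posterior draws. The "no trend" verdict requires every pairwise probability
inside (0.05, 0.95) — one concrete operationalisation of a posterior-
probability trend screen, flagged as such.

**Robust subarea pooling.** Subarea-year mean SMRs (unweighted means over
the areas of a subarea) are pooled per subarea with a Student-t(ν = 10)
likelihood with location θ and scale σ, `θ ~ Normal(1, 1)` (centred at the
null SMR), and `σ² ~ Scaled-Inv-χ²(10, s²)`, where the prior scale s² runs
over a grid of 100 equally spaced values in [0.1, 1.5]. Because how the
grid should be collapsed into one summary is an open design question, the
whole grid is reported; subareas are called "not significantly different"
only when their 95% intervals for θ overlap at **every** grid value. The
two-parameter posterior is evaluated by grid quadrature (241 × 161 nodes on
θ × log σ²), which is deterministic and exact to grid resolution — with two
free parameters there is no reason to pay MCMC noise here. The
t-likelihood grid is shared across prior scales, so the 100-point sweep
costs one likelihood evaluation.

## The model grid

Eight hierarchical Poisson log-linear models:

| family | random component        | phase |
|--------|-------------------------|-------|
| M1     | none                    | 1     |
| M2     | IID intercept `u_i`     | 2     |
| M3     | ICAR intercept `s_i`    | 3     |
| M4     | BYM: `u_i + s_i`        | 4     |

each with (B) and without (A) a linear year term. Covariate coding:
PM2.5 centred at the grand mean over all area-years and scaled by
15 µg/m³ (so the coefficient is a log rate ratio per 15 µg/m³ and the
column mean is exactly zero); urban and peri-urban merged so `rural` is a
0/1 indicator; `year_c = year − first_year`. Expected counts enter as the
offset `log e_it`. Random intercepts are shared across years within an
area, so the fitted RR surface is temporally smoothed; the adjacency matrix
is one constant matrix for all years.

Priors: `β ~ Normal(0, 3²)` ("standard deviation of 3 on the log ratio
scale"; its 95% prior interval ≈ ±5.88 is one of the calibration checks).
Random-effect variances carry Inverse-Gamma(0.01, 0.01) hyperpriors by
default; because IG(ε, ε) is known to behave badly when the variance is
near zero, a `half_normal` family (on the SD scale) is available in the
same prior slot. The BYM component uses the classic two-variance
convolution, not the rescaled BYM2.

A Poisson log-linear model yields **rate ratios**; the package reports the
exponentiated coefficients as RR throughout (part of the applied literature
prints them as OR).

### ICAR parameterisation

The intrinsic CAR prior `p(s) ∝ exp(−½ Σ_{i~j} (s_i − s_j)²/σ_s²)` is
improper with a flat direction along the constant vector. Rather than a
soft sum-to-zero constraint, the implementation whitens the prior in the
spectral basis of the graph Laplacian: `s = σ_s · V₊ Λ₊^{−1/2} z`,
`z ~ N(0, I_{n−1})`, where `(Λ₊, V₊)` are the non-null eigenpairs. This is
the same distribution restricted to the sum-to-zero subspace, imposes the
constraint exactly, and presents HMC with a near-spherical geometry — in
development the soft-constrained parameterisation mixed an order of
magnitude worse under the static-trajectory sampler. The eigendecomposition
is O(n³) once per fit, negligible for lattices of a few hundred areas (a
sparse formulation would be needed for much larger maps).

### Sampler

Fitting uses a compact Hamiltonian Monte Carlo sampler written for this
package (analytic gradients of the joint log density; no autodiff stack):
static trajectories with leapfrog length jittered uniformly on
{1, …, 24}, dual-averaging step-size adaptation targeting 85% acceptance,
and a diagonal mass matrix estimated from the 30–80% warmup window, after
which step-size adaptation restarts. Chains are vectorised: all chains step
through the same trajectory lengths simultaneously, with per-chain step
sizes and accept/reject decisions. Proposals with energy error beyond 1000
count as divergences and are rejected. IID effects are non-centred
(`u = σ_u z`), and variances are sampled as `log σ²` with the prior
Jacobian included.

Defaults follow the study contract — 4 chains, warmup equal to the
retained half of each chain, 4 × 5000 = 20,000 retained draws — but every
entry point takes `chains/draws/warmup`, and the test suite and example
configs run scaled-down chains (2–4 chains × 250–1000 draws) on scaled-down
bundles (40 areas × 2 years), sizes chosen so the whole suite stays
interactive while every behavioural check retains power. Exceedance
probabilities are computed over all retained draws (the estimand is
identical to resampling a fixed 100,000; this deviation is deliberate).
Convergence is gated on split-Rhat ≤ 1.01 (via arviz, computed for the
coefficients, variances and all random effects): an unconverged fit is
returned flagged with warnings, never silently, and `propagate_priors`
refuses it.

### Prior propagation between phases

Phases are fitted in order M1 → M2 → M3 → M4. The best fit of a phase (by
WAIC) defines the next phase's priors: each shared coefficient gets
`Normal(posterior mean, posterior SD)`, and each variance component with a
counterpart in the previous fit gets an Inverse-Gamma re-centred on the
posterior median m of σ², parameterised as IG(4, 3m) (mean m, SD m/√2 —
informative but not dogmatic). The BYM phase draws its IID variance prior
from the IID phase and its coefficient/ICAR priors from the ICAR phase,
since its immediate predecessor carries no IID component. This narrowing of
coefficient priors is what controls the collinearity between the spatially
smooth exposure and the ICAR field: with a tight prior from a phase without
spatial random effects, the CAR component can no longer absorb the exposure
contrast. (The exposure surface is nearly time-invariant within an area, so
even the IID intercepts partially absorb cross-sectional exposure effects;
at full study scale the exposure coefficient is weakly identified and
propagated priors matter.)

### Risk classification

Per area-year, the posterior RR is `exp(log μ − log e)`; the summary is its
median and `PP = P(RR > 1)` over all retained draws. `PP > 0.90` classifies
"high", `P(RR < 1) > 0.90` classifies "low" — for continuous posteriors the
low rule is identical to `PP < 0.10`, but posterior mass exactly at RR = 1
counts toward neither tail, so a degenerate all-unity posterior is neutral.
Choropleths bin RR at {0.75, 1.00, 1.25} and PP at {0.10, 0.90}.

## Model comparison

WAIC: `lppd_i = log mean_d exp(ll_di)`, `p_waic,i = Var_d(ll_di)` (sample
variance, n−1), `elpd_i = lppd_i − p_waic,i`, reported on the deviance
scale `−2 Σ elpd_i` with `SE = 2 √(n · Var_i(elpd_i))`. LOO uses
Pareto-smoothed importance sampling: raw log ratios `−ll_di` are smoothed
with arviz's PSIS routine and `elpd_i` is the self-normalised estimate;
observations with Pareto k > 0.7 are flagged. Pairwise comparisons use the
pointwise elpd differences for the SE, a two-sided normal test, and
Bonferroni correction over all pairs in the call. The elpd-difference SE is
known to be unreliable when two fits are nearly identical replicas of the
same model (their pointwise MC errors are correlated across observations
through the shared draws); the comparison is meant for distinct models on
identical data, and the null calibration is verified in the tests with a
model whose per-observation posteriors are independent.

## Synthetic-data generator

The generator's defaults are the study conditions; they are fixed, not
tuning knobs.

- **Lattice**: a seeded Voronoi tessellation of uniform points in a
  1.25 × 1 rectangle (mirror-image trick for bounded boundary cells);
  contiguity from shared cell edges, which yields the irregular degree
  distribution of real municipal maps (a regular rook grid is available).
  Subareas of exact sizes 53/58/77 are cut as slabs along a projection
  direction, retrying directions until every slab induces a connected
  subgraph. Urbanisation: 2 urban cores (the most central area of each of
  the two largest subareas) with peri-urban rings grown outwards to 28
  non-rural areas in total; the rest (160/188) rural.
- **Population**: log-normal area weights (σ = 1) with one dominant area
  drawn to hold 11.8–13.2% of the total (the provincial capital), floors of
  100 residents per area, total 535,666. One fixed age profile (a two-bump
  mixture peaked at mid-life with an old-age shoulder) and a male fraction
  declining linearly with age, shifted so the expected male share is
  exactly 48.28%; cells are integerised by largest-remainder rounding, so
  the realised male share matches to rounding error. The table is
  replicated across years (fixed reference population).
- **Exposure**: a Gaussian field synthesised in the Moran-eigenvector
  basis of the contiguity graph (eigenvectors of the doubly centred
  adjacency matrix) with spectral weights λ⁵, plus a monotone north–south
  gradient (weight 0.3); `spatial_range` (default 0.985) is the variance
  share of this smooth component against white noise, and a small yearly
  innovation (SD 0.1) keeps the pattern stable across years. Each year is
  rescaled exactly to the target mean/SD — defaults are the study window's
  printed yearly means (17.5–23.6 µg/m³) and SDs (5.1–6.5) — and floored
  at 0.5 µg/m³. This calibration gives sample Moran's I ≈ 0.95 on a
  188-area lattice, emulating the study's I = 0.954; a first-order GMRF
  draw on the graph was tried first and cannot reach that smoothness (its
  fields top out near I ≈ 0.6), which is why the spectral synthesis is
  used.
- **Outcomes**: baseline stratum risks rise exponentially with age class
  (log slope 0.45 per class, ×1.3 male excess at a given age), normalised
  so the implied crude rate is 4.5 per 1000 (the scale of the study's
  printed rates). Deaths are drawn at the stratum level,
  `Poisson(pop_aj · risk_j · exp(η_at))` (capped at the stratum
  population), with the linear predictor coded exactly as the risk models
  code it; area-year totals and province-wide stratum totals are therefore
  consistent realisations of one process, and the stratum table feeds
  internal standardisation downstream. Default effects: RR 1.075 per
  15 µg/m³ PM2.5, RR 1.022 for rural, no year trend, IID heterogeneity
  SD 0.15 (BYM optional). The full truth (coefficients, random effects,
  per-area-year RR) is stored in the bundle.

What the generator does **not** emulate: real municipal geography and
polygon shapes, spatial clustering of the population beyond one dominant
area, age-profile differences between areas, migration or population
change over time, exposure measurement error, and any confounder beyond
urbanisation. Passing tests therefore demonstrate that the estimators
recover the generating process under the study's data structure — not that
the substantive findings of any particular real-world analysis are
correct.

## Numerical choices and degenerate inputs

- Linear predictors are clipped at ±30 before exponentiation; unstable
  proposals become −∞ log densities and are rejected.
- `Moran's I` errors on constant vectors; `compute_smr` errors on e ≤ 0;
  standardisation errors when a stratum has deaths but no population;
  `exceedance_summary` uses strict `>` at the limit value.
- Bundle loading rejects (rather than repairs) asymmetric adjacency,
  missing areas, negative counts and deaths exceeding population.
- All randomness flows from explicit integer seeds; `make_bundle` and the
  pipeline spawn per-stage sub-seeds deterministically, so identical
  configurations reproduce byte-identical tables.

## Known limitations

- Dense eigendecompositions (lattice generation, ICAR whitening) limit
  practical lattice sizes to a few thousand areas.
- The static-trajectory HMC is tuned for these posteriors; it has no
  NUTS-style adaptive trajectory length and may need a larger
  `max_leapfrog` for substantially stiffer models.
- No spatio-temporal interaction random effects, Leroux/BYM2 variants, or
  exposure measurement-error models; direct standardisation and external
  reference populations are out of scope.
- PM2.5 centring is global (one grand mean over all area-years), not
  per-year; with per-year risk re-estimation in the offset this is the
  natural pairing, but analysts pooling risks across years may prefer
  per-year centring.
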