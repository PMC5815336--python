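# Methods

This note documents the models implemented in `steppediv`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions that affect results.

## Survey data model

The unit of analysis is a *subplot*: a regular grid (default 10×10) of square
quadrats (default 0.5 m side, so 0.25 m² each, 25 m² per subplot), each with
integer individual counts per species and optional environmental
measurements. Replicate subplots (default three per treatment) share a
species pool (union of columns; absent species read as 0) and a treatment
label, `grazed` or `fenced`.

Conventions, stated once and used everywhere: grid indices are 0-based
(row, col); the quadrat centre is at ((col+0.5)·q, (row+0.5)·q) metres for
quadrat size q; all distances are Euclidean between quadrat centres.

**Windows.** Nothing in a quadrat survey dictates how larger square sampling
units are placed, so window placement is explicit: the default is
non-overlapping tiling anchored at (0, 0) (⌊rows/k⌋·⌊cols/k⌋ windows of side
k, leftover quadrats dropped for that k), which keeps the per-area values
statistically independent and matches a nested-quadrat reading; a `sliding`
mode (all (rows−k+1)(cols−k+1) placements) is available where smoother
surfaces are wanted at the cost of overlap.

**Aggregation over replicate subplots.** Quantities are always computed per
subplot first and averaged afterwards — raw counts are never pooled across
subplots. For per-quadrat analyses (variograms, variance partitioning) the
aligned-cell mean is used: each grid position's value is averaged over the
replicate subplots of a treatment, yielding one field of 100 values per
treatment.

## Diversity metrics

Richness S (count of species present), abundance N (count of individuals),
Shannon H′ = −Σ pᵢ ln pᵢ, Simpson D = 1 − Σ pᵢ², Pielou J = H′/ln S, and
density N/area. Natural logarithms throughout. Windows with no individuals
yield NaN (an explicit undefined marker) for the relative-abundance indices
rather than 0, and curve averaging skips them; returning 0 would silently
drag diversity–area points downward. Shannon/Simpson/Pielou are evaluated by
scikit-bio behind this module's interface.

## Diversity–area models

Curves are (A, S̄) pairs with A = (k·q)² and S̄ the subplot-averaged window
mean at side k (k = 1..10 by default, so A spans 0.25–25 m²). Families:

| family | formula | parameters |
|---|---|---|
| power (multiplicative) | S = αA^β | 2 |
| power (additive) | S = α + A^β | 2 |
| exponential | S = α ln A + β | 2 |
| logistic | S = β/(1 + exp((δ − log A)/α)) | 3 |
| parabolic | S = α(ln A)² + β ln A + δ | 3 |
| linear | S = αA + β | 2 |

Both power dialects are first-class because both appear in field practice;
they must be selected explicitly. The `log` inside the logistic and
parabolic families is the natural log by default and configurable to
base 10; every fit records the base used.

Fitting is least squares on the original response scale (no log transform of
S), so the selection criterion — the residual sum of squares — is comparable
across families; ties are broken in favour of fewer parameters.
Linear-in-parameter families (exponential, parabolic, linear) are solved
exactly by `lstsq`; the others by Levenberg–Marquardt from a fixed,
documented multi-start grid (logistic: β₀ = 1.05·max S, δ₀ = log median A,
α₀ ∈ {0.5, 1, 2, 5}; power: slope of the log–log fit), making the result
deterministic for a given curve. 95% confidence half-widths come from the
local linearisation: t₀.₉₇₅,ₙ₋ₚ · SE with the covariance σ̂²(JᵀJ)⁻¹. A
constant curve gets an exact flat fit (with a zero-variance warning) for
families that can represent one; the logistic cannot and raises.

**Null model.** Random placement preserves each species' whole-subplot total
Nᵢ and drops every individual uniformly over quadrats. The closed-form
expectation at subarea fraction a/A is E[S] = Σᵢ [1 − (1 − a/A)^{Nᵢ}]; the
randomisation version re-places individuals (multinomial over cells),
recomputes the tiling curve, and reports the replicate mean and 2.5/97.5%
quantiles. Individuals (not occurrences) are randomised because abundance
data are available; the two routes agree within Monte Carlo error and are
tested against each other.

## Variograms

The empirical semivariogram is the omnidirectional Matheron estimator:
unordered point pairs binned by distance into classes of width one quadrat
size (0.5 m), pairs beyond the maximum lag (default half the largest
inter-point distance) excluded, NaN values dropped pairwise. Defaults are
standard practice for a regular grid and are configurable and logged.

Model fitting is weighted least squares with pair counts as weights —
distant, pair-poor bins should not steer the fit — with C₀, C ≥ 0 enforced
by bounds. R² is computed unweighted over the lag means so it can be read
like an ordinary goodness of fit. Because the exponential and Gaussian
sills are asymptotic, the reported range A₀ is the practical range (95% of
sill): 3a for exponential, √3·a for Gaussian, a for spherical; the raw a is
reported alongside. The range parameter is capped at the largest sampled
lag: beyond the lag window the range is not identifiable, and an unbounded
fit of a trend-like (non-plateauing) variogram otherwise runs to an infinite
sill. Structural variance is likewise capped at 10× the larger of sample
variance and maximum semivariance. A flat empirical variogram or a
non-converged fit falls back to pure nugget with a warning.

The treatment comparison labels the sill change fenced − grazed as
increased/decreased, or unchanged when within 5% of the larger sill — a
reporting tolerance, not a significance test.

## Variance partitioning

Responses are the per-quadrat diversity variables (aligned-cell means per
treatment); a Hellinger-transformed community matrix (per-row
√(count/row-total)) can be supplied instead, and both paths share one code
path via a p ≥ 1 response contract. Environmental variables are z-scored
(sample SD, ddof = 1); constant columns are dropped with a warning, and a
greedy |r| > 0.8 pre-filter removes strongly collinear variables before
selection (threshold configurable).

**PCNM.** Spatial predictors are the classical principal coordinates of
neighbour matrices: Euclidean distances truncated at t = the longest
minimum-spanning-tree edge (the smallest threshold keeping the graph
connected), distances beyond t replaced by 4t, Gower double-centring of
−½D², eigendecomposition, and retention of axes with eigenvalue >
1e−10 × the largest. Leading axes are broad-scale spatial waves; trailing
ones fine-scale. The construction is cross-checked in the test suite
against an independent dense eigendecomposition and against R's
`vegan::pcnm`.

**RDA R² and adjustment.** The (column-centred) response is projected onto
the orthonormalised span of the centred predictors; R² is the explained
share of the total sum of squares, reducing to ordinary multiple-regression
R² for a univariate response. Rank-deficient predictor sets are reduced
with a warning, never silently. Adjusted R² uses the Ezekiel formula
1 − (1 − R²)(n − 1)/(n − m − 1), the standard choice for this partitioning
framework.

**Forward selection.** Three stopping rules together:

1. a *global pre-test* — a permutation test of the model containing every
   candidate; if it is not significant at α nothing is selected. Without
   this, greedily testing the best of k candidates inflates the type-I
   error far beyond α; with it, the probability of selecting anything under
   a null response is ≈ α (verified at α = 0.05 over 500 all-noise
   replicates in the acceptance suite);
2. per-step permutation tests (residuals of the current model permuted,
   Freedman–Lane conditioning; p = (#{F* ≥ F} + 1)/(n_perm + 1), default
   n_perm = 999) with stop at p > α;
3. stop when the cumulative adjusted R² would exceed the full model's.

Ties in added R² break to the lowest candidate index, so the selected set
is invariant to candidate order and deterministic under a seed.

**Fractions.** With selected sets E and S: a + b = adjR²(E), b + c =
adjR²(S), a + b + c = adjR²(E ∪ S); a, b, c, d follow by subtraction and
sum to 1 exactly. Individual fractions may be slightly negative (an
adjusted-R² artifact) and are reported raw, with a floor-at-zero display
option; percentages are the raw fractions × 100. [a] and [c] are tested by
residual permutation under the partial model, [a + b + c] by raw
permutation of the response.

## Synthetic community generator

The generator emulates the survey design the analyses assume: per subplot,
environmental fields are zero-mean Gaussian random fields with exponential
covariance C(h) = σ²·exp(−h/a) plus nugget noise, sampled exactly by
Cholesky factorisation of the dense covariance of quadrat centres
(escalating jitter 0 → 1e−6 if factorisation fails). Species counts are
Poisson with a log link:

n_sq ~ Poisson(exp(μ_s + Σ_v β_sv·env_v + clustering_s·GRF_s + log t_s))

with a species-specific aggregation field GRF_s (range 0.3 m) and treatment
multiplier t_s. Poisson-with-log-link is the simplest count model
compatible with the Hellinger and variogram assumptions downstream;
overdispersed (negative-binomial) counts are a possible extension.

Defaults describe a semi-arid bunchgrass steppe:

- 10×10 grid of 0.5 m quadrats, 3 subplots × 2 treatments, 25 species;
- seven environmental fields (soil water, compaction, organic carbon, four
  texture fractions) with ranges 0.5–1.0 m — the fine-scale autocorrelation
  a 0.5 m grid can resolve; dominant-grass cover and density are derived
  from the simulated grass itself;
- species pool: one dominant unpalatable bunchgrass (mean ~16
  individuals/quadrat, weakly clustered) plus 24 subordinate species with
  lognormally spread mean abundances (median 0.35/quadrat) and moderate to
  strong aggregation, giving ~8–11 species per quadrat rising to ~25 per
  subplot. Every species responds positively to soil water (moisture
  limitation is near-universal in desert steppe, and a shared driver is
  what gives richness its spatial structure); responses to texture/carbon
  are species-specific in sign;
- treatment effects: inside the fence palatable species' expected
  abundance is ×0.25 (release of the dominant grass crowds out subordinate
  forbs over a multi-year exclusion) and unpalatable species' ×2.2
  (herbivory release). These produce the two contrasts the design encodes —
  more individuals but fewer species per quadrat inside the fence — in
  ≈96% of simulated surveys each.

Everything derives from one integer seed (numpy `SeedSequence`; the
pipeline fans the run seed out to per-stage child seeds by a fixed indexed
rule so stages can be re-run in isolation).

What the generator does **not** emulate: temporal dynamics of the exclusion
(treatments differ only through static multipliers), between-subplot
environmental gradients (subplot fields are i.i.d. realisations),
species interactions, overdispersion beyond log-normal×Poisson mixing, and
observation error in the environmental measurements. Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the stated model, not the field realism of any particular fitted
value.

## Numerical choices and edge cases

- Nonlinear fits use tight tolerances (1e−14) and fixed multi-starts;
  noise-free curves from every family are recovered to 1e−6 (tested).
- Monte Carlo agreement checks use 3 standard errors plus a rule-of-three
  absolute slack (3/n_reps): near saturation a species-miss can be too rare
  for any replicate to show, collapsing the empirical SE to zero while the
  closed-form expectation still differs by a sliver.
- Spherical-model ranges shorter than the first lag are not identifiable
  (the model is exactly flat beyond the range); tests use identifiable
  configurations and the fitter reports whichever exact-fit member the
  multi-start reaches.
- Empty selections are valid everywhere: the partition collapses exactly
  (b = c = 0, a = adjR²(env) when space selects nothing).
- Permutation p-values use the add-one convention, so the smallest
  attainable p is 1/(n_perm + 1).

## Problem sizes

Default analysis sizes: 10 window sides per curve, 999 null-model
replicates, 999 permutations for selection and partitioning (the pipeline
default uses 199 null replicates; drivers that print headline tables use
999). The test suite exercises grids up to 30×30 for calibration
simulations and 500 replicates for the selection type-I check; these sizes
give stable Monte Carlo estimates at the stated tolerances.

## Known limitations

- Variogram ranges reported at or near the lag cap mean "no plateau within
  the sampled window", not a measured range.
- The per-step forward-selection test is conditionally valid given the
  global pre-test; p-values of later steps inherit selection effects, as in
  the standard procedure.
- Diversity–area CIs assume independent homoscedastic residuals across
  areas; with tiling windows the per-area means are near-independent, but
  the small number of areas (10) makes the t-based CIs approximate.
- The significance labels of the partition test [a] and [c] refer to the
  selected predictor sets, conditioning on (not accounting for) selection.
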