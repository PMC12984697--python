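# Methods

This note documents the statistical procedures implemented in
`farmsustain`, the choices made where the methodology is genuinely open,
and what the synthetic generator does and does not emulate.

## Efficiency measurement

Technical efficiency is the radial input-oriented score under variable
returns to scale (VRS): the envelopment LP minimises θ subject to the
evaluated farm's input bundle, contracted by θ, remaining producible by a
convex combination of observed farms at no less than the farm's output.
The convexity constraint Σλ = 1 distinguishes VRS from CRS; dropping it
gives the CRS variant (`rts="crs"`), and VRS scores dominate CRS scores
farm by farm.

Numerical choices:

- LPs are solved with HiGHS at feasibility/optimality tolerance 1e-8.
  Input and output columns are rescaled to unit mean before solving;
  radial scores are units-invariant, so this is purely a conditioning
  measure (survey input columns span five orders of magnitude).
- Zero or near-zero inputs make a radial model ill-posed, so inputs are
  floored at 1e-6 × the column mean, with a warning. Survey near-zeros
  (e.g. a 0.01 kg concentrate record) are placeholders, not measurements.
- A second-stage slack maximisation at fixed θ is available
  (`slack_stage=True`) to expose non-radial input excess, but scores and
  group labels are defined by the radial stage alone.
- Efficiency groups partition (0,1] exhaustively as [0,0.50],
  (0.50,0.75), [0.75,1]. Published band conventions written as
  "0.51–0.74" leave continuous scores between 0.50 and 0.51 unassigned;
  the half-open convention closes that gap while agreeing with the
  published bands at every score they cover.

An exhaustive active-set vertex-enumeration solver
(`farmsustain.dea_reference`) provides an algorithmically independent
check: every basic solution of the envelopment polyhedron is enumerated
and the minimal feasible θ returned. It is exponential in farm count and
intended only for validating the LP path on small instances, which the
test suite does on random problems to 1e-6.

## Composite sustainability index

Indicators are defined by a user-editable YAML schema (name, dimension,
direction, scale). Normalisation is directional min–max against the
observed sample range — the analysed sample is the reference frame, so a
dimension index is invariant to affine re-unit-ing of any indicator.
Open choices, resolved as follows:

- Constant columns carry no ordering information and map to 0.5 for all
  farms (warning issued): a neutral value that does not drag the
  dimension mean toward either pole.
- Missing responses are imputed with the indicator median, with a count
  in the warning.
- Frequency scales ("never" … "more than four times a year") are coded
  linearly 1–6 before normalisation; the coding lives in the schema and
  can be replaced.
- Within a dimension, indicators are equally weighted (arithmetic mean);
  differential indicator weighting would require evidence the survey
  instruments do not provide.
- In the default schema both herd size (capital intensity, $/LU) and
  unit production cost are negative-direction economic indicators; the
  shipped schema is a starting point and fully user-editable.

Dimension weights come from AHP over expert pairwise comparisons on
Saaty's 1–9 scale: entrywise geometric-mean aggregation (which preserves
reciprocity exactly), then priority weights by the row-average
approximation (default, matching common field practice) or the principal
eigenvector (power iteration to 1e-12; both methods agree exactly on
consistent matrices and within 0.02 per component near consistency).
Consistency uses λmax = mean((Aw)_i / w_i), CI = (λmax − n)/(n − 1), and
CR = CI/RI with Saaty's random indices (RI = 0.58 at n = 3); CR < 0.10
is the acceptability bound. For the widely used worked-example matrix
[[1,2,2],[½,1,2],[½,½,1]] the row-average weights round to
(0.49, 0.31, 0.20) and CR ≈ 0.046.

The composite index is the weighted sum CSI = w₁·ESI + w₂·EnSI + w₃·SSI,
computed per farm; because the weights are fixed, the mean CSI equals
the same combination of the mean dimension indices. Classes are
Unacceptable (≤0.20), Borderline (≤0.40), Average (≤0.60), Good (≤0.80),
Best (≤1.00), with the bottom class closed at 0.

Scale reliability is summarised by Cronbach's alpha with sample (n−1)
variances. Note alpha equals 1 only for *parallel* perfectly correlated
items; unequal item variances lower it even at correlation 1.

## Group comparison

Kruskal–Wallis H is computed from pooled midranks with the standard tie
correction and referred to χ²(k−1); an exact permutation p-value by
complete enumeration of group assignments is available for pooled N ≤ 10
(at N = 6 with two groups of three, the χ² approximation gives 0.0495
where the exact answer is 0.100 — small-N asymptotics are rough, which
is why the exact option exists). All observations identical is signalled
as an error (the tie correction degenerates). Shapiro–Wilk is delegated
to SciPy's Royston implementation rather than re-derived. No post hoc
pairwise tests or multiplicity adjustment across the four dimensions are
applied; the omnibus H per dimension is the analysis.

## Two-limit Tobit

The latent score y* = x'β + ε, ε ~ N(0, σ²), is observed censored at
both limits (0 and 1 for DEA scores; with DEA there is exact mass at 1
and usually none at 0, and the two-limit likelihood degenerates
correctly). Observations within 1e-9 of a limit count as censored.
The likelihood is maximised by BFGS on (β, log σ) with analytic
gradients from an OLS warm start (log σ makes the search unconstrained);
convergence requires gradient norm below 1e-5. Standard errors use the
observed information — the numerical Hessian of the negative
log-likelihood at the optimum — which is one of the two conventions
desktop packages use; z-scores are asymptotically normal.

Average marginal effects are on the *observed* (censored) outcome:
AME_j = β_j · mean_i[Φ((U−x_i'β)/σ) − Φ((L−x_i'β)/σ)]. The bracket is
one scalar shared by all covariates, so AME/β is constant across slopes
— an algebraic identity the tests verify to machine precision. A
discrete-difference AME for binary covariates is available separately.
Diagnostics: LR test against the intercept-only fit, centered VIFs
(infinite VIF flagged on perfect collinearity), and White's n·R² test
with squares and cross products, dropping rank-deficient auxiliary
columns. With many binary regressors, squares duplicate levels and are
dropped by the rank check; the χ² df is the retained column count.

A single regression specification is fitted (the seven standard
covariates: crop and livestock experience, education level, non-farm
income, indebtedness, computer, internet); no information-criterion
specification search is performed.

## Sampling design helpers

Required stratified sample size:
n = (Σ N_h S_h)² / (N² D² + Σ N_h S_h²) with D² = d²/z², rounded up;
z defaults to 2.576 (99% confidence) and d is an *absolute* margin of
error (a relative margin must be converted by the caller). Neyman
allocation is proportional to N_h S_h with largest-remainder rounding
(conserves the total deterministically) and per-stratum caps at N_h with
redistribution.

## Synthetic generator

The generator emulates the study conditions of a 72-farm smallholder
buffalo survey:

- **Production**: Cobb–Douglas frontier over the five inputs with
  elasticities (0.15, 0.10, 0.45, 0.15, 0.05) summing to 0.9 — herd size
  is the dominant input and the technology is concave, so the production
  set is convex and the VRS frontier is the correct benchmark. Observed
  GPV is frontier output × true efficiency, rescaled so the sample mean
  GPV equals the published survey mean 13,800.57 $/farm (input-oriented
  DEA is invariant to output scaling, so this calibration changes no
  score).
- **Inputs**: lognormal marginals matched to the published means and
  coefficients of variation (roughage 39,834 kg cv 1.84; concentrate
  13,151 kg cv 1.53 with 6% near-zero placeholders; 22.4 LU cv 0.82;
  1,614 h cv 0.81; $510 cv 0.63), sharing a common farm-size factor with
  loading 0.9: feed, labor, and veterinary spending scale nearly
  proportionally with herd size, and this realistic co-movement is also
  what lets a 5-input DEA at n = 72 discriminate (the package's
  known-truth check requires rank correlation > 0.7 between true and
  DEA-estimated efficiency on average).
- **True efficiency**: e = clip(1 − u + x'β + σ_t·ε, 0.05, 1) with u
  half-normal (scale 0.3, the baseline managerial inefficiency) and
  x'β a centered covariate shift with slopes (−0.014, +0.255, +0.016,
  −0.059, −0.203, −0.118, +0.176) and σ_t = 0.12. The clip at 1 yields
  an exact frontier mass (≈14/72 at the defaults — the published
  right-censoring pattern); with the slopes, σ_t and the inefficiency
  scale all zero, every farm is fully efficient. Covariate marginals
  match the published summary statistics; crop and livestock experience
  are drawn with correlation 0.8 (farmers accumulate both in parallel).
- **Indicators**: drawn from per-indicator priors (Bernoulli,
  categorical, truncated normal, lognormal, Poisson). By default the
  economic indicators GPV, relative/absolute profit, herd size and unit
  cost are *derived* from the production block, so they genuinely carry
  efficiency signal; `independent_indicator_priors()` replaces every
  derived channel with free marginals, giving the zero-linkage null
  under which efficiency groups should not differ in sustainability.
- **Experts**: pairwise matrices are w_i/w_j × lognormal noise snapped
  to the nearest Saaty value, exact reciprocals below the diagonal;
  at zero noise (and Saaty-expressible weight ratios) the matrices are
  exactly consistent, and geometric-mean aggregation over 17 experts
  recovers the true weights within 0.05 per component at noise SD 0.1.

All randomness flows from a single seed (default 20240201) through
named spawned PCG64 substreams, so identical configurations produce
byte-identical tables and extending one block never reorders another.

What the generator does **not** emulate: the joint distribution of a
real survey (only marginal moments and the censoring pattern are
targeted), item-level correlation among Likert scales (Cronbach's alpha
on generated data is near 0 by construction, not the "acceptable to
high" values real instruments show), measurement error, nor any
behavioural response linking efficiency to sustainability beyond the
explicit channels above. Passing pipeline tests therefore demonstrate
correctness of the *procedures*, not empirical claims about real farms.

## Problem sizes used in validation

The test suite validates the DEA LP against the brute-force solver on
100 random instances of up to 10 farms × 3 dimensions; Tobit recovery on
200 replicates of n = 500; test size/power by seeded simulation (400 to
1000 replicates depending on the statistic); and the pipeline
null-structure property over 100 seeded 72-farm populations. These sizes
give stable Monte-Carlo estimates for the asserted bands while keeping
the default test run fast.

## Known limitations

- DEA with five inputs at n = 72 puts roughly half the farms on the
  frontier (dimensionality, not a bug); published studies with the same
  design report fewer frontier farms than a fresh simulation typically
  yields. Bootstrap or dimension-reduction remedies are out of scope.
- The Tobit stage treats DEA scores as data; the two-stage sampling
  problem (scores are estimates, correlated across farms) is documented
  but not corrected (no Simar–Wilson bootstrap).
- Shapiro–Wilk and the χ² reference for H are approximations; the exact
  Kruskal–Wallis path is limited to pooled N ≤ 10 by design.
- AHP group aggregation reports only CR; no consensus diagnostics.
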