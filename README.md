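# farmsustain

Analytics for the efficiency–sustainability question in smallholder
livestock systems: does a farm that converts inputs to output efficiently
also score well on economic, social, and environmental sustainability?
The package is aimed at agricultural economists analysing farm survey
data (the motivating system is water-buffalo dairying, but nothing is
species-specific), and it ships a synthetic survey generator with known
ground truth so the full pipeline can be exercised and validated without
access to confidential microdata.

## What it computes

**Technical efficiency (DEA).** Each farm's radial input-oriented
efficiency under variable returns to scale, from the envelopment LP

```
min θ   s.t.  Σ_j λ_j x_ij ≤ θ x_io  (each input i)
              Σ_j λ_j y_j  ≥ y_o
              Σ_j λ_j = 1,  λ ≥ 0
```

with one output (gross production value, $/farm) and five inputs
(roughage kg, concentrate kg, herd size in livestock units, labor hours,
veterinary cost). θ ∈ (0,1]; θ = 1 is frontier-efficient. Farms are
grouped as inefficient (θ ≤ 0.50), moderately efficient (0.50 < θ < 0.75)
and efficient (θ ≥ 0.75). An independent exhaustive vertex-enumeration
solver (`farmsustain.dea_reference`) cross-checks the LP on small
instances.

**Composite sustainability index (CSI).** Indicators (binary, Likert 1–5,
frequency 1–6, continuous; default schema of 13 economic + 18 social +
12 environmental items) are min–max normalised with direction
(`l = (x−min)/(max−min)` or its complement), averaged per dimension into
ESI / SSI / EnSI, and combined as

```
CSI = w₁·ESI + w₂·EnSI + w₃·SSI
```

with dimension weights from the analytic hierarchy process: geometric-mean
aggregation of expert pairwise matrices, row-average (or eigenvector)
priority weights, and consistency ratio CR = CI/RI with
CI = (λmax − n)/(n − 1), acceptable below 0.10. Scores classify as
Unacceptable/Borderline/Average/Good/Best at 0.20/0.40/0.60/0.80.

**Group comparison.** Shapiro–Wilk normality screening and the
Kruskal–Wallis H test (midranks, tie correction, optional exact
permutation p for pooled N ≤ 10) of each dimension and the CSI across the
three efficiency groups.

**Determinants of efficiency (two-limit Tobit).** Maximum-likelihood
censored regression of θ ∈ [0,1] on farm covariates, with
observed-information standard errors, likelihood-ratio joint test,
average marginal effects on the observed score
(AME_j = β_j · mean Φ-gap — one common shrinkage scalar for all slopes),
VIF multicollinearity and White heteroskedasticity diagnostics.

Also included: stratified sample-size determination with Neyman
allocation, and Cronbach's alpha scale reliability.

## Worked example

```
farmsustain run-all --seed 20240201 --out run
farmsustain report run
```

simulates a 72-farm survey, scores it, and writes `run/report.md`:

```
## Technical efficiency
mean 0.813, min 0.114, max 1.000, SD 0.250, frontier farms 36
group sizes: {'efficient': 49, 'inefficient': 12, 'moderately_efficient': 11}

## Sustainability
dimension means: composite 0.553, economic 0.532, environmental 0.586, social 0.552
dimension weights (default): 0.490, 0.310, 0.200

## Efficiency-group comparison (Kruskal-Wallis)
- composite: H = 3.999, df = 2, p = 0.135
- economic: H = 5.249, df = 2, p = 0.072
- environmental: H = 4.176, df = 2, p = 0.124
- social: H = 2.646, df = 2, p = 0.266

## Tobit determinants of efficiency
right-censored 36 of 72, logL -25.126, LR chi2(7) = 42.59 (p = 4.009e-07)

## Efficiency vs sustainability
descriptive OLS R^2 = 0.050 (scatter: efficiency_vs_csi.png)
```

Reading: half the simulated farms sit on the DEA frontier (36 of 72 —
small-sample DEA with five inputs is generous); none of the four
Kruskal–Wallis tests rejects at 5%, so efficiency groups do not differ
systematically in sustainability — the efficiency–sustainability
disconnect the generator's default (independent indicators) encodes —
while the Tobit stage recovers a strongly significant joint effect of the
covariates that truly drive latent efficiency (LR χ²(7) = 42.59). The
near-zero scatter R² (0.05) makes the same disconnect visible per farm.

Every stage is also importable directly; see `farmsustain.dea`,
`farmsustain.ahp`, `farmsustain.tobit`, etc., and
`farmsustain --help` for the remaining subcommands
(`simulate`, `sample-size`, `dea`, `index`, `ahp`, `compare`, `tobit`).

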