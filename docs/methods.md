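# Methods

## The problem

Multivariable Mendelian randomisation (MVMR) estimates the direct causal
effects θ₁…θ_K of K exposures on an outcome from per-variant GWAS summary
statistics, using genetic variants as instruments. The working model for
variant *i* is

    β̂_y,i = θ₁ β̂_x1,i + … + θ_K β̂_xK,i + α_i,    ε_i ~ N(0, σ_y,i²),

where α_i is a horizontal-pleiotropy term. Regression-type estimators
(IVW, MR-Egger, weighted median) need all, balanced, or a majority of
variants to be valid. Under the plurality-valid (ZEMPA) assumption — the
largest cluster of variant-specific causal-estimate estimands sits at the
true effect — univariable modal estimators exist, but there is no modal
*regression*. This package implements the residual framework that fills
that gap, together with the comparator estimators and the Monte-Carlo
study used to validate it.

## The residual framework

For a target exposure (say exposure 1), both the variant-outcome
associations β̂_y and the variant-target associations β̂_x1 are regressed,
without an intercept, on the remaining exposures' associations using
weighted least squares with weights 1/σ_y,i². The residual pair
(β̃_y, β̃_x1) behaves like a univariable instrument set, and its Wald
ratios β̃_y,i/β̃_x1,i are fed to a univariable plurality-valid estimator:

* **multivariable-MBE** — the weighted mode-based estimator;
* **multivariable-CM** — the contamination mixture.

Both residual regressions use the *same* outcome-variance weights. This is
a deliberate design choice: with common weights, intercept-free IVW on the
residual pair reproduces the direct multivariable-IVW coefficient exactly
(the Frisch–Waugh–Lovell identity), which is the structural property the
framework's validity argument rests on. The identity is enforced to 1e-8
in the test suite. With K > 2 exposures all non-target exposures are
removed jointly in one multivariable WLS; iterating pairwise is not
equivalent and is not done.

The residual Wald-ratio standard error is the usual first-order
approximation SE_i = σ_y,i / |β̃_x1,i|: exposure associations are treated
as precisely measured, so residualisation leaves the outcome standard
error untouched. Variants with |β̃_x1,i| below a floor (default 1e-10) are
dropped with a warning, since their ratio is undefined.

A consequence worth being explicit about: β̃_x1 is centred near zero by
construction, so some residual denominators are small and the ratio set is
heavy-tailed — far more so than a curated univariable instrument set.
Several numerical choices below exist specifically to make the modal
estimators well-behaved under those tails.

## Estimators

**IVW / MR-Egger.** Intercept-free (IVW) or with-intercept (Egger)
weighted least squares, weights 1/σ_y,i², through `statsmodels` WLS.
Standard errors use multiplicative overdispersion with the
residual-variance factor floored at 1 — random-effects when the data are
heterogeneous, fixed-effect otherwise, the standard summary-MR convention.
Egger first orients every variant so its association with exposure 1 is
positive (the whole row, outcome included, flips sign), because the Egger
intercept is not orientation-invariant.

**Weighted median.** Intercept-free quantile regression (τ = 0.5) of the
outcome associations on the exposure associations with weights 1/σ_y,i².
The check function is positively homogeneous, so multiplying each row by
its weight turns `statsmodels` QuantReg into the exact weighted-L1 fit.
The standard error is a parametric bootstrap (default 1000 resamples,
seeded): β̂_y* ~ N(β̂_y, σ_y²) and β̂_x* ~ N(β̂_x, SE_x²), SD of the
refitted coefficients. The quantile-regression sandwich SE is unstable at
a couple of hundred variants, which is why the bootstrap is the default.

**Mode-based estimator.** The weighted kernel density of the ratios uses
normal kernels, weights (1/SE_i²)/Σ(1/SE_j²) (a `weighted=False` flag
gives the simple mode), and the modified Silverman bandwidth
h = φ · 0.9 · min(s, IQR/1.349) · n^(−1/5), default φ = 1. The mode is the
argmax of that density: the density is evaluated at the observed ratios
themselves and then refined on shrinking local grids to ~h/1000. A fixed
global evaluation grid — the convention of older implementations — is
*wrong* under heavy ratio tails: one ratio outlier of 10⁴ makes a 512-point
grid step tens of bandwidths wide, the cluster falls between grid points,
and the returned "mode" is an artefact. The standard error is a parametric
bootstrap (θ̂_i* ~ N(θ̂_i, SE_i²), bandwidth recomputed per resample,
default 1000 resamples, seeded) with a symmetric normal CI. If all ratios
are identical the bandwidth is zero and the common value is returned.

**Contamination mixture.** Each ratio is modelled as either valid,
N(θ, SE_i²), or invalid, N(0, SE_i² + ψ²); the profile log-likelihood at
each candidate θ takes the per-variant maximum over the two classes, and
the 95% confidence set is {θ : 2(ℓ_max − ℓ(θ)) ≤ 3.84}, reported as a
union of disjoint intervals (ties in the argmax resolve to the smallest
θ). Defaults:

* ψ = 1.5 × SD of the ratio estimates — the convention of the canonical
  contamination-mixture implementation. Under the residual pipeline's
  heavy tails this SD is outlier-dominated and ψ is large, making the
  invalid component a nearly flat slab; that is the regime in which the
  method's reported precision arises, and it is what users of the
  reference implementation get. If the ratios are numerically identical
  (SD ≈ 0) ψ falls back to 1. ψ is configurable and surfaced in the
  diagnostics; sensitivity can be probed by passing multiples.
* grid step 0.01 over a span built from precision-weighted ratio
  quantiles, doubled automatically whenever the likelihood argmax or the
  confidence set touches a boundary. A span based on mean ± c·max(SE)
  would be destroyed by a single near-zero residual denominator (step ~1
  on a quantity of width 0.09); the weighted-quantile span is immune to
  that. A boundary argmax on an explicitly supplied span is an error, not
  silently accepted.

The CM point estimate and confidence-set endpoints are resolved to the
grid step; tests treat 0.01 (one step) as the modal estimators'
resolution. For disjoint confidence sets, "CI width" is the sum of the
interval widths and the hull width is kept as a diagnostic; "includes
zero" means any interval contains it.

## The simulation study

The data-generating mechanism simulates, per replicate: 200 independent
SNPs with genotype Binomial(1, 0.4) + Binomial(1, 0.4); per-SNP exposure
effects b ~ N(0.05, 0.02²); a standard-normal confounder entering the two
exposures with coefficients 0.3 and 0.4 and the outcome with coefficient
1; unit-variance trait noise; pleiotropic direct effects
p ~ N(BETA, 0.1²) on the first 0/20/40/80 SNPs, with BETA = 0 (balanced)
or −0.03 (directional); and causal effects (0.3, 0.4) or (0, 0). Summary
statistics come from per-SNP OLS (with intercept) in three mutually
disjoint samples of 200,000 individuals — one GWAS per trait, no sample
overlap.

Two structural decisions:

* The per-SNP effect vectors of the two exposures are drawn
  *independently*. A shared vector would make the exposures genetically
  collinear (conditional F ≈ 1–2), contradicting the strong-instrument
  regime the study design clearly intends; independent draws give
  conditional F ≈ 55 and marginal F ≈ 200 per exposure.
* The pleiotropic SNPs are a fixed prefix of the SNP list, which is
  deterministic and distributionally equivalent under i.i.d. draws.

Implementation: genotypes are generated by thresholding 16-bit uniforms
(category probabilities exact to 2⁻¹⁶, an error below 2×10⁻⁵ — orders of
magnitude under allele-frequency sampling noise at n = 200,000), and
within a sample only one trait is regressed, so confounder and noise are
drawn as a single normal with the combined variance. Per-sample
individual-level data live in reused buffers; memory does not grow with
the replicate count. One replicate (three GWAS of 200,000 × 200) takes
about one second on one CPU core.

Instrument strength is reported two ways: `conditional_f` implements the
summary-data conditional F (intercept-free WLS of the target exposure's
associations on the others', weights 1/SE², F = Σ w δ²/(n−K)), and
`marginal_f` the mean per-variant (β̂/SE)². The conditional statistic is
the one that measures what "conditional" means; the marginal one is what
is conventionally quoted for instrument lists, and is the statistic whose
simulated value (~200 per exposure) matches the instrument-strength level
this design is calibrated to.

Performance measures per scenario × method × exposure: mean bias
(estimate minus truth), sample SD of estimates (n−1), mean 95% CI width,
% of replicates whose CI includes 0, and coverage of the truth. In null
scenarios includes-0 and coverage coincide by construction and the test
suite asserts this exactly.

### Study sizes and what the desk-scale run shows

The package defaults run scenarios at a few hundred replicates rather than
thousands; `run_study` exposes replicate count, per-GWAS sample size and
estimator options, so a full-fidelity run is one call. The reproduction
script (`scripts/acceptance.py`) uses 150 replicates for the causal-bias
cells, 220 for the null coverage cells, and 100 at n = 50,000 per GWAS for
the additional null settings probed only for the mode-based estimator's
coverage bound (a conservative-coverage bound is insensitive to the
summary-statistic precision, which only widens the already-wide CIs).
Monte-Carlo uncertainty at those sizes is the dominant error term for the
bias cells and is quoted alongside each tolerance in the tests.

### Known divergences from the published comparison values

Verified analytically and numerically, and deliberately *not* patched over:

* **No-pleiotropy CI widths.** Under the mechanism above, the outcome
  variance is 2.94 (causal) and 2.0 (null), which gives IVW widths of
  ~0.060/0.046 and CM widths of ~0.048/0.046 in the no-pleiotropy cells.
  The published no-pleiotropy widths (0.096/0.032 IVW, 0.093/0.033 CM)
  back out outcome variances of ~8.2 (causal) and ~1.0 (null) — mutually
  inconsistent with the printed mechanism, while every pleiotropy-column
  width (dominated by the overdispersion term, hence variance-insensitive)
  matches this implementation to ~2%. This package follows the printed
  mechanism, so its no-pleiotropy widths are the smaller, internally
  consistent ones.
* **Mode-based-estimator dispersion.** With the mode located correctly
  (see above), multivariable-MBE is far more stable here than previously
  reported (null CI widths ~0.1 rather than 0.3–5, and correspondingly
  lower null includes-0 rates under directional pleiotropy). The
  previously reported instability is reproduced by this package only if
  the mode search is made deliberately coarse, and then it *over*-explodes;
  we keep the correct search.

## Limitations

* Inputs are assumed pre-harmonised; no allele alignment, LD clumping or
  data-source queries are performed.
* The simulated SNPs are independent (no LD), samples are non-overlapping,
  traits are linear-Gaussian with homogeneous effects, and only two
  exposures are simulated; the estimators themselves accept any K ≥ 1.
* The Wald-ratio SE ignores exposure-association error (NOME-style
  bandwidth or SE corrections are out of scope), so weak-instrument
  settings will under-state ratio uncertainty.
* The contamination mixture's estimate can depend on ψ; the default is a
  convention, not an optimum, and directional pleiotropy biases the
  estimator because the invalid component is centred at zero by
  assumption.
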