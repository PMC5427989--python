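# Methods notes

This note records the modelling assumptions, defaults and numerical choices
behind the package, and what the synthetic-data tests do and do not
establish about real data.

## Synthetic cohort generator

**Methylation model.** Each bin j is generated as
`value = mu_j + sd_j * (a A + c C + u U + e eps)`, where A is an
additive-genetic standard-normal component (correlation 1 within MZ pairs,
0.5 within DZ pairs), C is shared within pair, U is a persistent unique
component and eps is per-visit noise. For longitudinally stable bins the
variance shares are `a^2 = bin_h2`, `c^2 = bin_c2`,
`u^2 = test_retest_r − bin_h2 − bin_c2`, `e^2 = 1 − test_retest_r`; the
persistent part (A, C, U) carries over to the second visit, so the expected
test–retest correlation is exactly `test_retest_r`. This forces the
constraint `test_retest_r ≥ bin_h2 + bin_c2` for stable bins, enforced at
configuration time: genetic and shared-environment components cannot decay
between visits in this model. Unstable bins are pure per-visit noise. All
three share parameters accept per-bin arrays, which is how cohorts with
heritability rising across stability classes are built in tests.

**Value scale.** Bin means are uniform on [5, 10] (FPKM-like) with
`sd = mu/5`. The fixed mean/SD ratio is deliberate: zero-inflated entries
(exact zeros mimicking bins without MeDIP coverage) then sit exactly 5 SD
below the mean for every bin, so a low default zero-inflation rate (0.01)
attenuates correlations uniformly and mildly rather than destroying
high-mean bins. Zeros are injected per entry (i.i.d. Bernoulli) after the
Gaussian draw, and zeros are *retained* in all correlation estimators — the
QC filter, not the estimator, is the defence against zero inflation, which
is the pipeline's own logic. Gaussian-with-zero-inflation is a stand-in for
the true (right-skewed, FPKM-like) distribution of bin methylation, whose
form the pipeline does not depend on; no claim of distributional
equivalence is made. Negative values (possible only ~5 SD out) are clipped
to zero.

**Inter-bin correlation is not simulated.** Real overlapping 500 bp bins at
250 bp step are strongly locally correlated; generated bins are
independent. Consequently the effective number of tests on simulated data
is close to the bin count, and the Li–Ji machinery is instead validated
against dense-eigendecomposition oracles on matrices with injected
correlation. Passing tests therefore demonstrate correctness of the
counting rule, not the magnitude of the reduction on real data.

**Disease model.** Liability is
`L = beta_age (age − mean) + beta_bmi (BMI − mean) + sum_j gamma_j z_j + A_L + E_L`
with `Var(A_L) = liability_h2`, `Var(E_L) = 1 − liability_h2 − sum gamma^2`,
and `z_j` the empirically standardized methylation of designated causal
bins. Status is `L > tau` with `tau` set from the target prevalence on the
standardized-liability scale using the theoretical variance of L, so
empirical prevalence is unbiased. Defaults: `liability_h2 = 0.636`,
prevalence 0.15 (a mid-range population CWP figure; the source cohort's
exact rate is not published), `beta_age = 0.01`/year and
`beta_bmi = 0.02`/unit (affected individuals older and heavier, each
covariate contributing well under 5% of liability variance), and four
causal bins with equal per-SD effects summing to `gamma^2 = 0.06`.

**Cohort structure.** 565 MZ + 244 DZ pairs + 90 singletons = 1708 women by
default. Twins share age (uniform 17–82); BMI is N(25.6, 4.5²) per
individual, uncorrelated within pair. Singletons are generated as full
pairs whose cotwin's status is kept (`cotwin_cwp` column) but whose
methylation is dropped; their latent genetic correlation with the phantom
cotwin alternates MZ-like/DZ-like since the registry's singletons are real
twins of unrecorded retained zygosity. Smoking is known for 76.5% of
individuals (45% ever-smokers among those, 489 ex : 99 current), WBC
subtype counts for 25.8% — matching the published availability; neither is
linked to liability by default, so smoking/WBC terms are null covariates in
the models. A fraction (default 0.17, ≈ 292 usable individuals) receives a
second visit with gap ~ N(7, 1.2²) years truncated at 3.

One `numpy` Generator seeded from the integer config seed drives
everything; identical configs give byte-identical outputs.

## Stability screen and twin correlations

Test–retest and twin correlations are plain Pearson correlations with
p-values from the exact t transform `t = r sqrt(n−2)/sqrt(1−r²)`. An lsBIN
additionally requires `r > 0`: negative "stability" is meaningless, and the
observed stability correlations of such screens are all positive. Because
the pipeline's threshold contract ("lsBIN p = 1.0 keeps every bin") needs a
pure-p rule, the positivity requirement is a config switch
(`lsbin_require_positive`, default on). Per-bin n is tracked
pairwise-complete, since real matrices have missingness. Twin-1/twin-2
assignment within a pair is randomized once per run from the config seed;
an intraclass-correlation estimator would avoid the randomization but is
not what a Pearson-based screen uses, so it is out of scope. The MZ/DZ
correlation ratio is only formed where `R_DZ ≥ 0.05` (reported exclusion
count) to avoid division blow-ups.

## Association testing

Discovery uses the paired t test on (affected − unaffected) differences
within CWP-discordant MZ pairs — any within-pair-constant effect (genotype,
shared environment, age) cancels exactly, which is tested as an invariance.
If more discordant pairs exist than requested (default 50), a seeded
uniform draw fixes the discovery set. Replication is a Welch (unequal
variance) two-sample t test on the disjoint remaining sample; the plain "t
test" of the original design is underspecified and Welch is the safe
default. Methylation is residualized on age and age² first (the
methylation–age relationship is nonlinear). Twin dependence within the
replication sample is deliberately not modelled, matching the design being
reproduced; its main consequence is mild miscalibration of replication
p-values on real data, which the null-calibration test sidesteps by
simulating exchangeable individuals (no twin methylation correlation) —
that test certifies the gate arithmetic (0.05 × 0.05 × ½), not robustness
to clustering.

Fisher combination `chi2 = −2(ln p_disc + ln p_rep)` on 4 df is gated on
both p-values < 0.05 *and* sign concordance of the t statistics (positive =
hypermethylated in affected, both stages). Bins failing the gate keep their
component statistics; both gated and ungated pass counts are reported,
since the two published counts of combined signals are mutually
inconsistent and the gated (direction-concordant) rule is the one the
results section describes.

## Multiple testing

The effective number of tests follows Li & Ji: each eigenvalue lambda of
the bin correlation matrix contributes `1{lambda ≥ 1} + (lambda −
floor(lambda))`. Eigenvalues are clamped at zero and snapped to integers
within 1e-9 before flooring — an exactly rank-1 block otherwise picks up a
spurious fractional part of ~1 from floating-point dust. At epigenome scale
a dense eigendecomposition is infeasible, so bins are processed in
contiguous per-chromosome blocks (default 5,000 bins) and block
contributions summed; blocking ignores inter-block correlation and thus
never undercounts relative to the dense estimate. The published "modified"
version of the counting rule is not recoverable from its description; the
canonical rule with blockwise evaluation is used, and the block size is
exposed. BY FDR is delegated to statsmodels (`fdr_by`) and cross-checked
against a hand-computed step-up in tests.

## Covariate models

Logistic fits are standard maximum likelihood (statsmodels Logit, Newton,
tol 1e-10, 100 iterations), cross-checked against a brute-force
Newton–Raphson oracle in tests. The twin design enters only through the
cotwin-affection-status covariate, which absorbs familial dependence in the
mean; no cluster-robust variance is applied by default since the original
analysis describes none. Methylation is standardized per model
(coefficients per SD; `standardize=False` gives per-unit). Smoking is coded
ever/never; complete-case handling per model with the n actually used
reported (smoking and WBC counts exist only for subsets). Perfect
separation surfaces as an error or a `converged=False` flag, never silent
output. Eta² is `SS_between/SS_total` from one-way ANOVA, affine-invariant.

## Liability decomposition

An AE model (no shared-environment C) is fitted because the decomposition
being reproduced reports only additive-genetic, epigenetic and residual
components; with MZ/DZ pairs only, A, C and E are not jointly identifiable
alongside per-bin effects anyway. Methylation enters as a *fixed* covariate
of liability — it is not itself decomposed — so EGF_j = gamma_j² and the
identity AGF + sum EGF + RES = 1 holds by construction. Pair likelihoods
are bivariate-normal orthant probabilities from a vectorized
Drezner–Wesolowsky/Genz quadrature (20-point Gauss–Legendre on the arcsin
transform for |rho| < 0.925, tail expansion otherwise; abs. error ~1e-14,
verified against `scipy.stats.multivariate_normal` on a grid). Singleton
contributions are univariate tails; their known cotwin status is available
as a mean-model covariate but does not enter the correlation structure, the
conservative reading of an ambiguous design.

Optimization is L-BFGS-B with bounds (`a2 ∈ [0, 1)`, `|gamma| ≤ 0.95`,
`tau ∈ [−6, 6]`) from three fixed starts `a2 ∈ {0.1, 0.4, 0.7}`; best
log-likelihood wins, ties to the smallest a2. A penalty guards the
`a2 + sum gamma² < 1` region. Standard errors come from the numerical
(central-difference) Hessian of the negative log-likelihood; at a boundary
the fit is flagged and the SE may be undefined. The LRT for V_AD > 0 uses
the boundary mixture ½χ²₀ + ½χ²₁, whose nominal calibration under the null
is verified by simulation. Component SEs in the variance report use the
delta method on the full parameter covariance.

## Problem sizes and tolerances

Default simulated problem sizes (5,000 bins × 1,708 individuals for
pipeline runs; 10⁴–10⁵ bins for calibration nulls; 100 replicates at the
published twin counts for heritability recovery) keep any single check
within seconds to a couple of minutes on one CPU while leaving Monte-Carlo
error well inside the asserted bands (binomial 3–4 SE for rates, 2
model-based SE for estimates). Oracle-equivalence checks are exact to
1e-9–1e-12.

## Known limitations

- No inter-bin (genomic-neighbourhood) correlation, batch effects, MeDIP
  enrichment bias or sequencing-depth variation in the generator.
- Gaussian-with-zero-inflation value model; real FPKM distributions are
  right-skewed.
- Smoking and WBC counts are simulated as null covariates; tests involving
  them check plumbing (complete-case n, term presence), not biology.
- The replication t test ignores twin clustering (by design fidelity).
- Liability model is AE only; a C component is a straightforward extension
  but is not exposed as a default.
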