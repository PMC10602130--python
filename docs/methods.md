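# Methods

## The model

`feiscan` analyses the presence of FVIII inhibitors at study entry
(baseline status, a 0/1 outcome) in cohorts of hemophilia-A patients. Two
features of such cohorts violate the independence assumptions of ordinary
association tests: patients recruited through hemophilia treatment centres
are often related (brothers, uncle–nephew pairs, grandfather–grandson
pairs), and patients share identical causative F8 lesions — nearly half of
severe cases carry the same recurrent intron-22 inversion — whose effect on
inhibitor risk is a nuisance signal for any scan of non-F8 loci.

Both are modeled as structured random effects in a linear mixed model on
the observed 0/1 scale:

    y = a + X b + g + m + e
    Var(y) = sigma2_g * K + sigma2_m * M + sigma2_e * I

* `K` — empirical kinship / genomic relationship matrix, the GCTA-style
  per-marker-standardized estimator
  `K_ij = (1/L) sum_l (g_il - 2 p_l)(g_jl - 2 p_l) / (2 p_l (1 - p_l))`,
  with missing dosages mean-imputed at `2 p_l`. Centering makes the matrix
  invariant to which allele is counted. A pedigree-based numerator
  relationship matrix (recursive tabular method) is available as ground
  truth for simulations; the two lie on the same relatedness continuum and
  the empirical matrix converges to the pedigree one as markers accumulate
  (within a homogeneous population — under ancestry stratification the
  empirical matrix additionally captures between-group structure).
* `M` — shared-causative-mutation indicator: `M_ij = 1` iff subjects carry
  the same lesion. Granularity "allele" (identical lesion, the default —
  recurrent inversions are genuinely identical events, while missense
  substitutions are allelically diverse) or "category" (same lesion class).
  Subjects whose lesion was not identified never share: their lesions are
  unknown and almost surely distinct, so they form singleton blocks under
  either granularity. `M` is a disjoint union of blocks of ones, hence PSD
  with eigenvalues equal to the block sizes.

Variance components are estimated by REML (L-BFGS-B with analytic
gradients, non-negativity box bounds, deterministic multi-start from spread
variance splits, `ftol 1e-8`); fixed effects by GLS at the optimum.
Collinear component sets (e.g. K = M = I) are rejected up front by a rank
check on the vectorized component matrices. Component significance uses the
likelihood-ratio statistic referred to the 50:50 mixture of chi-square(0)
and chi-square(1), the standard correction when the null value lies on the
boundary of the parameter space.

Fitting a binary trait by Gaussian REML is deliberate: the observed-scale
linear mixed model is well defined, fast, and supports the same variance
partition as threshold-model machinery; results can be converted to the
liability scale afterwards (below). Heritabilities are variance shares:
`h2_g = sigma2_g / sigma2_total`, `h2_m = sigma2_m / sigma2_total`, and the
mutation share of total genetic signal is `h2_m / (h2_m + h2_g)` — with the
component pair (0.08, 0.47) this is 14.5%, i.e. roughly 15% at whole-percent
rounding.

## Observed scale vs liability scale

`observed_to_liability` implements the classical threshold-model factor
`h2_liab = h2_obs * P(1-P) / z^2` (`P` prevalence, `z` the standard-normal
density at the threshold); at `P = 0.5` the multiplier is `pi/2`. This
first-order factor comes from linearizing the covariance of two threshold
indicators, `cov = z^2 rho + z^2 t^2 rho^2 / 2 + ...`; at sibling-level
liability correlations (~0.3) the ignored terms reach ~13%. Where that
matters — the parameter-recovery experiment — the package instead inverts
the exact bivariate-normal relation per pair type (`K_ij`, `M_ij`, and the
race-specific effective thresholds), weighted by pair counts
(`experiments.liability_components_from_observed`). The inversion is purely
model-derived and reduces to the `z^2` division for small correlations.

## Gene-centric association scan

Each polymorphic, non-collinear SNP is tested as a fixed effect. Default
mode `wald_fixed_V` fixes `V` at the null-model REML estimates and tests
the GLS coefficient by Wald z — the standard fast approximation; mode
`full_lrt` re-estimates the variance components by ML with and without the
SNP and refers twice the log-likelihood difference to chi-square(1). The
two agree closely for moderate signals (checked to 20% relative on |z| < 4).
The counted allele is re-oriented to the minor allele of the combined
sample and per-race frequencies are reported, since ancestry-restricted
variants (common in one group, rare in the other) are a feature of immune
loci panels.

Multiple testing is Bonferroni on the -log10 scale: chip-wide
`-log10(alpha / n_all)` and per-gene `-log10(alpha / n_gene)` over each
gene's assigned QC-passed SNPs (for a 137,776-SNP panel at alpha 0.05 the
chip-wide threshold is 6.44; genes with 287, 281 and 362 SNPs get 3.76,
3.75 and 3.86). Reported thresholds are rounded half-up to 2 decimals; a
SNP exactly on a threshold is not significant (strict inequality).

## Joint models

The top SNPs plus race enter a multivariate logistic model (statsmodels
IRLS); odds ratios carry Wald 95% CIs. Race-by-genotype interplay is probed
by exhaustive BIC comparison over all subsets of race x SNP product terms
(main effects always retained; BIC = -2 loglik + k ln n as a Bayes-factor
approximation); models with separation are excluded with a warning.
Fisher's method combines independent chi-square p-values
(`-2 sum ln p ~ chi2_2k`). `cohort_summary` reproduces the descriptive
table: counts and 1-decimal percentages per race for inhibitor status and
each mutation category plus a 2x2 Pearson chi-square (no continuity
correction) for status by race.

## The synthetic cohort generator

No public genotype data exist for this design, so the generator emulates
the study conditions and every pipeline stage runs end to end on it.
Defaults (all overridable) are the cohort's published structure:

| parameter | default | source/rationale |
|---|---|---|
| n_subjects | 450 | cohort size |
| race mix | 206 BA / 244 WE | cohort composition |
| family mix | 21% sib-pair + 10% avuncular subjects | ~31% of subjects with an in-sample relative, the figure reported for comparable HTC-recruited cohorts |
| mutation categories | I22-inv 0.416, missense 0.216, unidentified 0.098, rest uniform | published spectrum; unlisted categories share the residual mass uniformly (calibration choice, exact per-category counts are not printed) |
| distinct missense alleles | 61 | published count |
| variance components | sigma2_g 0.47, sigma2_m 0.08, sigma2_e 0.45 (liability) | published heritabilities; residual completes unit variance |
| race effect | 0.21 liability shift for BA | reproduces per-race baseline rates 21.5%/15.9% at the combined prevalence |
| prevalence | 0.185 baseline, 0.305 historical | combined from the published per-race rates |
| markers | 10 genes x 30 SNPs, MAF U(0.05, 0.5), 10% ancestry-restricted (rare < 0.01 in one group) | a desk-scale stand-in for an immune-loci chip |

Pedigrees are drawn as family units (singleton; sib pair; uncle–nephew via
an unsampled connecting parent), each family assigned one ancestry.
Genotypes are gene-dropped: founders Binomial(2, p_race), children inherit
one allele per parent with transmission probability dosage/2. Mutations are
assigned per family (relatives share the familial lesion); both inversion
types are recurrent shared alleles, missense lesions draw from the 61-allele
pool, other categories get family-unique labels, unidentified lesions get
per-subject unique tokens. The phenotype thresholds a liability
`a + X beta + g + m + e` with `g ~ N(0, sigma2_g K_ped)` by Cholesky and
the mutation effect drawn once per distinct allele (so `cov(m) =
sigma2_m M` exactly); the threshold is the upper-prevalence quantile of the
theoretical marginal mixture over race groups, so prevalence is matched in
expectation. Historical status uses the lower historical-prevalence
threshold of the same liability, making baseline-positive a subset of
historical-positive.

Not emulated: linkage disequilibrium, admixture/continuous ancestry,
genotyping error, X-linked marker transmission (the F8 lesion is X-linked
but marker genotypes are simulated autosomal-diploid, as on an autosomal
chip), longitudinal inhibitor histories. Passing tests therefore show the
estimators handle relatedness, allele-sharing structure and
race-stratified frequencies correctly — not that they are robust to LD or
ancestry admixture.

## The parameter-recovery experiment

`experiments.heritability_recovery` asks whether the pipeline recovers the
generating heritabilities at the study conditions. This is deliberately a
hard setting: one 450-subject binary cohort with ~31% relatedness and a
single mutation allele shared by 42% of subjects carries little information
about either component. Per-cohort REML estimates are enormously dispersed
(liability-scale SD ~0.6 for h2_g across replicates, ~35% of fits on the
zero boundary), and the arithmetic mean of non-negativity-constrained
estimates is therefore inflated — the mean of a truncated noisy estimator
exceeds its centre (measured +0.07 on h2_g and +0.09 on h2_m over 300
replicates, matching E[max(N(theta, sd), 0)] closely). The experiment
instead fits one pooled restricted likelihood over all replicate cohorts
(block-diagonal covariance, shared variance parameters, per-cohort fixed
effects; `varcomp.fit_vc_pooled`), which accumulates information across
replicates and is centred on the generating values, then converts the
pooled observed-scale components to the liability scale by the exact
threshold inversion described above. Per-cohort estimates remain available
(`per_cohort=True`) as dispersion diagnostics. Default problem size: 150
replicate cohorts in the test suite, 600 in the acceptance script (several
minutes on one core); at 600 cohorts the pooled estimates carry a sampling
SE of about 0.03 (h2_g) and well under 0.01 (h2_m).

## Numerical choices

* REML optimizer: L-BFGS-B, analytic gradients, bounds [0, 10 * var(y)]
  per component, 5 deterministic starts (pooled fits use 1; the pooled
  surface is information-rich), `ftol 1e-8`.
* PSD validation: Cholesky of the matrix jittered by `1e-8 * max(diag)`
  (O(n^3/3); a full eigendecomposition is only computed to format error
  messages).
* Degenerate inputs: monomorphic marker panels, constant phenotypes,
  collinear components, zero-variance simulations and empty cohorts raise
  immediately with named errors; non-convergence flags the fit rather than
  failing silently.
* Tie rule: threshold equality in significance flags counts as not
  significant; reported thresholds round half-up to 2 decimals.
* Missing dosages: out-of-band sentinel (-1), mean-imputed only inside the
  GRM and the scan, never persisted as 0.

## Known limitations

* The observed-scale Gaussian REML is a quasi-likelihood for a binary
  trait; single-cohort component estimates at n=450 are honest but very
  noisy, and their constrained means across replicates are biased upward
  (see above). Conclusions about single real cohorts of this size should
  lean on the LRT, not on point heritabilities.
* The exact threshold inversion assumes the generator's liability model
  (probit link, race-specific thresholds); for real data with unknown
  ascertainment it would need the sampling design.
* Wald CIs (not profile likelihood) for odds ratios; no Firth correction,
  so near-separated joint models are rejected rather than penalized.
* `full_lrt` scan mode refits variance components per SNP and is O(n^3)
  per marker — practical for candidate panels, not chip-wide scans.
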