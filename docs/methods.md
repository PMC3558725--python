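# Methods

## Disease model and cohort simulation

Cohorts are simulated from a prospective logistic model and then sampled
retrospectively. Each population subject receives

* a genotype G at the causal locus, drawn under Hardy–Weinberg
  equilibrium with minor-allele frequency q: P(G = 0,1,2) =
  ((1−q)², 2q(1−q), q²);
* a continuous exposure E* (heme iron, mg/day) from a normal
  distribution truncated at zero (the motivating data report only means
  and SDs; defaults 1.29 ± 0.43 mg/day, the HPFS-like cohort);
* BMI and age from untruncated normals (25.05 ± 3.46 kg/m²,
  54.19 ± 8.36 y by default);
* k standard-normal "eigenvector" covariates. These are pure noise:
  population structure is deliberately not simulated, the covariates
  exist so the fitted models have the same dimension as the real
  analysis.

Disease status follows

    logit P(Y=1) = β₀ + log(OR_g)·g + log(OR_e)·e + log(OR_gxe)·g·e
                   + log(OR_bmi)·(BMI−μ_bmi) + log(OR_age)·(age−μ_age)

where g is the allele count (log-additive) or a carrier indicator
(dominant — the risk model uses the indicator but stored genotypes stay
0/1/2), and e is either the mean-centered continuous exposure or a 0/1
indicator of the top population tertile. The tertile boundary is the
theoretical 2/3 quantile of the truncated-normal exposure distribution,
computed before any sampling, so the indicator refers to the source
population rather than to the realized case-enriched sample. BMI and age
enter centered so that β₀ keeps its interpretation as the baseline
log-odds; the default β₀ = −2.5 gives ≈ 8% population prevalence,
matching the U.S. adult T2D prevalence. Because a case-control study
oversamples cases, exact quotas are filled by batch rejection sampling
from this population model; an unattainable quota (pathological β₀ or
effect sizes) aborts with a diagnostic after a configurable attempt cap.

Only the first SNP of a panel is causal; all others are drawn
independently of status, which is what makes large null panels cheap and
exactly null. The generator does **not** simulate linkage
disequilibrium, genotyping error, relatedness, exposure measurement
error, or genotype–exposure dependence — so passing tests demonstrate
the statistical machinery is correct and calibrated under the model's
assumptions, not that real cohort data meet those assumptions.

## Per-SNP models

The three nested logistic models (environmental, genetic, interaction)
are fit by iteratively reweighted least squares on the binomial
log-likelihood, with step-halving. Convergence requires the largest
score component < 1e−8 or a relative log-likelihood change < 1e−10,
within 50 iterations; the covariance is the inverse observed information
at the optimum. A rank-deficient design raises immediately; a
non-convergent fit with any |coefficient| > 15 is classified as
quasi-separation (a log-odds of 15 is far beyond anything estimable in
cohort data, so this flags likelihoods without a finite maximum rather
than real effects). SNPs with minor-allele count < 10 in the analysis
sample (configurable) are flagged monomorphic/near-monomorphic and
skipped, since Wald statistics are unstable there. Missing genotypes are
handled per SNP by complete-case analysis with the used n recorded.

The 1-df interaction test is the Wald test of the product term —
matching the convention of standard GWAS software — with a 1-df LRT
available by option; the two agree asymptotically and both are verified
uniform under the null. The 2-df joint test is a likelihood ratio of the
interaction model against the environmental model fit *on the same
complete cases*, so the models stay nested. Exposure coding options:
mean-centered continuous (centering shifts the SNP main effect but is
algebraically irrelevant to the product term — asserted as a test),
dichotomized at the control median, or the top-tertile indicator.

## Meta-analysis

Per-SNP estimates from k cohorts are pooled by inverse-variance-weighted
fixed effects (wᵢ = 1/seᵢ², pooled se = (Σwᵢ)^(−1/2)). A
sample-size-weighted z scheme (zᵢ = sign(βᵢ)Φ⁻¹(1−pᵢ/2), pooled
z = Σzᵢ√nᵢ/√Σnᵢ) is provided as an explicit alternative because
published pooled p-values are sometimes computed that way; the package
defaults to IVW and asserts neither as "the" published scheme.
Heterogeneity is screened with Cochran's Q (χ², k−1 df) and reported,
never used to switch to random effects. Effect alleles are aligned to
the first cohort's; a swapped allele pair flips the beta sign, anything
else excludes the SNP with a log entry, and palindromic (A/T, C/G) SNPs
are flagged. Only SNPs with an ok status in every cohort are pooled.

## Pathway enrichment null

Synthetic pathways are built gene-wise: for each template gene with k
SNPs, one platform gene whose SNP count lies in
[⌈k(1−tol)⌉, ⌊k(1+tol)⌋] (tol = 0.10) is drawn uniformly without
replacement within a pathway; genes may repeat across the 1,000
pathways. The integer window means genes with k ≤ 4 require an exact
count match; the window always contains k. Template genes are excluded
from the candidate pool entirely (stronger than excluding only template
SNPs — prevents partial self-matching), and any platform gene sharing a
SNP with the template is likewise ineligible.

Counting uses strict inequality (p < T) and drops SNPs without a
p-value from both observed and synthetic counts, with a logged tally.
Two empirical quantities are reported because the field's conventions
conflict: the strict fraction #{C_obs > C_syn}/N (large under
enrichment; the form quoted in the motivating analysis) and the standard
permutation estimator (1 + #{C_syn ≥ C_obs})/(N + 1) (small under
enrichment, never exactly zero). Default thresholds
T ∈ {0.05, 0.01, 0.001}; one synthetic set is drawn per analysis and
reused across all thresholds and effect types so comparisons share a
common null draw.

The bundled iron metabolism pathway table transcribes the published
panel verbatim: 29 gene rows, 321 (gene, SNP) rows including five
duplicate listings, 316 unique SNPs after de-duplication. The loader
reports its own de-duplicated counts rather than forcing any externally
quoted total.

## Power analysis

Power for the 1-df test is estimated by full Monte-Carlo: each replicate
simulates a complete case-control cohort (default 1,806 cases / 2,965
controls, the pooled two-cohort size) with a binary top-tertile exposure
(population prevalence 1/3, OR 1.3), a causal locus (MAF 0.4, genetic
OR 1.2 — "relative risks" in the design literature are interpreted as
odds ratios here), fits the interaction model, and tests the product
term; power is the rejection fraction and its Monte-Carlo SE is
binomial, √(p̂(1−p̂)/reps). Non-convergent replicates are excluded from
the denominator and counted (none occur at these sample sizes). Power
scenarios include age and BMI as null covariates and omit eigenvector
covariates; an analytic design calculation would include neither.
`power_curve` reuses one seed across grid points (common random
numbers), which keeps the curve monotone at moderate replicate counts.

At these settings the log-additive scenario (interaction OR 1.8,
α = 7.33 × 10⁻⁸) yields ≈ 85% power — consistent with the ~80% quoted
for this design. The dominant scenario (interaction OR 1.5,
α = 2.10 × 10⁻⁴) yields ≈ 23%, far below the ~80% sometimes quoted. The
shortfall is structural, not a simulation artifact: with carrier
frequency 1−0.6² = 0.64 and a binary exposure of prevalence 1/3, the
partial variance of the carrier × exposure product after adjusting for
its margins is Var(D)·Var(E) ≈ 0.051, giving an expected Wald z of
about 3.0 at n = 4,771 against the 4.55 needed for 80% power at that
α. Reaching ~80% under a dominant model would require a different
exposure parameterization (e.g. a 0/1/2 tertile trend) or an
uncorrected α, neither of which matches the stated design; the package
reports what the stated design actually delivers.

## Numerical and design choices

* Convergence tolerances and the separation heuristic as above; all
  closed-form checks (2×2 table, intercept-only) are exact to ≤ 1e−8.
* Bonferroni thresholds are α/m with m supplied by the caller; the
  package never hard-codes a platform's SNP count.
* The pipeline driver writes TSV between stages, PLINK bed/bim/fam only
  at the genotype boundary (variant-major, A1 = minor/effect allele),
  and embeds seed + configuration hash in every output so a report is
  reproducible from its header. Single-cohort runs skip the
  meta-analysis stage with a warning.
* Default test-suite and acceptance problem sizes — 1,000-SNP null
  panels for calibration, 200 cohorts for effect recovery, 1,000
  replicates per power scenario, 1,000 synthetic pathways — were chosen
  as the smallest sizes at which the binomial/KS tolerances used are
  meaningful.

## Known limitations

* No LD, imputation dosages, X-chromosome handling, or genomic control;
  no random-effects meta-analysis; no gene-set methods modeling LD or
  gene length (the matched-pathway test is exactly the published
  procedure, no more).
* The empirical "p-value" under the strict definition is a fraction
  that grows with enrichment; it is reported alongside the conventional
  estimator precisely because the two answer differently.
* Synthetic eigenvectors carry no confounding signal, so the package
  cannot demonstrate stratification correction — only that including
  the covariates leaves the tests calibrated.
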