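# hemegxe

Genome-wide gene × dietary-heme-iron interaction analysis for type 2
diabetes (T2D), packaged as a tested, reusable pipeline.

Dietary heme iron (the iron in hemoglobin/myoglobin from animal foods,
measured in mg/day) is a consistently reported T2D risk factor, and iron
overload plausibly stresses pancreatic beta cells. This package asks the
natural follow-up question for epidemiologists and statistical
geneticists: *is the association between common SNPs and T2D modified by
heme iron intake?* It provides every stage needed to run that analysis on
case-control cohorts — and, because the motivating cohort genotypes are
consent-restricted, a calibrated synthetic-cohort generator so the whole
pipeline is exercisable and testable end to end.

## The models

For each SNP (coded 0/1/2 minor alleles), three nested logistic
regressions per cohort, with age (years), BMI (kg/m²) and
principal-component eigenvectors as covariates and heme centered on the
cohort mean:

```
Model 1 (environmental):  logit P(T2D) = β₀ + β(age) + β(BMI) + β(heme)
Model 2 (genetic):        logit P(T2D) = β₀ + β₁(SNP) + β(age) + β(BMI) + β(heme)
Model 3 (interaction):    logit P(T2D) = β₀ + β₁(SNP) + β(age) + β(BMI) + β₄(heme) + β₅(SNP × heme)
```

* **1-df interaction test** — Wald test of β₅ in Model 3 (LRT optional).
* **2-df joint test** — likelihood ratio of Model 3 vs Model 1,
  χ² with 2 df: sensitive to a SNP acting through its main effect, its
  interaction, or both.
* **Marginal SNP test** — Wald test of β₁ in Model 2.
* **Meta-analysis** — inverse-variance-weighted fixed effects across
  cohorts (β̄ = Σwᵢβᵢ/Σwᵢ, wᵢ = 1/seᵢ²), with METAL-style
  sample-size-weighted z as an alternative, Cochran's Q heterogeneity
  screening, and effect-allele alignment.
* **Pathway enrichment** — compares C_obs, the number of pathway SNPs
  with p < T, against C_syn in 1,000 synthetic pathways matched on gene
  count and per-gene SNP count ±10%, drawn from a platform-wide
  annotation excluding the pathway itself. Both the strict empirical
  fraction #{C_obs > C_syn}/N and the conventional permutation p are
  reported.
* **Power analysis** — Monte-Carlo power of the 1-df test under
  configurable inheritance (log-additive / dominant), MAF, marginal and
  interaction odds ratios, and significance threshold.

A transcription of the 29-gene iron metabolism pathway panel (316 unique
SNPs after de-duplication) ships with the package
(`hemegxe.HEME_PATHWAY_FILE`).

## Worked example

Simulate two cohorts the size of the motivating studies (725/1,273 and
1,081/1,692 cases/controls) sharing a 50-SNP panel whose first SNP
carries a true interaction odds ratio of 1.8, scan each, and pool:

```python
from hemegxe import (SimulationConfig, simulate_cohort, genome_scan,
                     ModelSpec, meta_scan)
from hemegxe.simulate import generate_platform_annotation

ann, panel = generate_platform_annotation(10, 5, seed=0)
cfgs = [
    SimulationConfig(n_cases=725, n_controls=1273, maf_range=(0.3, 0.3),
                     or_interaction=1.8, exposure_mean=1.29, exposure_sd=0.43,
                     n_eigenvectors=4, cohort_label="HPFS_SYN", seed=1),
    SimulationConfig(n_cases=1081, n_controls=1692, maf_range=(0.3, 0.3),
                     or_interaction=1.8, exposure_mean=1.36, exposure_sd=0.45,
                     n_eigenvectors=3, cohort_label="NHS_SYN", seed=2),
]
tables = []
for cfg in cfgs:
    cohort = simulate_cohort(cfg, panel_template=panel)
    tables.append(genome_scan(cohort, ModelSpec(n_eigenvectors=cfg.n_eigenvectors)))
pooled = meta_scan(tables, effect="interaction")
print(pooled.sort_values("P_POOLED").head(3)
      [["SNP", "BETA_POOLED", "SE_POOLED", "P_POOLED", "Q", "P_HET"]])
```

prints

```
          SNP  BETA_POOLED  SE_POOLED  P_POOLED        Q    P_HET
rs_syn_000001     0.465064   0.104431  0.000008 0.475992 0.490244
rs_syn_000048    -0.319646   0.104656  0.002256 0.532476 0.465568
rs_syn_000015    -0.222840   0.102655  0.029948 0.371402 0.542241
```

The causal SNP (`rs_syn_000001`) tops the pooled interaction scan with
β̂₅ = 0.47 (one replicate's estimate of the true log OR, log 1.8 ≈ 0.59)
and shows no between-cohort heterogeneity (P_HET 0.49); the remaining
SNPs are null. Power for the two published design scenarios:

```python
from hemegxe import PowerScenario, estimate_power
est = estimate_power(PowerScenario(reps=1000, seed=1806))   # log-additive defaults
# -> power=0.854, mc_se=0.011   (OR_gxe 1.8 at genome-wide alpha 7.33e-8)
est = estimate_power(PowerScenario(inheritance="dominant", or_interaction=1.5,
                                   alpha=2.10e-4, reps=1000, seed=1806))
# -> power=0.230, mc_se=0.013   (OR_gxe 1.5 at pathway alpha 2.10e-4)
```

See `docs/methods.md` for why the simulated dominant-model power is far
below the ~80% sometimes quoted for this design.

The same stages are available from a shell:

```bash
hemegxe simulate --config cfg.yaml --out run/ --seed 1
hemegxe scan --bed run/SYNTH --out run/scan.tsv
hemegxe meta --in hpfs.tsv --in nhs.tsv --effect interaction --out pooled.tsv
hemegxe pathway-null --results pooled.tsv --pathway heme.tsv \
    --annotation platform.tsv --out enrich.tsv
hemegxe power --reps 1000 --seed 1
hemegxe pipeline --out run/ --seed 1     # simulate -> scan -> meta -> enrichment -> report
```

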