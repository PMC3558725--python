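"""Synthetic case-control cohorts for gene x diet interaction analysis.

Generates cohorts with the statistical structure a genome-wide
gene-environment interaction scan assumes: Hardy-Weinberg genotypes across
a minor-allele-frequency spectrum, a continuous dietary exposure (mg/day,
normal truncated at zero), BMI/age covariates, principal-component noise
covariates, and binary disease status drawn from a prospective logistic
model with configurable marginal and interaction odds ratios.  Case and
control quotas are filled by rejection sampling from the population model.

Also generates platform-wide gene -> SNP annotations, the substrate for
matched synthetic-pathway null sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MISSING",
    "SimulationConfig",
    "GenotypePanel",
    "CohortData",
    "GeneAnnotation",
    "QuotaError",
    "simulate_genotype_vector",
    "simulate_cohort",
    "generate_platform_annotation",
]

#: sentinel for a missing genotype in the 0/1/2 minor-allele-count coding
MISSING: int = -1


class QuotaError(RuntimeError):
    """Case/control quota could not be filled under the disease model."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated case-control cohort.

    Odds ratios are per minor allele (log-additive) or per carrier
    (dominant) for the genetic term, per mg/day (continuous coding) or per
    top-tertile membership for the exposure, and per unit for BMI/age.
    The first SNP of the panel is the causal SNP; all remaining SNPs are
    null (independent of disease).
    """

    n_cases: int = 725
    n_controls: int = 1273
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_snps: int = 1
    baseline_log_odds: float = -2.5  # ~8% population prevalence
    or_snp: float = 1.0
    or_exposure: float = 1.0
    or_interaction: float = 1.0
    exposure_mean: float = 1.29  # mg/day
    exposure_sd: float = 0.43
    bmi_mean: float = 25.05  # kg/m^2
    bmi_sd: float = 3.46
    age_mean: float = 54.19  # years
    age_sd: float = 8.36
    or_bmi: float = 1.0
    or_age: float = 1.0
    n_eigenvectors: int = 4
    inheritance: str = "log-additive"  # or "dominant"
    exposure_coding: str = "continuous"  # or "top-tertile"
    missing_rate: float = 0.0
    seed: int = 0
    cohort_label: str = "SYNTH"

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("exposure_sd", "bmi_sd", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("or_snp", "or_exposure", "or_interaction", "or_bmi", "or_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive odds ratio")
        if self.n_eigenvectors < 0:
            raise ValueError("n_eigenvectors must be non-negative")
        if self.inheritance not in ("log-additive", "dominant"):
            raise ValueError(f"unknown inheritance model: {self.inheritance!r}")
        if self.exposure_coding not in ("continuous", "top-tertile"):
            raise ValueError(f"unknown exposure coding: {self.exposure_coding!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GenotypePanel:
    """SNP metadata plus a subjects x SNPs matrix of minor-allele counts.

    ``genotypes`` holds values in {0, 1, 2} with :data:`MISSING` (-1) for
    missing calls; dtype int8.  A panel with zero rows carries metadata
    only (e.g. a platform annotation's companion panel).
    """

    snp_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        g = self.genotypes
        if g.size and not np.isin(g, (0, 1, 2, MISSING)).all():
            raise ValueError("genotypes must be 0/1/2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def index_of(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def genotype_vector(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.index_of(snp_id)]


@dataclass
class CohortData:
    """Subject-level data for one cohort: outcome, exposure, covariates, genotypes.

    ``exposure`` is the continuous intake in mg/day.  When the cohort was
    simulated under top-tertile exposure coding, ``exposure_binary`` holds
    the 0/1 indicator of membership in the highest population tertile (the
    variable that entered the risk model); it is None otherwise.
    """

    cohort_label: str
    status: np.ndarray  # 1 = case
    exposure: np.ndarray  # mg/day
    bmi: np.ndarray
    age: np.ndarray
    eigenvectors: np.ndarray  # subjects x k
    panel: GenotypePanel
    exposure_binary: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.status)
        for name in ("exposure", "bmi", "age"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match status")
        if self.eigenvectors.shape[0] != n:
            raise ValueError("eigenvectors row count does not match status")
        if self.panel.genotypes.shape[0] != n:
            raise ValueError("genotype row count does not match status")
        if not (0 < self.status.sum() < n):
            raise ValueError("both cases and controls must be present")

    @property
    def n_subjects(self) -> int:
        return len(self.status)


@dataclass
class GeneAnnotation:
    """Platform-wide mapping from gene id to the SNPs assigned to it."""

    gene_ids: list[str]
    gene_to_snps: dict[str, list[str]]

    def __post_init__(self) -> None:
        for g in self.gene_ids:
            if not self.gene_to_snps.get(g):
                raise ValueError(f"gene {g!r} has an empty SNP list")

    def snp_count(self, gene_id: str) -> int:
        return len(self.gene_to_snps[gene_id])

    @property
    def all_snps(self) -> set[str]:
        return {s for snps in self.gene_to_snps.values() for s in snps}


# ---------------------------------------------------------------------------
# genotype sampling


def simulate_genotype_vector(
    maf: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` Hardy-Weinberg genotypes (0/1/2 minor-allele counts).

    Genotype probabilities are ((1-q)^2, 2q(1-q), q^2) for minor-allele
    frequency ``q``.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    if n <= 0:
        raise ValueError("n must be positive")
    return rng.binomial(2, maf, size=n).astype(np.int8)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) truncated at zero, by resampling the negative tail."""
    x = rng.normal(mean, sd, size=n)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x < 0
    return x


def population_tertile_cutoff(mean: float, sd: float) -> float:
    """Upper-tertile boundary of the zero-truncated normal exposure model."""
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.ppf(2.0 / 3.0, a, np.inf, loc=mean, scale=sd))


# ---------------------------------------------------------------------------
# cohort simulation


def _simulate_subject_batch(
    cfg: SimulationConfig,
    causal_maf: float,
    tertile_cut: float,
    rng: np.random.Generator,
    batch: int,
) -> tuple[np.ndarray, ...]:
    """Draw one population batch and its disease status."""
    g = simulate_genotype_vector(causal_maf, batch, rng)
    exposure = _truncated_normal(rng, cfg.exposure_mean, cfg.exposure_sd, batch)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=batch)
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=batch)

    g_risk = (g > 0).astype(float) if cfg.inheritance == "dominant" else g.astype(float)
    if cfg.exposure_coding == "top-tertile":
        e_risk = (exposure > tertile_cut).astype(float)
    else:
        # centered so baseline_log_odds keeps its prevalence interpretation
        e_risk = exposure - cfg.exposure_mean

    lp = (
        cfg.baseline_log_odds
        + math.log(cfg.or_snp) * g_risk
        + math.log(cfg.or_exposure) * e_risk
        + math.log(cfg.or_interaction) * g_risk * e_risk
        + math.log(cfg.or_bmi) * (bmi - cfg.bmi_mean)
        + math.log(cfg.or_age) * (age - cfg.age_mean)
    )
    y = rng.random(batch) < 1.0 / (1.0 + np.exp(-lp))
    return g, exposure, bmi, age, y


def simulate_cohort(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1000,
    panel_template: GenotypePanel | None = None,
) -> CohortData:
    """Simulate one case-control cohort under the logistic disease model.

    Subjects are drawn from the population model and assigned disease
    status; sampling continues in batches until exactly ``n_cases`` cases
    and ``n_controls`` controls have been collected (rejection sampling).
    SNP 1 is the causal SNP; SNPs 2..n_snps are null, drawn independently
    of status under Hardy-Weinberg equilibrium.

    ``panel_template`` fixes SNP metadata (ids, positions, alleles, MAFs)
    so several cohorts can share one panel, as a meta-analysis requires;
    it overrides ``cfg.n_snps`` and ``cfg.maf_range``.

    Raises :class:`QuotaError` if a quota is still unfilled after
    ``max_attempts`` batches, e.g. for an extreme ``baseline_log_odds``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if panel_template is not None:
        cfg = replace(cfg, n_snps=panel_template.n_snps)
        mafs = np.asarray(panel_template.maf, dtype=float)
    else:
        lo, hi = cfg.maf_range
        mafs = (
            rng.uniform(lo, hi, size=cfg.n_snps)
            if lo < hi
            else np.full(cfg.n_snps, lo)
        )
    tertile_cut = population_tertile_cutoff(cfg.exposure_mean, cfg.exposure_sd)

    n_total = cfg.n_cases + cfg.n_controls
    batch = max(10_000, 2 * n_total)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_cases_got = n_controls_got = 0
    for attempt in range(max_attempts):
        g, exposure, bmi, age, y = _simulate_subject_batch(
            cfg, float(mafs[0]), tertile_cut, rng, batch
        )
        rows = np.column_stack([g.astype(float), exposure, bmi, age])
        if n_cases_got < cfg.n_cases:
            cases.append(rows[y])
            n_cases_got += int(y.sum())
        if n_controls_got < cfg.n_controls:
            controls.append(rows[~y])
            n_controls_got += int((~y).sum())
        if n_cases_got >= cfg.n_cases and n_controls_got >= cfg.n_controls:
            break
    else:
        raise QuotaError(
            f"could not fill quota of {cfg.n_cases} cases / {cfg.n_controls} "
            f"controls after {max_attempts} batches of {batch} "
            f"(got {n_cases_got} / {n_controls_got}); check baseline_log_odds "
            f"({cfg.baseline_log_odds}) and effect sizes"
        )

    case_rows = np.vstack(cases)[: cfg.n_cases]
    control_rows = np.vstack(controls)[: cfg.n_controls]
    rows = np.vstack([case_rows, control_rows])
    status = np.r_[np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]

    genotypes = np.empty((n_total, cfg.n_snps), dtype=np.int8)
    genotypes[:, 0] = rows[:, 0].astype(np.int8)
    for j in range(1, cfg.n_snps):
        genotypes[:, j] = simulate_genotype_vector(float(mafs[j]), n_total, rng)
    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[miss] = MISSING

    exposure = rows[:, 1]
    if panel_template is not None:
        panel = GenotypePanel(
            snp_ids=list(panel_template.snp_ids),
            chromosome=panel_template.chromosome.copy(),
            position=panel_template.position.copy(),
            effect_allele=panel_template.effect_allele.copy(),
            other_allele=panel_template.other_allele.copy(),
            maf=mafs.copy(),
            genotypes=genotypes,
        )
    else:
        panel = GenotypePanel(
            snp_ids=[f"rs_syn_{j + 1:06d}" for j in range(cfg.n_snps)],
            chromosome=np.array(["1"] * cfg.n_snps, dtype=object),
            position=np.arange(1, cfg.n_snps + 1) * 1000,
            effect_allele=np.array(["A"] * cfg.n_snps, dtype=object),
            other_allele=np.array(["G"] * cfg.n_snps, dtype=object),
            maf=mafs,
            genotypes=genotypes,
        )
    return CohortData(
        cohort_label=cfg.cohort_label,
        status=status,
        exposure=exposure,
        bmi=rows[:, 2],
        age=rows[:, 3],
        eigenvectors=rng.standard_normal((n_total, cfg.n_eigenvectors)),
        panel=panel,
        exposure_binary=(
            (exposure > tertile_cut).astype(np.int8)
            if cfg.exposure_coding == "top-tertile"
            else None
        ),
    )


# ---------------------------------------------------------------------------
# platform annotation


def generate_platform_annotation(
    n_genes: int,
    snps_per_gene_sampler: int | Sequence[int] | Callable[[np.random.Generator], int],
    rng: np.random.Generator | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[GeneAnnotation, GenotypePanel]:
    """Generate a platform-wide gene -> SNP annotation with disjoint SNP lists.

    ``snps_per_gene_sampler`` sets the per-gene SNP count: a fixed integer,
    a sequence tiled deterministically across genes (gene i gets
    ``counts[i % len(counts)]``, so a sequence of per-gene counts is
    reproduced exactly when ``n_genes`` equals its length), or a callable
    ``sampler(rng) -> int``.

    The companion panel carries metadata (ids, positions, alleles, MAFs)
    and an empty genotype matrix; cohort simulation fills genotypes.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    if isinstance(snps_per_gene_sampler, int):
        counts = [snps_per_gene_sampler] * n_genes
    elif callable(snps_per_gene_sampler):
        counts = [int(snps_per_gene_sampler(rng)) for _ in range(n_genes)]
    else:
        seq = list(snps_per_gene_sampler)
        if not seq:
            raise ValueError("empty per-gene count sequence")
        counts = [int(seq[i % len(seq)]) for i in range(n_genes)]
    if any(c <= 0 for c in counts):
        raise ValueError("per-gene SNP counts must be positive")

    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    gene_to_snps: dict[str, list[str]] = {}
    snp_ids: list[str] = []
    k = 0
    for gid, c in zip(gene_ids, counts):
        snps = [f"rs_syn_{k + j + 1:06d}" for j in range(c)]
        gene_to_snps[gid] = snps
        snp_ids.extend(snps)
        k += c

    n_snps = len(snp_ids)
    lo, hi = maf_range
    panel = GenotypePanel(
        snp_ids=snp_ids,
        chromosome=np.array(["1"] * n_snps, dtype=object),
        position=np.arange(1, n_snps + 1) * 1000,
        effect_allele=np.array(["A"] * n_snps, dtype=object),
        other_allele=np.array(["G"] * n_snps, dtype=object),
        maf=rng.uniform(lo, hi, size=n_snps),
        genotypes=np.empty((0, n_snps), dtype=np.int8),
    )
    return GeneAnnotation(gene_ids=gene_ids, gene_to_snps=gene_to_snps), panel
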