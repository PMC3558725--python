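"""Per-SNP logistic models for gene x dietary-exposure interaction in T2D.

Three nested logistic regressions per SNP, each adjusted for age, BMI and
principal-component (eigenvector) covariates:

* environmental model — disease on exposure + covariates (no SNP);
* genetic model — adds the SNP; its coefficient is the marginal SNP test;
* interaction model — adds a SNP x exposure product term; the single-df
  Wald test of that coefficient is the primary gene-environment test, and
  the 2-df joint test compares the interaction model against the
  environmental model by likelihood ratio (chi-square, 2 df).

Fitting is iteratively reweighted least squares on the binomial
log-likelihood, with the covariance taken as the inverse observed
information at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MISSING, CohortData

__all__ = [
    "ModelSpec",
    "LogisticFit",
    "SnpAssociation",
    "DegenerateDesignError",
    "fit_logistic",
    "center_exposure",
    "dichotomize_exposure",
    "test_interaction_1df",
    "test_joint_2df",
    "marginal_snp_test",
    "genome_scan",
    "bonferroni_threshold",
]

# fit_logistic convergence policy
MAX_ITER = 50
SCORE_TOL = 1e-8
REL_LL_TOL = 1e-10
SEPARATION_BETA = 15.0


class DegenerateDesignError(ValueError):
    """Design matrix is rank-deficient (collinear or constant columns)."""


@dataclass
class ModelSpec:
    """How the per-SNP models are parameterized.

    exposure_coding:
        ``continuous-centered`` — exposure centered on the cohort mean;
        ``dichotomous-at-control-median`` — 1 iff above the control median;
        ``top-tertile`` — 0/1 indicator of the highest exposure tertile
        (the cohort's stored indicator when simulated that way, else the
        empirical upper tertile).
    genotype_coding:
        ``additive`` (0/1/2 minor alleles) or ``dominant`` (carrier 0/1).
    interaction_test:
        ``wald`` (default) or ``lrt`` for the 1-df product-term test.
    min_minor_allele_count:
        SNPs with fewer minor alleles than this in the analysis sample are
        flagged monomorphic/near-monomorphic and skipped.
    """

    exposure_coding: str = "continuous-centered"
    covariates: tuple[str, ...] = ("age", "bmi")
    n_eigenvectors: int | None = None  # None: use all available columns
    genotype_coding: str = "additive"
    interaction_test: str = "wald"
    min_minor_allele_count: int = 10

    def __post_init__(self) -> None:
        if self.exposure_coding not in (
            "continuous-centered",
            "dichotomous-at-control-median",
            "top-tertile",
        ):
            raise ValueError(f"unknown exposure coding: {self.exposure_coding!r}")
        if self.genotype_coding not in ("additive", "dominant"):
            raise ValueError(f"unknown genotype coding: {self.genotype_coding!r}")
        if self.interaction_test not in ("wald", "lrt"):
            raise ValueError(f"unknown interaction test: {self.interaction_test!r}")
        if self.n_eigenvectors is not None and self.n_eigenvectors < 0:
            raise ValueError("n_eigenvectors must be non-negative")


@dataclass
class LogisticFit:
    term_names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_used: int
    iterations: int
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.term_names.index(term)])

    def se(self, term: str) -> float:
        i = self.term_names.index(term)
        return float(math.sqrt(self.covariance[i, i]))

    def wald_p(self, term: str) -> float:
        z = self.coef(term) / self.se(term)
        return float(2.0 * stats.norm.sf(abs(z)))

    @property
    def separated(self) -> bool:
        """Quasi-separation heuristic: runaway coefficient without convergence."""
        return (not self.converged) and bool(
            (np.abs(self.coefficients) > SEPARATION_BETA).any()
        )


@dataclass
class SnpAssociation:
    """Per-SNP results across the genetic and interaction models."""

    snp_id: str
    beta_marginal: float = math.nan
    se_marginal: float = math.nan
    p_marginal: float = math.nan
    beta_interaction: float = math.nan
    se_interaction: float = math.nan
    p_1df: float = math.nan
    p_2df: float = math.nan
    n_used: int = 0
    status: str = "ok"  # ok | monomorphic | separation | non-convergence


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # ll = sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    response: np.ndarray,
    design: np.ndarray,
    term_names: list[str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the largest score component falls below 1e-8 or the
    relative log-likelihood change falls below 1e-10, within 50
    iterations.  Step-halving guards against overshooting.  Raises
    :class:`DegenerateDesignError` for a rank-deficient design and
    ``ValueError`` if only one response class is present.
    """
    y = np.asarray(response, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("design must be subjects x terms, matching response")
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if len(term_names) != p:
        raise ValueError("term_names length must match design columns")
    if not (0 < y.sum() < n):
        raise ValueError("response must contain both classes")
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDesignError(
            f"design matrix is rank-deficient ({p} terms, rank "
            f"{np.linalg.matrix_rank(X)})"
        )

    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(y, eta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            it -= 1
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break  # information singular at current iterate
        # step-halving: accept the first step that does not decrease ll
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = _log_likelihood(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta = cand, eta_c
        rel = abs(ll_c - ll) / (abs(ll) + 1e-300)
        ll = ll_c
        if rel < REL_LL_TOL:
            mu = 1.0 / (1.0 + np.exp(-eta))
            converged = bool(np.max(np.abs(X.T @ (y - mu))) < math.sqrt(SCORE_TOL))
            break

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-300, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if converged and np.max(np.abs(X.T @ (y - mu))) >= SCORE_TOL:
        # relative-ll stop: double-check score is small enough to trust Wald
        converged = bool(np.max(np.abs(X.T @ (y - mu))) < 1e-4)
    if np.max(np.abs(beta)) > SEPARATION_BETA:
        # runaway log-odds: the likelihood has no finite maximum (quasi-separation)
        converged = False
    return LogisticFit(
        term_names=list(term_names),
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        n_used=n,
        iterations=it,
        converged=converged,
    )


def center_exposure(values: np.ndarray) -> np.ndarray:
    """Center an exposure vector on its mean (per-cohort centering)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot center an empty vector")
    return v - v.mean()


def dichotomize_exposure(values: np.ndarray, control_mask: np.ndarray) -> np.ndarray:
    """Code exposure 1 iff strictly above the median among controls.

    The median of an even number of controls is the midpoint of the two
    central order statistics (numpy's convention).
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(control_mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("values and control_mask must have equal length")
    if not m.any():
        raise ValueError("no controls available to define the median")
    med = np.median(v[m])
    return (v > med).astype(np.int8)


# ---------------------------------------------------------------------------
# design assembly


def _coded_exposure(cohort: CohortData, spec: ModelSpec) -> tuple[np.ndarray, str]:
    if spec.exposure_coding == "continuous-centered":
        return center_exposure(cohort.exposure), "heme_centered"
    if spec.exposure_coding == "dichotomous-at-control-median":
        return (
            dichotomize_exposure(cohort.exposure, cohort.status == 0).astype(float),
            "heme_high",
        )
    # top-tertile
    if cohort.exposure_binary is not None:
        return cohort.exposure_binary.astype(float), "heme_top_tertile"
    cut = np.quantile(cohort.exposure, 2.0 / 3.0)
    return (cohort.exposure > cut).astype(float), "heme_top_tertile"


def _covariate_matrix(cohort: CohortData, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for name in spec.covariates:
        cols.append(np.asarray(getattr(cohort, name), dtype=float))
        names.append(name)
    k = cohort.eigenvectors.shape[1]
    if spec.n_eigenvectors is not None:
        if spec.n_eigenvectors > k:
            raise ValueError(
                f"requested {spec.n_eigenvectors} eigenvectors, cohort has {k}"
            )
        k = spec.n_eigenvectors
    for j in range(k):
        cols.append(cohort.eigenvectors[:, j])
        names.append(f"ev{j + 1}")
    C = np.column_stack(cols) if cols else np.empty((cohort.n_subjects, 0))
    return C, names


def _coded_genotype(g: np.ndarray, spec: ModelSpec) -> np.ndarray:
    g = g.astype(float)
    return (g > 0).astype(float) if spec.genotype_coding == "dominant" else g


@dataclass
class _SnpContext:
    """Shared arrays for fitting all three models on one SNP's complete cases."""

    y: np.ndarray
    g: np.ndarray  # coded genotype
    e: np.ndarray  # coded exposure
    C: np.ndarray
    cov_names: list[str]
    n_used: int


def _snp_context(cohort: CohortData, snp_id: str, spec: ModelSpec) -> _SnpContext | None:
    """Complete-case arrays for one SNP, or None when near-monomorphic."""
    graw = cohort.panel.genotype_vector(snp_id)
    mask = graw != MISSING
    g = graw[mask].astype(float)
    n = int(mask.sum())
    mac = min(g.sum(), 2 * n - g.sum())
    if mac < spec.min_minor_allele_count:
        return None
    e, ename = _coded_exposure(cohort, spec)
    C, cov_names = _covariate_matrix(cohort, spec)
    return _SnpContext(
        y=cohort.status[mask].astype(float),
        g=_coded_genotype(g, spec),
        e=e[mask],
        C=C[mask],
        cov_names=[ename] + cov_names,
        n_used=n,
    )


def _fit_models(ctx: _SnpContext, which: str) -> LogisticFit:
    """Fit the environmental ('env'), genetic ('gen') or interaction ('int') model."""
    const = np.ones_like(ctx.y)
    base = [const, ctx.e] + [ctx.C[:, j] for j in range(ctx.C.shape[1])]
    names = ["const"] + ctx.cov_names
    if which == "env":
        return fit_logistic(ctx.y, np.column_stack(base), names)
    if which == "gen":
        return fit_logistic(
            ctx.y, np.column_stack([base[0], ctx.g] + base[1:]), ["const", "snp"] + names[1:]
        )
    return fit_logistic(
        ctx.y,
        np.column_stack([base[0], ctx.g] + base[1:] + [ctx.g * ctx.e]),
        ["const", "snp"] + names[1:] + ["snp_x_heme"],
    )


def _status_of(fit: LogisticFit) -> str:
    if fit.converged:
        return "ok"
    return "separation" if fit.separated else "non-convergence"


def test_interaction_1df(
    cohort: CohortData, snp_id: str, spec: ModelSpec | None = None
) -> SnpAssociation:
    """Single-df test of the SNP x exposure product term.

    Fits the interaction model and reports the product-term coefficient,
    its standard error, and the two-sided Wald p-value
    ``2 * (1 - Phi(|beta| / se))`` (or a 1-df likelihood-ratio p when the
    spec requests ``lrt``).
    """
    spec = spec or ModelSpec()
    ctx = _snp_context(cohort, snp_id, spec)
    if ctx is None:
        return SnpAssociation(snp_id=snp_id, status="monomorphic")
    try:
        fit3 = _fit_models(ctx, "int")
    except DegenerateDesignError:
        return SnpAssociation(snp_id=snp_id, n_used=ctx.n_used, status="separation")
    out = SnpAssociation(snp_id=snp_id, n_used=ctx.n_used, status=_status_of(fit3))
    if out.status != "ok":
        return out
    out.beta_interaction = fit3.coef("snp_x_heme")
    out.se_interaction = fit3.se("snp_x_heme")
    if spec.interaction_test == "wald":
        out.p_1df = fit3.wald_p("snp_x_heme")
    else:
        fit2 = _fit_models(ctx, "gen")
        lr = max(0.0, 2.0 * (fit3.log_likelihood - fit2.log_likelihood))
        out.p_1df = float(stats.chi2.sf(lr, df=1))
    return out


def test_joint_2df(
    cohort: CohortData, snp_id: str, spec: ModelSpec | None = None
) -> float:
    """Joint 2-df likelihood-ratio test of SNP main effect plus interaction.

    Compares the interaction model against the environmental (no-SNP)
    model on the same complete cases: ``2 * (ll_int - ll_env)`` referred
    to chi-square with 2 df.
    """
    spec = spec or ModelSpec()
    ctx = _snp_context(cohort, snp_id, spec)
    if ctx is None:
        return math.nan
    fit3 = _fit_models(ctx, "int")
    fit1 = _fit_models(ctx, "env")
    if not (fit3.converged and fit1.converged):
        return math.nan
    lr = max(0.0, 2.0 * (fit3.log_likelihood - fit1.log_likelihood))
    return float(stats.chi2.sf(lr, df=2))


def marginal_snp_test(
    cohort: CohortData, snp_id: str, spec: ModelSpec | None = None
) -> SnpAssociation:
    """Marginal SNP test: Wald p for the SNP term of the genetic model."""
    spec = spec or ModelSpec()
    ctx = _snp_context(cohort, snp_id, spec)
    if ctx is None:
        return SnpAssociation(snp_id=snp_id, status="monomorphic")
    fit2 = _fit_models(ctx, "gen")
    out = SnpAssociation(snp_id=snp_id, n_used=ctx.n_used, status=_status_of(fit2))
    if out.status != "ok":
        return out
    out.beta_marginal = fit2.coef("snp")
    out.se_marginal = fit2.se("snp")
    out.p_marginal = fit2.wald_p("snp")
    return out


def associate_snp(
    cohort: CohortData, snp_id: str, spec: ModelSpec | None = None
) -> SnpAssociation:
    """All three per-SNP results (marginal, 1-df interaction, 2-df joint)."""
    spec = spec or ModelSpec()
    ctx = _snp_context(cohort, snp_id, spec)
    if ctx is None:
        return SnpAssociation(snp_id=snp_id, status="monomorphic")
    try:
        fit3 = _fit_models(ctx, "int")
        fit2 = _fit_models(ctx, "gen")
        fit1 = _fit_models(ctx, "env")
    except DegenerateDesignError:
        return SnpAssociation(snp_id=snp_id, n_used=ctx.n_used, status="separation")
    out = SnpAssociation(snp_id=snp_id, n_used=ctx.n_used)
    for f in (fit3, fit2, fit1):
        s = _status_of(f)
        if s != "ok":
            out.status = s
            return out
    out.beta_marginal = fit2.coef("snp")
    out.se_marginal = fit2.se("snp")
    out.p_marginal = fit2.wald_p("snp")
    out.beta_interaction = fit3.coef("snp_x_heme")
    out.se_interaction = fit3.se("snp_x_heme")
    if spec.interaction_test == "wald":
        out.p_1df = fit3.wald_p("snp_x_heme")
    else:
        lr1 = max(0.0, 2.0 * (fit3.log_likelihood - fit2.log_likelihood))
        out.p_1df = float(stats.chi2.sf(lr1, df=1))
    lr2 = max(0.0, 2.0 * (fit3.log_likelihood - fit1.log_likelihood))
    out.p_2df = float(stats.chi2.sf(lr2, df=2))
    return out


SCAN_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "N",
    "BETA_MARG", "SE_MARG", "P_MARG",
    "BETA_INT", "SE_INT", "P_1DF", "P_2DF", "STATUS",
]


def genome_scan(cohort: CohortData, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Run all per-SNP tests across the panel.

    Returns one row per SNP ordered by (chromosome, position); SNPs whose
    fits fail carry a non-ok STATUS instead of aborting the scan.
    """
    spec = spec or ModelSpec()
    panel = cohort.panel
    if panel.n_snps == 0:
        raise ValueError("cohort panel is empty")
    order = sorted(
        range(panel.n_snps),
        key=lambda i: (str(panel.chromosome[i]), int(panel.position[i])),
    )
    rows = []
    for i in order:
        sid = panel.snp_ids[i]
        r = associate_snp(cohort, sid, spec)
        rows.append(
            (
                sid, str(panel.chromosome[i]), int(panel.position[i]),
                str(panel.effect_allele[i]), str(panel.other_allele[i]), r.n_used,
                r.beta_marginal, r.se_marginal, r.p_marginal,
                r.beta_interaction, r.se_interaction, r.p_1df, r.p_2df, r.status,
            )
        )
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / m
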