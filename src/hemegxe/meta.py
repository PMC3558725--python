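"""Fixed-effects meta-analysis of per-SNP cohort results.

Pools log-odds estimates across cohorts by inverse-variance weighting
(default) or by METAL-style sample-size-weighted z-scores, after aligning
effect alleles, and screens for between-cohort heterogeneity with
Cochran's Q.  Only SNPs present with an ok status in every cohort are
pooled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummary",
    "MetaResult",
    "AlleleAlignmentError",
    "align_effect_alleles",
    "pool_fixed_ivw",
    "pool_sample_size_z",
    "cochran_q",
    "meta_scan",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlleleAlignmentError(ValueError):
    """Effect alleles of two cohorts cannot be reconciled for one SNP."""


@dataclass
class CohortSummary:
    """One cohort's estimate for one SNP (marginal or interaction effect)."""

    snp_id: str
    cohort_label: str
    beta: float
    se: float
    p: float
    n: int
    effect_allele: str = "A"
    other_allele: str = "G"
    effect: str = "interaction"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class MetaResult:
    snp_id: str
    pooled_beta: float
    pooled_se: float
    z: float
    p_pooled: float
    q_statistic: float = math.nan
    q_df: int = 0
    p_het: float = math.nan
    scheme: str = "ivw-beta"


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def align_effect_alleles(summaries: list[CohortSummary]) -> list[CohortSummary]:
    """Express all betas relative to the first cohort's effect allele.

    A summary whose effect/other alleles are swapped relative to the
    reference has its beta negated.  Any other allele combination is
    irreconcilable and raises :class:`AlleleAlignmentError`; palindromic
    (strand-ambiguous) SNPs are logged.
    """
    if not summaries:
        raise ValueError("no summaries to align")
    if len({s.snp_id for s in summaries}) != 1:
        raise ValueError("summaries must share one snp_id")
    ref = summaries[0]
    ea, oa = ref.effect_allele.upper(), ref.other_allele.upper()
    if _is_palindromic(ea, oa):
        log.warning("SNP %s is strand-ambiguous (%s/%s)", ref.snp_id, ea, oa)
    out = [ref]
    for s in summaries[1:]:
        sea, soa = s.effect_allele.upper(), s.other_allele.upper()
        if (sea, soa) == (ea, oa):
            out.append(s)
        elif (sea, soa) == (oa, ea):
            out.append(
                replace(s, beta=-s.beta, effect_allele=ref.effect_allele,
                        other_allele=ref.other_allele)
            )
        else:
            raise AlleleAlignmentError(
                f"SNP {s.snp_id}: alleles {sea}/{soa} in {s.cohort_label} "
                f"cannot be aligned to {ea}/{oa} in {ref.cohort_label}"
            )
    return out


def pool_fixed_ivw(summaries: list[CohortSummary]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling.

    Weights are 1/se_i^2; the pooled beta is the weighted mean, the pooled
    variance the reciprocal total weight, and the pooled p the two-sided
    normal p of pooled_beta / pooled_se.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    b = np.array([s.beta for s in summaries])
    w = np.array([1.0 / s.se**2 for s in summaries])
    pooled_beta = float((w * b).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    z = pooled_beta / pooled_se
    res = MetaResult(
        snp_id=summaries[0].snp_id,
        pooled_beta=pooled_beta,
        pooled_se=pooled_se,
        z=float(z),
        p_pooled=float(2.0 * stats.norm.sf(abs(z))),
        scheme="ivw-beta",
    )
    if len(summaries) >= 2:
        res.q_statistic, res.q_df, res.p_het = cochran_q(summaries)
    return res


def pool_sample_size_z(summaries: list[CohortSummary]) -> MetaResult:
    """Sample-size-weighted z-score pooling (METAL's alternative scheme).

    Per-cohort z's are reconstructed as sign(beta) * Phi^{-1}(1 - p/2) and
    combined as sum(z_i sqrt(n_i)) / sqrt(sum n_i); no pooled beta/se is
    produced on this scheme.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    if any(s.n <= 0 for s in summaries):
        raise ValueError("sample-size weighting requires n > 0 for every cohort")
    zs = np.array(
        [math.copysign(stats.norm.isf(s.p / 2.0), s.beta) for s in summaries]
    )
    ns = np.array([s.n for s in summaries], dtype=float)
    z = float((zs * np.sqrt(ns)).sum() / math.sqrt(ns.sum()))
    res = MetaResult(
        snp_id=summaries[0].snp_id,
        pooled_beta=math.nan,
        pooled_se=math.nan,
        z=z,
        p_pooled=float(2.0 * stats.norm.sf(abs(z))),
        scheme="sample-size-z",
    )
    if len(summaries) >= 2:
        res.q_statistic, res.q_df, res.p_het = cochran_q(summaries)
    return res


def cochran_q(summaries: list[CohortSummary]) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q = sum w_i (beta_i - pooled)^2, chi2 with k-1 df."""
    if len(summaries) < 2:
        raise ValueError("heterogeneity needs at least two cohorts")
    b = np.array([s.beta for s in summaries])
    w = np.array([1.0 / s.se**2 for s in summaries])
    pooled = (w * b).sum() / w.sum()
    q = float((w * (b - pooled) ** 2).sum())
    df = len(summaries) - 1
    return q, df, float(stats.chi2.sf(q, df))


META_COLUMNS = [
    "SNP", "CHR", "POS", "BETA_POOLED", "SE_POOLED", "Z", "P_POOLED",
    "Q", "DF", "P_HET", "N_COHORTS",
]


def meta_scan(
    tables: list[pd.DataFrame],
    effect: str = "interaction",
    scheme: str = "ivw",
    cohort_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pool per-cohort scan tables SNP by SNP.

    ``tables`` are genome-scan results (one per cohort, as produced by
    :func:`hemegxe.association.genome_scan`).  Only SNPs present in every
    table with STATUS ok are pooled; ``effect`` selects the interaction
    (BETA_INT/P_1DF) or marginal (BETA_MARG/P_MARG) columns and ``scheme``
    the weighting (``ivw`` or ``ssz``).
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least two cohort tables")
    if effect not in ("interaction", "marginal"):
        raise ValueError(f"unknown effect: {effect!r}")
    if scheme not in ("ivw", "ssz"):
        raise ValueError(f"unknown scheme: {scheme!r}")
    if cohort_labels is None:
        cohort_labels = [f"cohort{i + 1}" for i in range(len(tables))]
    bcol, scol, pcol = (
        ("BETA_INT", "SE_INT", "P_1DF")
        if effect == "interaction"
        else ("BETA_MARG", "SE_MARG", "P_MARG")
    )
    ok_tables = [t[t["STATUS"] == "ok"].set_index("SNP") for t in tables]
    shared = set(ok_tables[0].index)
    for t in ok_tables[1:]:
        shared &= set(t.index)
    n_dropped = len(set().union(*(set(t.index) for t in ok_tables))) - len(shared)
    if n_dropped:
        log.info("meta_scan: %d SNPs not shared/ok across cohorts dropped", n_dropped)
    if not shared:
        raise ValueError("no SNP is present with ok status in every cohort")

    pool = pool_fixed_ivw if scheme == "ivw" else pool_sample_size_z
    rows = []
    for sid in shared:
        summaries = []
        for t, lab in zip(ok_tables, cohort_labels):
            r = t.loc[sid]
            summaries.append(
                CohortSummary(
                    snp_id=sid, cohort_label=lab,
                    beta=float(r[bcol]), se=float(r[scol]),
                    p=float(min(max(r[pcol], 1e-300), 1.0)),
                    n=int(r["N"]),
                    effect_allele=str(r["EA"]), other_allele=str(r["OA"]),
                    effect=effect,
                )
            )
        try:
            aligned = align_effect_alleles(summaries)
        except AlleleAlignmentError as exc:
            log.warning("%s; SNP excluded", exc)
            continue
        res = pool(aligned)
        r0 = ok_tables[0].loc[sid]
        rows.append(
            (
                sid, str(r0["CHR"]), int(r0["POS"]),
                res.pooled_beta, res.pooled_se, res.z, res.p_pooled,
                res.q_statistic, res.q_df, res.p_het, len(aligned),
            )
        )
    out = pd.DataFrame(rows, columns=META_COLUMNS)
    return out.sort_values(["CHR", "POS", "SNP"], kind="mergesort").reset_index(drop=True)
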