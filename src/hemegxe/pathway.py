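"""Matched synthetic-pathway enrichment test.

Asks whether a SNP pathway (e.g. the iron metabolism gene panel) carries
more sub-threshold association p-values than expected, by comparing the
observed count C_obs of pathway SNPs with p < T against the counts C_syn
in random "synthetic pathways" drawn from a platform-wide gene -> SNP
annotation.  Each synthetic pathway matches the template on gene count
and, gene by gene, on SNP count within a +-10% window; template genes and
SNPs are excluded from the draw.

Two empirical p-value conventions are reported for every comparison:

* ``empirical_p_strict`` — #{C_obs > C_syn_i} / N, the strict-inequality
  fraction (large when the observed pathway is enriched);
* ``empirical_p_conventional`` — (1 + #{C_syn_i >= C_obs}) / (N + 1), the
  standard permutation p (small when enriched).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneAnnotation

__all__ = [
    "PathwayDefinition",
    "SyntheticPathwaySet",
    "EnrichmentResult",
    "MatchingInfeasibleError",
    "HEME_PATHWAY_FILE",
    "load_pathway",
    "snp_count_window",
    "build_matched_pathway",
    "build_synthetic_pathway_set",
    "count_below_threshold",
    "empirical_enrichment_p",
    "pathway_enrichment_analysis",
]

log = logging.getLogger(__name__)

#: bundled iron (heme) metabolism pathway: gene -> SNPs on the array
HEME_PATHWAY_FILE = Path(__file__).parent / "data" / "heme_pathway.tsv"


class MatchingInfeasibleError(RuntimeError):
    """The annotation offers no candidate gene for some template gene."""


@dataclass
class PathwayDefinition:
    name: str
    gene_to_snps: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.gene_to_snps:
            raise ValueError("pathway must contain at least one gene")
        seen: set[str] = set()
        for g, snps in self.gene_to_snps.items():
            if not snps:
                raise ValueError(f"gene {g!r} has an empty SNP list")
            dup = seen.intersection(snps)
            if dup:
                raise ValueError(f"SNPs {sorted(dup)} appear in more than one gene")
            seen.update(snps)

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_snps)

    @property
    def all_snps(self) -> set[str]:
        return {s for snps in self.gene_to_snps.values() for s in snps}

    @property
    def snp_counts(self) -> list[int]:
        return [len(v) for v in self.gene_to_snps.values()]


@dataclass
class SyntheticPathwaySet:
    template_name: str
    pathways: list[PathwayDefinition]
    tolerance: float = 0.10
    seed: int | None = None


@dataclass
class EnrichmentResult:
    effect: str  # "main" or "interaction"
    threshold: float
    c_obs: int
    c_syn: np.ndarray
    empirical_p_strict: float
    empirical_p_conventional: float
    n_missing_observed: int = 0


def load_pathway(path: str | Path, name: str | None = None) -> PathwayDefinition:
    """Read a two-column (gene_id, snp_id) TSV into a pathway definition.

    Repeated (gene, snp) rows are collapsed with a warning — published
    pathway tables sometimes list a SNP twice under one gene.  A SNP
    assigned to two different genes is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"pathway file {path} is empty")
    if list(df.columns[:2]) != ["gene_id", "snp_id"]:
        raise ValueError(
            f"pathway file {path} must have columns gene_id, snp_id "
            f"(got {list(df.columns)})"
        )
    if df[["gene_id", "snp_id"]].isna().any().any():
        raise ValueError(f"pathway file {path} contains malformed rows")
    n_dup = int(df.duplicated(["gene_id", "snp_id"]).sum())
    if n_dup:
        log.warning(
            "pathway %s: %d duplicate (gene, snp) rows collapsed", path.name, n_dup
        )
    df = df.drop_duplicates(["gene_id", "snp_id"])
    gene_to_snps: dict[str, list[str]] = {}
    for g, sub in df.groupby("gene_id", sort=False):
        gene_to_snps[str(g)] = list(sub["snp_id"])
    pw = PathwayDefinition(name=name or path.stem, gene_to_snps=gene_to_snps)
    log.info(
        "pathway %s: %d genes, %d unique SNPs", pw.name, pw.n_genes, len(pw.all_snps)
    )
    return pw


def snp_count_window(k: int, tolerance: float) -> tuple[int, int]:
    """Admissible per-gene SNP counts for a template count k: [ceil(k(1-tol)), floor(k(1+tol))].

    Integer rounding makes small genes (k <= 4 at 10%) require an exact
    match; the window always contains k itself.
    """
    if k < 1:
        raise ValueError("template SNP count must be positive")
    if not (0.0 <= tolerance < 1.0):
        raise ValueError("tolerance must lie in [0, 1)")
    return math.ceil(k * (1.0 - tolerance)), math.floor(k * (1.0 + tolerance))


def _candidate_genes_by_count(
    annotation: GeneAnnotation, template: PathwayDefinition, excluded: set[str]
) -> dict[int, list[str]]:
    """Annotation genes eligible as synthetic-pathway members, keyed by SNP count."""
    template_genes = set(template.gene_to_snps)
    by_count: dict[int, list[str]] = {}
    for g in annotation.gene_ids:
        if g in template_genes:
            continue
        snps = annotation.gene_to_snps[g]
        if excluded.intersection(snps):
            continue
        by_count.setdefault(len(snps), []).append(g)
    return by_count


def build_matched_pathway(
    annotation: GeneAnnotation,
    template: PathwayDefinition,
    excluded: set[str],
    tolerance: float,
    rng: np.random.Generator,
    _by_count: dict[int, list[str]] | None = None,
) -> PathwayDefinition:
    """Draw one synthetic pathway matched to the template.

    For every template gene with k SNPs, one annotation gene whose SNP
    count falls inside the +-tolerance window is drawn uniformly, without
    replacement within this pathway.  Member SNPs never intersect
    ``excluded`` (typically the template's own SNPs) and template genes
    are never candidates.
    """
    by_count = (
        _by_count
        if _by_count is not None
        else _candidate_genes_by_count(annotation, template, excluded)
    )
    used: set[str] = set()
    gene_to_snps: dict[str, list[str]] = {}
    for tg, tsnps in template.gene_to_snps.items():
        k = len(tsnps)
        lo, hi = snp_count_window(k, tolerance)
        pool = [
            g
            for c in range(lo, hi + 1)
            for g in by_count.get(c, ())
            if g not in used
        ]
        if not pool:
            raise MatchingInfeasibleError(
                f"no unused annotation gene with {lo}..{hi} SNPs to match "
                f"template gene {tg!r} (k={k})"
            )
        g = pool[int(rng.integers(len(pool)))]
        used.add(g)
        gene_to_snps[g] = list(annotation.gene_to_snps[g])
    return PathwayDefinition(name=f"synthetic({template.name})", gene_to_snps=gene_to_snps)


def build_synthetic_pathway_set(
    annotation: GeneAnnotation,
    template: PathwayDefinition,
    n: int = 1000,
    tolerance: float = 0.10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SyntheticPathwaySet:
    """Draw ``n`` synthetic pathways matched to the template (genes may repeat across pathways)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    excluded = template.all_snps
    by_count = _candidate_genes_by_count(annotation, template, excluded)
    pathways = [
        build_matched_pathway(
            annotation, template, excluded, tolerance, rng, _by_count=by_count
        )
        for _ in range(n)
    ]
    return SyntheticPathwaySet(
        template_name=template.name, pathways=pathways, tolerance=tolerance, seed=seed
    )


def count_below_threshold(
    pvals: dict[str, float], snps: set[str] | list[str], threshold: float
) -> int:
    """Number of SNPs with p strictly below the threshold.

    SNPs without a p-value (missing from ``pvals`` or NaN) are dropped
    from the count with a logged tally.
    """
    missing = 0
    count = 0
    for s in snps:
        p = pvals.get(s)
        if p is None or (isinstance(p, float) and math.isnan(p)):
            missing += 1
            continue
        if p < threshold:
            count += 1
    if missing:
        log.info("count_below_threshold: %d SNPs had no p-value", missing)
    return count


def empirical_enrichment_p(c_obs: int, c_syn: np.ndarray) -> tuple[float, float]:
    """Empirical enrichment p-values from observed vs synthetic counts.

    Returns ``(p_strict, p_conventional)``: the strict fraction
    #{c_obs > c_syn_i}/N, and the permutation estimator
    (1 + #{c_syn_i >= c_obs})/(N + 1).
    """
    c_syn = np.asarray(c_syn)
    if c_syn.size == 0:
        raise ValueError("need at least one synthetic count")
    n = c_syn.size
    greater = int((c_obs > c_syn).sum())
    p_strict = greater / n
    p_conv = (1 + int((c_syn >= c_obs).sum())) / (n + 1)
    return p_strict, p_conv


def pathway_enrichment_analysis(
    results: pd.DataFrame,
    template: PathwayDefinition,
    annotation: GeneAnnotation,
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001),
    n_syn: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    effect_columns: dict[str, str] | None = None,
    tolerance: float = 0.10,
) -> list[EnrichmentResult]:
    """Full enrichment analysis over thresholds and effect types.

    ``results`` must hold a column ``SNP`` plus one p-value column per
    effect named in ``effect_columns`` (default main -> ``P_MARG``,
    interaction -> ``P_1DF``).  One synthetic-pathway set is drawn per
    call and reused across every threshold and effect, so all comparisons
    share the same null draw for a given seed.
    """
    if effect_columns is None:
        effect_columns = {"main": "P_MARG", "interaction": "P_1DF"}
    if rng is None:
        rng = np.random.default_rng(seed)
    syn_set = build_synthetic_pathway_set(
        annotation, template, n=n_syn, tolerance=tolerance, rng=rng, seed=seed
    )
    out: list[EnrichmentResult] = []
    for effect, col in effect_columns.items():
        if col not in results.columns:
            raise ValueError(f"results table lacks column {col!r} for effect {effect!r}")
        pvals = dict(zip(results["SNP"].astype(str), results[col].astype(float)))
        obs_snps = template.all_snps
        n_missing = sum(
            1
            for s in obs_snps
            if s not in pvals or math.isnan(pvals[s])
        )
        for t in thresholds:
            c_obs = count_below_threshold(pvals, obs_snps, t)
            c_syn = np.array(
                [count_below_threshold(pvals, pw.all_snps, t) for pw in syn_set.pathways]
            )
            p_strict, p_conv = empirical_enrichment_p(c_obs, c_syn)
            out.append(
                EnrichmentResult(
                    effect=effect,
                    threshold=t,
                    c_obs=c_obs,
                    c_syn=c_syn,
                    empirical_p_strict=p_strict,
                    empirical_p_conventional=p_conv,
                    n_missing_observed=n_missing,
                )
            )
    return out
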