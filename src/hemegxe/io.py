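"""File I/O: PLINK bed/bim/fam, phenotype/covariate TSV, annotation TSV.

Genotypes cross the package boundary in PLINK 1.9 binary format
(variant-major .bed with its 3-byte magic, plus .bim/.fam sidecars); the
effect (A1) allele of the .bim is the minor allele whose 0/1/2 count the
analysis models.  Everything else is tab-separated text.  Scan and meta
result tables embed provenance (seed, config hash) as ``#`` header lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, CohortData, GeneAnnotation, GenotypePanel

__all__ = [
    "PlinkFormatError",
    "write_plink",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "read_cohort",
    "write_cohort",
    "write_table",
    "read_table",
    "write_annotation",
    "read_annotation",
]

log = logging.getLogger(__name__)

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK bed, variant-major

# 2-bit codes per PLINK spec: 00 = hom A1 (2 minor alleles), 01 = missing,
# 10 = het, 11 = hom A2 (0 minor alleles)
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    """Malformed or inconsistent PLINK fileset."""


def _pack_variant(counts: np.ndarray) -> bytes:
    codes = np.empty(counts.size, dtype=np.uint8)
    for cnt, code in _COUNT_TO_CODE.items():
        codes[counts == cnt] = code
    pad = (-counts.size) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    codes = codes.reshape(-1, 4)
    packed = codes[:, 0] | (codes[:, 1] << 2) | (codes[:, 2] << 4) | (codes[:, 3] << 6)
    return packed.astype(np.uint8).tobytes()


def write_plink(
    prefix: str | Path,
    panel: GenotypePanel,
    iids: list[str] | None = None,
    status: np.ndarray | None = None,
) -> None:
    """Write a genotype panel as prefix.bed/.bim/.fam.

    The .fam phenotype column is 2 for cases and 1 for controls when
    ``status`` is given, else -9 (missing).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.genotypes.shape
    if iids is None:
        iids = [f"id{i + 1:06d}" for i in range(n)]
    if len(iids) != n:
        raise ValueError("iids length must match the genotype row count")

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        for j in range(m):
            fh.write(_pack_variant(panel.genotypes[:, j]))

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(
                f"{panel.chromosome[j]}\t{panel.snp_ids[j]}\t0\t"
                f"{int(panel.position[j])}\t{panel.effect_allele[j]}\t"
                f"{panel.other_allele[j]}\n"
            )

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, iid in enumerate(iids):
            if status is None:
                pheno = -9
            else:
                pheno = 2 if status[i] == 1 else 1
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t{pheno}\n")


def read_genotypes(prefix: str | Path) -> tuple[GenotypePanel, list[str], np.ndarray]:
    """Read prefix.bed/.bim/.fam into a panel plus subject ids and status.

    Returns ``(panel, iids, status)`` where status is 1/0/-9 per the .fam
    phenotype column.  Raises :class:`PlinkFormatError` on a bad magic
    number or a truncated .bed.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing {prefix.with_suffix(ext)}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3]!r} "
            f"(expected variant-major PLINK bed)"
        )
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: {len(raw)} bytes, expected "
            f"{expected} for {n} samples x {m} variants (truncated or corrupt)"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample-within-byte little end first
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    genotypes = _CODE_TO_COUNT[codes[:, :n]].T.copy()  # subjects x variants

    counts = genotypes.astype(float)
    counts[genotypes == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(counts, axis=0) / 2.0
    status = np.where(fam["pheno"] == 2, 1, np.where(fam["pheno"] == 1, 0, -9)).astype(
        np.int8
    )
    panel = GenotypePanel(
        snp_ids=list(bim["snp"]),
        chromosome=bim["chrom"].to_numpy(dtype=object),
        position=bim["pos"].to_numpy(),
        effect_allele=bim["a1"].to_numpy(dtype=object),
        other_allele=bim["a2"].to_numpy(dtype=object),
        maf=maf,
        genotypes=genotypes,
    )
    return panel, list(fam["iid"]), status


PHENO_BASE_COLUMNS = ["IID", "STATUS", "HEME", "BMI", "AGE"]


def write_phenotypes(path: str | Path, cohort: CohortData, iids: list[str]) -> None:
    """Phenotype/covariate TSV: IID, STATUS, HEME, BMI, AGE, EV1..EVk."""
    k = cohort.eigenvectors.shape[1]
    df = pd.DataFrame({"IID": iids, "STATUS": cohort.status})
    df["HEME"] = cohort.exposure
    df["BMI"] = cohort.bmi
    df["AGE"] = cohort.age
    for j in range(k):
        df[f"EV{j + 1}"] = cohort.eigenvectors[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    missing = [c for c in PHENO_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns {missing}")
    return df


def write_cohort(prefix: str | Path, cohort: CohortData) -> None:
    """Write a cohort as PLINK triple plus ``<prefix>.pheno.tsv``."""
    prefix = Path(prefix)
    iids = [f"{cohort.cohort_label}_{i + 1:06d}" for i in range(cohort.n_subjects)]
    write_plink(prefix, cohort.panel, iids=iids, status=cohort.status)
    write_phenotypes(prefix.parent / (prefix.name + ".pheno.tsv"), cohort, iids)


def read_cohort(
    prefix: str | Path,
    pheno_path: str | Path | None = None,
    cohort_label: str | None = None,
) -> CohortData:
    """Assemble a cohort from a PLINK triple and phenotype TSV.

    Subjects are taken in .fam order; a mismatch between .fam and
    phenotype IDs raises with the offending IDs listed.
    """
    prefix = Path(prefix)
    if pheno_path is None:
        pheno_path = prefix.parent / (prefix.name + ".pheno.tsv")
    panel, iids, _ = read_genotypes(prefix)
    pheno = read_phenotypes(pheno_path)

    fam_ids, ph_ids = set(iids), set(pheno["IID"])
    if fam_ids != ph_ids:
        only_fam = sorted(fam_ids - ph_ids)[:10]
        only_ph = sorted(ph_ids - fam_ids)[:10]
        raise ValueError(
            f"ID mismatch between {prefix.name}.fam and {Path(pheno_path).name}: "
            f"fam-only {only_fam}, pheno-only {only_ph}"
        )
    pheno = pheno.set_index("IID").loc[iids].reset_index()
    ev_cols = [c for c in pheno.columns if c.startswith("EV")]
    return CohortData(
        cohort_label=cohort_label or prefix.name,
        status=pheno["STATUS"].to_numpy(dtype=np.int8),
        exposure=pheno["HEME"].to_numpy(dtype=float),
        bmi=pheno["BMI"].to_numpy(dtype=float),
        age=pheno["AGE"].to_numpy(dtype=float),
        eigenvectors=(
            pheno[ev_cols].to_numpy(dtype=float)
            if ev_cols
            else np.empty((len(pheno), 0))
        ),
        panel=panel,
    )


def write_table(
    path: str | Path, df: pd.DataFrame, header_meta: dict[str, object] | None = None
) -> None:
    """Write a result table as TSV with ``# key=value`` provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_annotation(path: str | Path, annotation: GeneAnnotation) -> None:
    """Two-column (gene_id, snp_id) TSV."""
    rows = [
        (g, s) for g in annotation.gene_ids for s in annotation.gene_to_snps[g]
    ]
    pd.DataFrame(rows, columns=["gene_id", "snp_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["gene_id", "snp_id"]:
        raise ValueError(
            f"annotation file {path} must have columns gene_id, snp_id"
        )
    gene_to_snps: dict[str, list[str]] = {}
    gene_ids: list[str] = []
    for g, sub in df.groupby("gene_id", sort=False):
        gene_ids.append(str(g))
        gene_to_snps[str(g)] = list(sub["snp_id"])
    return GeneAnnotation(gene_ids=gene_ids, gene_to_snps=gene_to_snps)
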