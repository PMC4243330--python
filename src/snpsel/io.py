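"""Reading and writing genotype/phenotype data.

Supported dialects:

``csv``
    Plain dosage table: first column sample id, header row of SNP ids,
    cells in {0,1,2} (or {1,2,3} with ``coding='simulated123'``); missing
    cells are empty or ``NA``.
``plink_raw``
    PLINK ``--recode A`` text export (header ``FID IID PAT MAT SEX
    PHENOTYPE SNP1_A ...``); allele counts 0/1/2, missing ``NA``.
``vcf``
    VCF with diploid GT fields, one biallelic record per SNP
    ("0/0" -> 0, "0/1"/"1/0" -> 1, "1/1" -> 2, "./." -> missing).

Missing genotypes are imputed as heterozygous (dosage 1) by
:func:`impute_missing_as_het`, the convention used for chip read errors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "nan", "NaN"}


def read_genotypes(path, dialect: str = "csv", coding: str = "dosage012") -> GenotypeMatrix:
    """Read a genotype file and normalize to the internal 0/1/2 dosage.

    Parameters
    ----------
    path : file path
    dialect : {'csv', 'plink_raw', 'vcf'}
    coding : {'dosage012', 'simulated123'}
        Only honoured for the csv dialect; ``simulated123`` maps the
        genotype classes 1/2/3 onto dosages 0/1/2.
    """
    if dialect == "csv":
        return _read_csv(path, coding)
    if dialect == "plink_raw":
        return _read_plink_raw(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path, coding: str) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = df.index.astype(str).to_numpy(dtype=object)
    snp_ids = df.columns.astype(str).to_numpy(dtype=object)
    raw = df.to_numpy(dtype=object)
    values = np.zeros(raw.shape, dtype=np.int8)
    mask = np.zeros(raw.shape, dtype=bool)
    if coding == "dosage012":
        valid, offset = {"0", "1", "2"}, 0
    elif coding == "simulated123":
        valid, offset = {"1", "2", "3"}, 1
    else:
        raise ValueError(f"unknown coding {coding!r}")
    for (r, c), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in _NA_STRINGS:
            mask[r, c] = True
            values[r, c] = 1
            continue
        if cell not in valid:
            raise ValueError(
                f"invalid genotype {cell!r} for coding {coding} at row "
                f"{sample_ids[r]!r}, column {snp_ids[c]!r}"
            )
        values[r, c] = int(cell) - offset
    origin = "dosage012" if coding == "dosage012" else "simulated123"
    return GenotypeMatrix(values, mask, snp_ids, sample_ids, origin)


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_meta = [c for c in meta_cols if c not in df.columns]
    if missing_meta:
        raise ValueError(f"not a PLINK .raw file: missing columns {missing_meta}")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    # PLINK suffixes each SNP name with the counted allele (e.g. rs123_A)
    snp_ids = np.asarray(
        [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols], dtype=object
    )
    sample_ids = df["IID"].to_numpy(dtype=object)
    raw = df[snp_cols].to_numpy(dtype=object)
    values = np.zeros(raw.shape, dtype=np.int8)
    mask = np.zeros(raw.shape, dtype=bool)
    for (r, c), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in _NA_STRINGS:
            mask[r, c] = True
            values[r, c] = 1
        elif cell in {"0", "1", "2"}:
            values[r, c] = int(cell)
        else:
            raise ValueError(
                f"invalid allele count {cell!r} at sample {sample_ids[r]!r}, "
                f"column {snp_cols[c]!r}"
            )
    return GenotypeMatrix(values, mask, snp_ids, sample_ids, "plink_raw")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    columns: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    snp_ids: list[str] = []
    for variant in vcf:
        label = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise ValueError(f"multi-allelic VCF record {label!r} is not supported")
        dos = np.ones(len(sample_ids), dtype=np.int8)
        miss = np.zeros(len(sample_ids), dtype=bool)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(f"non-diploid genotype in record {label!r}")
            if min(alleles) < 0:
                miss[i] = True
            else:
                dos[i] = alleles[0] + alleles[1]
        columns.append(dos)
        masks.append(miss)
        snp_ids.append(label)
    if not columns:
        raise ValueError("VCF contains no records")
    values = np.column_stack(columns)
    mask = np.column_stack(masks)
    return GenotypeMatrix(
        values, mask, np.asarray(snp_ids, dtype=object), sample_ids, "vcf_gt"
    )


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write the csv dialect (missing as NA).

    Matrices of simulated origin are written in their native 1/2/3
    genotype-class labels (read back with ``coding='simulated123'``); all
    others as 0/1/2 dosages.
    """
    offset = 1 if G.coding_origin == "simulated123" else 0
    out = G.to_dataframe().astype(object)
    for r in range(G.n_samples):
        for c in range(G.n_snps):
            out.iat[r, c] = "NA" if G.mask[r, c] else str(int(G.values[r, c]) + offset)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_phenotype(path) -> PhenotypeVector:
    """Read a two-column csv (sample_id, value); drops missing with a log."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("phenotype csv needs sample_id and value columns")
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    keep = vals.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d samples with missing phenotype", dropped)
    if not keep.any():
        raise ValueError("no samples with observed phenotype")
    return PhenotypeVector(vals[keep].to_numpy(), ids[keep].to_numpy(dtype=object))


def write_phenotype(y: PhenotypeVector, path) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "phenotype": y.values}).to_csv(
        path, index=False
    )


def impute_missing_as_het(G: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Set every missing genotype to heterozygous (dosage 1).

    Returns the imputed matrix and the number of cells imputed.
    """
    n = G.n_missing
    values = G.values.copy()
    values[G.mask] = 1
    out = GenotypeMatrix(
        values,
        np.zeros(values.shape, dtype=bool),
        G.snp_ids.copy(),
        G.sample_ids.copy(),
        G.coding_origin,
    )
    return out, n


def drop_monomorphic(G: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Remove SNPs with no allelic variation among non-missing calls."""
    removed: list[str] = []
    keep: list[str] = []
    for j, snp in enumerate(G.snp_ids):
        col = G.values[~G.mask[:, j], j]
        if np.unique(col).size >= 2:
            keep.append(snp)
        else:
            removed.append(snp)
    if not keep:
        raise ValueError("all SNPs are monomorphic; empty design matrix")
    return G.subset_snps(keep), removed


def write_arff(G: GenotypeMatrix, y: PhenotypeVector, path, relation: str = "snps") -> None:
    """Export a numeric ARFF file (attributes = SNP dosages, class = phenotype)."""
    if G.mask.any():
        raise ValueError("impute missing genotypes before ARFF export")
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for snp in G.snp_ids:
            fh.write(f"@attribute {snp} numeric\n")
        fh.write("@attribute class numeric\n\n@data\n")
        for i in range(G.n_samples):
            row = ",".join(str(int(v)) for v in G.values[i])
            fh.write(f"{row},{float(y.values[i])!r}\n")
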