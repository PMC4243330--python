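"""Per-SNP quality-control filters: call rate, MAF and Hardy-Weinberg.

All statistics are computed on the raw (pre-imputation) matrix; the HWE
test uses non-missing genotypes only.  The HWE threshold is Bonferroni
scaled, ``hwe_alpha / n_snps_for_bonferroni``, with the divisor defaulting
to the number of SNPs present before QC (the original chip count when the
data came off a chip).  In ``simultaneous`` mode every filter is evaluated
on the input matrix and a SNP is removed if it fails any of them, so the
retained set does not depend on filter order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix


@dataclass
class QCThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 0.05
    n_snps_for_bonferroni: int | None = None  # default: SNP count of the input
    apply_mode: str = "simultaneous"

    def __post_init__(self) -> None:
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.hwe_alpha < 0:
            raise ValueError("hwe_alpha must be nonnegative")
        if self.apply_mode not in ("simultaneous", "sequential"):
            raise ValueError("apply_mode must be 'simultaneous' or 'sequential'")


@dataclass
class QCReport:
    table: pd.DataFrame  # per-SNP call_rate, maf, hwe_p, pass flags
    n_removed_call_rate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_total: int
    thresholds: QCThresholds
    removed_snp_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_removed_call_rate": self.n_removed_call_rate,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_hwe": self.n_removed_hwe,
            "n_removed_total": self.n_removed_total,
            "removed_snp_ids": list(self.removed_snp_ids),
            "thresholds": {
                "min_call_rate": self.thresholds.min_call_rate,
                "min_maf": self.thresholds.min_maf,
                "hwe_alpha": self.thresholds.hwe_alpha,
                "n_snps_for_bonferroni": self.thresholds.n_snps_for_bonferroni,
                "apply_mode": self.thresholds.apply_mode,
            },
        }


def call_rate(column: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Fraction of non-missing genotypes in a SNP column."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty genotype column")
    if mask is None:
        mask = np.isnan(np.asarray(column, dtype=float))
    return float((~mask).sum() / column.size)


def maf(column: np.ndarray) -> float:
    """Minor-allele frequency of a column of non-missing dosages."""
    column = np.asarray(column, dtype=float)
    column = column[~np.isnan(column)]
    if column.size == 0:
        raise ValueError("no non-missing genotypes")
    p_b = column.sum() / (2 * column.size)
    return float(min(p_b, 1 - p_b))


def hwe_pvalue(counts: tuple[int, int, int]) -> float:
    """Hardy-Weinberg 1-df Pearson chi-square p-value from genotype counts.

    ``counts`` are (n_AA, n_AB, n_BB).  Monomorphic columns (allele
    frequency 0 or 1) carry no disequilibrium evidence and return 1.0.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_bb + n_ab) / (2 * n)  # B-allele frequency
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc_table(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, MAF and HWE p-value on the raw matrix."""
    rows = []
    for j, snp in enumerate(G.snp_ids):
        col_mask = G.mask[:, j]
        col = G.values[~col_mask, j]
        cr = float((~col_mask).sum() / G.n_samples)
        if col.size:
            m = maf(col.astype(float))
            counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            hwe = hwe_pvalue(counts)
        else:
            m, hwe = 0.0, 1.0
        rows.append((snp, cr, m, hwe))
    return pd.DataFrame(rows, columns=["snp_id", "call_rate", "maf", "hwe_p"])


def apply_qc(G: GenotypeMatrix, t: QCThresholds) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by call rate, MAF and Bonferroni-scaled HWE."""
    m_bonf = t.n_snps_for_bonferroni or G.n_snps
    hwe_threshold = t.hwe_alpha / m_bonf

    if t.apply_mode == "simultaneous":
        table = snp_qc_table(G)
        table["pass_call_rate"] = table["call_rate"] >= t.min_call_rate
        table["pass_maf"] = table["maf"] >= t.min_maf
        table["pass_hwe"] = table["hwe_p"] >= hwe_threshold
        table["pass_all"] = (
            table["pass_call_rate"] & table["pass_maf"] & table["pass_hwe"]
        )
    else:  # sequential: each filter sees the survivors of the previous one
        table = snp_qc_table(G)
        table["pass_call_rate"] = table["call_rate"] >= t.min_call_rate
        survivors = table["pass_call_rate"]
        table["pass_maf"] = survivors & (table["maf"] >= t.min_maf)
        survivors = table["pass_maf"]
        table["pass_hwe"] = survivors & (table["hwe_p"] >= hwe_threshold)
        table["pass_all"] = table["pass_hwe"]

    removed_ids = table.loc[~table["pass_all"], "snp_id"].tolist()
    report = QCReport(
        table=table,
        n_removed_call_rate=int((~table["pass_call_rate"]).sum()),
        n_removed_maf=int((~table["pass_maf"]).sum()),
        n_removed_hwe=int((~table["pass_hwe"]).sum()),
        n_removed_total=len(removed_ids),
        thresholds=t,
        removed_snp_ids=removed_ids,
    )
    kept = table.loc[table["pass_all"], "snp_id"].tolist()
    if not kept:
        err = ValueError("QC removed every SNP")
        err.report = report  # type: ignore[attr-defined]
        raise err
    return G.subset_snps(kept), report
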