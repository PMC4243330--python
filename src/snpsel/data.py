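"""Core in-memory containers: dosage genotype matrix and phenotype vector.

Genotypes are held as allele-B dosages in {0, 1, 2} (count of the B allele:
AA=0, AB=1, BB=2) with an explicit per-cell missingness mask.  Data sets
simulated in the 1/2/3 genotype-class convention (1 homozygous reference,
2 heterozygous, 3 homozygous variant) are converted to dosages on ingest and
tagged with ``coding_origin='simulated123'`` so indicator terms defined on
genotype classes can be evaluated faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

VALID_CODING_ORIGINS = ("dosage012", "simulated123", "vcf_gt", "plink_raw")


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        raise ValueError(f"duplicate {what} identifiers")
    return arr


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-B dosage matrix with missingness mask.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_snps)
        Integer dosages; entries under ``mask`` are ignored (conventionally 1).
    mask : ndarray of bool, same shape
        True where the genotype is missing.
    snp_ids, sample_ids : sequences of unique strings.
    coding_origin : one of {'dosage012', 'simulated123', 'vcf_gt', 'plink_raw'}.
    """

    values: np.ndarray
    mask: np.ndarray
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    coding_origin: str = "dosage012"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x snps)")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        self.snp_ids = _check_unique(self.snp_ids, "SNP")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if len(self.snp_ids) != self.values.shape[1]:
            raise ValueError("snp_ids length mismatch")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if self.coding_origin not in VALID_CODING_ORIGINS:
            raise ValueError(f"unknown coding_origin {self.coding_origin!r}")
        observed = self.values[~self.mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            bad = np.argwhere(~self.mask & ((self.values < 0) | (self.values > 2)))
            r, c = bad[0]
            raise ValueError(
                f"dosage outside {{0,1,2}} at sample {self.sample_ids[r]!r}, "
                f"SNP {self.snp_ids[c]!r}: {self.values[r, c]}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def genotype_classes(self) -> np.ndarray:
        """Genotype classes in the 1/2/3 convention (dosage + 1).

        Missing cells are returned as 0; callers must honour the mask.
        """
        classes = self.values.astype(np.int16) + 1
        classes[self.mask] = 0
        return classes

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_index(snp_id)
        return self.values[:, j]

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return int(hits[0])

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            mask=self.mask[:, idx].copy(),
            snp_ids=np.asarray(list(snp_ids), dtype=object),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return replace(
            self,
            values=self.values[idx, :].copy(),
            mask=self.mask[idx, :].copy(),
            sample_ids=np.asarray(list(sample_ids), dtype=object),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Dosage DataFrame (float, NaN for missing), samples as index."""
        vals = self.values.astype(float)
        vals[self.mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.snp_ids)

    def design_matrix(self) -> np.ndarray:
        """Float dosage matrix for numeric work; requires no missing cells."""
        if self.mask.any():
            raise ValueError("matrix has missing genotypes; impute first")
        return self.values.astype(float)


@dataclass
class PhenotypeVector:
    """Continuous per-sample trait values aligned to a GenotypeMatrix."""

    values: np.ndarray
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sample_ids is None:
            self.sample_ids = np.asarray(
                [f"S{i + 1}" for i in range(len(self.values))], dtype=object
            )
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != len(self.values):
            raise ValueError("sample_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids, name="phenotype")


def align(G: GenotypeMatrix, y: PhenotypeVector) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Restrict both objects to their common samples, in genotype order."""
    common = [s for s in G.sample_ids if s in set(y.sample_ids)]
    if not common:
        raise ValueError("no samples shared between genotypes and phenotype")
    G2 = G.subset_samples(common) if len(common) != G.n_samples else G
    ypos = {s: i for i, s in enumerate(y.sample_ids)}
    yv = np.asarray([y.values[ypos[s]] for s in common])
    return G2, PhenotypeVector(yv, np.asarray(common, dtype=object))
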