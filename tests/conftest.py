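import numpy as np
import pytest

from snpsel.data import GenotypeMatrix, PhenotypeVector


def make_geno(values, mask=None, origin="dosage012", snp_ids=None, sample_ids=None):
    """Small-matrix constructor for tests."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    if snp_ids is None:
        snp_ids = [f"SNP{j + 1}" for j in range(m)]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return GenotypeMatrix(values, np.asarray(mask, dtype=bool),
                          np.asarray(snp_ids, dtype=object),
                          np.asarray(sample_ids, dtype=object), origin)


@pytest.fixture
def toy_genotypes():
    """4 samples x 3 SNPs with one missing cell."""
    values = [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 1, 1]]
    mask = [[False, False, False], [False, True, False],
            [False, False, False], [False, False, False]]
    return make_geno(values, mask)


@pytest.fixture
def toy_phenotype():
    return PhenotypeVector([1.0, 2.0, 3.0, 4.0], ["S1", "S2", "S3", "S4"])
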