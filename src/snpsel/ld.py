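"""Pairwise linkage-disequilibrium (r^2) diagnostics.

Uses the composite (genotype-correlation) estimator: r^2 between two SNPs
is the squared Pearson correlation of their dosage columns.  Phase is not
required, which suits unphased chip or simulated data.  Typical use is to
compare the mean off-diagonal r^2 of a GA-selected subset with that of its
parent group — a drop indicates that redundant markers were pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix


@dataclass
class LDMatrix:
    values: np.ndarray  # symmetric, in [0, 1], unit diagonal
    snp_ids: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.snp_ids, columns=self.snp_ids)

    def mean_offdiagonal(self) -> float:
        n = len(self.snp_ids)
        if n < 2:
            return 0.0
        off = self.values[~np.eye(n, dtype=bool)]
        return float(off.mean())


def ld_r2_matrix(G: GenotypeMatrix, snp_ids=None) -> LDMatrix:
    """Composite-LD r^2 matrix over the listed SNPs (default: all).

    Requires imputed, polymorphic columns; a constant column raises an
    error naming the SNP.
    """
    if snp_ids is None:
        snp_ids = list(G.snp_ids)
    else:
        snp_ids = list(snp_ids)
    sub = G.subset_snps(snp_ids)
    if sub.mask.any():
        raise ValueError("impute missing genotypes before computing LD")
    X = sub.values.astype(float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = snp_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"SNP {bad!r} is constant; r^2 undefined")
    corr = np.corrcoef(X, rowvar=False)
    if corr.ndim == 0:  # single SNP
        corr = np.array([[1.0]])
    r2 = np.clip(corr**2, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(r2, snp_ids)


def plot_ld(ld: LDMatrix, path=None, cmap: str = "Greens_r"):
    """Heatmap of the r^2 matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ld.values, vmin=0, vmax=1, cmap=cmap)
    fig.colorbar(im, ax=ax, label=r"$r^2$")
    ax.set_title("Pairwise LD ($r^2$)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
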