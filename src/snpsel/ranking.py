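"""Stage 1: Spearman ranking of SNPs and nested p-value groups.

Each SNP's dosage column is rank-correlated with the phenotype (Spearman's
rho, i.e. Pearson correlation of mean ranks, which handles the heavy ties
of a three-valued dosage).  Two-sided p-values use the t approximation
t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.  Optionally
p-values are Bonferroni adjusted, p_adj = min(1, m * p_raw).

Groups are nested subsets A_1 c A_2 c ... defined by an increasing ladder
of thresholds with strict inclusion p < tau.  Two stock ladders:
``REAL_LADDER`` (1e-9 ... 1e-2, eight rungs) and ``SIMULATED_LADDER``
(seventeen rungs extending to 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, PhenotypeVector

REAL_LADDER: tuple[float, ...] = tuple(10.0**-k for k in range(9, 1, -1))
SIMULATED_LADDER: tuple[float, ...] = REAL_LADDER + (
    0.1,
    0.2,
    0.3,
    0.4,
    0.5,
    0.6,
    0.7,
    0.8,
    0.9,
)


@dataclass
class SNPStats:
    snp_id: str
    rho: float
    p_raw: float
    p_adj: float


@dataclass
class GroupSeries:
    """Nested subsets of SNPs defined by p-value thresholds."""

    thresholds: tuple[float, ...]
    members: list[list[str]]  # one list of snp_ids per threshold, input order
    use_adjusted: bool

    def __post_init__(self) -> None:
        prev: set[str] = set()
        for k, mem in enumerate(self.members):
            cur = set(mem)
            if not prev <= cur:
                raise ValueError(f"group {k + 1} is not a superset of group {k}")
            prev = cur

    def __len__(self) -> int:
        return len(self.thresholds)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.members]

    def empty_flags(self) -> list[bool]:
        return [len(m) == 0 for m in self.members]

    def to_dict(self) -> dict:
        return {
            "use_adjusted": self.use_adjusted,
            "groups": [
                {"threshold": t, "snp_ids": list(m), "n_snps": len(m)}
                for t, m in zip(self.thresholds, self.members)
            ],
        }


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def spearman_stats(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    adjust_m: int | None = None,
) -> list[SNPStats]:
    """Spearman rho and p-value of every SNP column against the phenotype.

    ``adjust_m`` is the Bonferroni adjustment count (default: number of
    SNPs in ``G``).  Requires an imputed matrix and n >= 3 samples.
    Degenerate (constant) columns get rho = 0, p = 1.
    """
    if G.mask.any():
        raise ValueError("matrix has missing genotypes; impute first")
    n = G.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    yv = y.values
    if np.ptp(yv) == 0:
        raise ValueError("constant phenotype: correlation undefined")
    if len(yv) != n:
        raise ValueError("phenotype length differs from sample count")
    m = adjust_m if adjust_m is not None else G.n_snps

    ry = _rank(yv)
    ry_c = ry - ry.mean()
    ry_ss = float(ry_c @ ry_c)

    X = G.values.astype(float)
    RX = np.apply_along_axis(_rank, 0, X)
    RX_c = RX - RX.mean(axis=0)
    col_ss = np.einsum("ij,ij->j", RX_c, RX_c)
    degenerate = col_ss <= 0

    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (RX_c.T @ ry_c) / np.sqrt(col_ss * ry_ss)
    rho = np.where(degenerate, 0.0, rho)
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(degenerate, 1.0, p)

    return [
        SNPStats(snp, float(r), float(pr), bonferroni_adjust(float(pr), m))
        for snp, r, pr in zip(G.snp_ids, rho, p)
    ]


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Bonferroni family-wise adjustment: min(1, m * p_raw)."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return float(min(1.0, m * p_raw))


def stats_table(stats_list: list[SNPStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.snp_id, s.rho, s.p_raw, s.p_adj) for s in stats_list],
        columns=["snp_id", "rho", "p_raw", "p_adj"],
    )


def build_groups(
    stats_list: list[SNPStats],
    thresholds: tuple[float, ...] = REAL_LADDER,
    use_adjusted: bool = False,
) -> GroupSeries:
    """Build the nested group ladder A_k = {snp : p < tau_k} (strict <)."""
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    members = []
    for tau in thresholds:
        members.append(
            [
                s.snp_id
                for s in stats_list
                if (s.p_adj if use_adjusted else s.p_raw) < tau
            ]
        )
    return GroupSeries(thresholds, members, use_adjusted)


def resolve_ladder(name_or_values) -> tuple[float, ...]:
    """Map 'real'/'simulated' (or an iterable of floats) to a ladder."""
    if isinstance(name_or_values, str):
        if name_or_values == "real":
            return REAL_LADDER
        if name_or_values == "simulated":
            return SIMULATED_LADDER
        return tuple(float(v) for v in name_or_values.split(","))
    return tuple(float(v) for v in name_or_values)
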