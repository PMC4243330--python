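"""Model/results interface for the full two-stage selection method.

``SNPSelector`` bundles the data and the method's configuration; ``fit``
runs the four steps — (1) Spearman p-values per SNP, (2) nested p-value
groups, (3) repeated-CV SVR evaluation of each group per kernel and choice
of the best group, (4) GA pruning of that group — and returns a
``SNPSelectionResults`` carrying every intermediate table, the selected
markers and LD diagnostics, with a ``summary()`` in the style of the
group-evaluation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeVector, align
from .ga import GAConfig, GAResult, ga_select
from .io import drop_monomorphic, impute_missing_as_het
from .ld import LDMatrix, ld_r2_matrix
from .qc import QCReport, QCThresholds, apply_qc
from .ranking import GroupSeries, build_groups, resolve_ladder, spearman_stats, stats_table
from .svr import CVResult, SVRHyper, default_grids, grid_search, repeated_cv_correlation, select_best_group


def derive_seed(master: int, stream: int) -> int:
    """Deterministic 31-bit child seed for one pipeline stage."""
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0] % (2**31))


class SNPSelector:
    """Two-stage SNP selection model for a continuous phenotype.

    Parameters
    ----------
    genotypes, phenotype : aligned on shared sample ids at construction.
    qc_thresholds : optional QCThresholds applied before ranking.
    adjust : {'raw', 'bonferroni'} — which p-value defines the groups.
    ladder : 'real', 'simulated' or an increasing sequence of thresholds.
    kernels : kernel families to evaluate (subset of linear/rbf/puk).
    selection_kernel : family whose CV correlation drives group choice.
    cv_folds, cv_repeats : the repeated-CV evaluation protocol.
    tuning_repeats, grid_preset : budget of the hyperparameter search.
    tie_tolerance : groups within this mean-correlation margin of the top
        group count as ties and the smallest wins.
    min_ga_size : GA is skipped when the best group has at most this many
        SNPs (the first selection already did the pruning).
    ga_* : GA wrapper parameters (crossover/mutation rates etc.).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotype: PhenotypeVector,
        *,
        qc_thresholds: QCThresholds | None = None,
        adjust: str = "raw",
        ladder="real",
        kernels: Sequence[str] = ("linear", "rbf", "puk"),
        selection_kernel: str = "puk",
        cv_folds: int = 10,
        cv_repeats: int = 10,
        tuning_repeats: int = 1,
        grid_preset: str = "coarse",
        tie_tolerance: float = 0.005,
        min_ga_size: int = 10,
        ga_population: int = 20,
        ga_generations: int = 20,
        ga_p_crossover: float = 0.6,
        ga_p_mutation: float = 0.033,
        ga_elitism: int = 1,
        ga_fitness_folds: int = 10,
    ):
        if adjust not in ("raw", "bonferroni"):
            raise ValueError("adjust must be 'raw' or 'bonferroni'")
        if selection_kernel not in kernels:
            raise ValueError("selection_kernel must be one of the evaluated kernels")
        self.genotypes, self.phenotype = align(genotypes, phenotype)
        self.qc_thresholds = qc_thresholds
        self.adjust = adjust
        self.ladder = resolve_ladder(ladder)
        self.kernels = tuple(kernels)
        self.selection_kernel = selection_kernel
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.tuning_repeats = tuning_repeats
        self.grid_preset = grid_preset
        self.tie_tolerance = tie_tolerance
        self.min_ga_size = min_ga_size
        self.ga_population = ga_population
        self.ga_generations = ga_generations
        self.ga_p_crossover = ga_p_crossover
        self.ga_p_mutation = ga_p_mutation
        self.ga_elitism = ga_elitism
        self.ga_fitness_folds = ga_fitness_folds

    @classmethod
    def from_dataframe(
        cls, genotype_df: pd.DataFrame, phenotype: pd.Series, coding: str = "dosage012", **kwargs
    ) -> "SNPSelector":
        """Build from a samples x SNPs dosage DataFrame and a phenotype Series."""
        vals = genotype_df.to_numpy(dtype=float)
        mask = np.isnan(vals)
        vals = np.where(mask, 1.0, vals)
        offset = 1 if coding == "simulated123" else 0
        G = GenotypeMatrix(
            (vals - offset).astype(np.int8),
            mask,
            genotype_df.columns.astype(str).to_numpy(dtype=object),
            genotype_df.index.astype(str).to_numpy(dtype=object),
            "simulated123" if coding == "simulated123" else "dosage012",
        )
        y = PhenotypeVector(
            phenotype.to_numpy(dtype=float), phenotype.index.astype(str).to_numpy(dtype=object)
        )
        return cls(G, y, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "SNPSelectionResults":
        log: list[str] = []
        G, y = self.genotypes, self.phenotype
        log.append(f"input: {G.n_samples} samples x {G.n_snps} SNPs")

        qc_report = None
        if self.qc_thresholds is not None:
            G, qc_report = apply_qc(G, self.qc_thresholds)
            log.append(f"qc: {qc_report.n_removed_total} SNPs removed, {G.n_snps} remain")

        G, n_imputed = impute_missing_as_het(G)
        if n_imputed:
            log.append(f"imputation: {n_imputed} missing genotypes set to heterozygote")
        G, monomorphic = drop_monomorphic(G)
        if monomorphic:
            log.append(f"monomorphic: {len(monomorphic)} SNPs removed, {G.n_snps} remain")

        stats = spearman_stats(G, y)
        groups = build_groups(stats, self.ladder, use_adjusted=self.adjust == "bonferroni")
        log.append(
            f"ranking: groups of sizes {groups.sizes()} on "
            f"{'adjusted' if self.adjust == 'bonferroni' else 'raw'} p-values"
        )

        X_full = G.design_matrix()
        yv = y.values
        col_of = {s: j for j, s in enumerate(G.snp_ids)}
        cv_seed = derive_seed(seed, 1)

        evaluations: dict[str, list[CVResult | None]] = {f: [] for f in self.kernels}
        tuned: dict[str, list[SVRHyper | None]] = {f: [] for f in self.kernels}
        cache: dict[tuple[str, tuple[str, ...]], tuple[SVRHyper, CVResult]] = {}
        for family in self.kernels:
            for mem in groups.members:
                if not mem:
                    evaluations[family].append(None)
                    tuned[family].append(None)
                    continue
                key = (family, tuple(mem))
                if key not in cache:
                    grid = default_grids(
                        family, float(np.std(yv)), preset=self.grid_preset, n_features=len(mem)
                    )
                    Xg = X_full[:, [col_of[s] for s in mem]]
                    best, _, _ = grid_search(
                        Xg, yv, grid, k=self.cv_folds, r=self.tuning_repeats, seed=cv_seed
                    )
                    res = repeated_cv_correlation(
                        Xg, yv, best, k=self.cv_folds, r=self.cv_repeats, seed=cv_seed
                    )
                    cache[key] = (best, res)
                best, res = cache[key]
                tuned[family].append(best)
                evaluations[family].append(res)
        sel_evals = [
            ev if ev is not None else CVResult([0.0], 0.0, 0.0, self.cv_folds, 0, cv_seed)
            for ev in evaluations[self.selection_kernel]
        ]
        best_idx = select_best_group(groups, sel_evals, self.tie_tolerance)
        best_members = groups.members[best_idx]
        best_hyper = tuned[self.selection_kernel][best_idx]
        log.append(
            f"first selection: group {best_idx + 1} (p < {groups.thresholds[best_idx]:g}) "
            f"with {len(best_members)} SNPs, mean r = {sel_evals[best_idx].mean:.3f}"
        )

        ga_result: GAResult | None = None
        ga_skipped_reason = None
        if len(best_members) <= self.min_ga_size:
            ga_skipped_reason = (
                f"best group has {len(best_members)} SNPs (<= min_ga_size="
                f"{self.min_ga_size}); the first selection is already small"
            )
            log.append(f"ga: skipped — {ga_skipped_reason}")
            selected = list(best_members)
        else:
            config = GAConfig(
                population_size=self.ga_population,
                generations=self.ga_generations,
                p_crossover=self.ga_p_crossover,
                p_mutation_per_bit=self.ga_p_mutation,
                elitism_count=self.ga_elitism,
                fitness_folds=self.ga_fitness_folds,
                seed=derive_seed(seed, 2),
                svr_hyper=best_hyper,
            )
            Xg = X_full[:, [col_of[s] for s in best_members]]
            ga_result = ga_select(Xg, yv, best_members, config)
            selected = ga_result.selected_snp_ids
            log.append(
                f"ga: {len(best_members)} -> {len(selected)} SNPs, "
                f"CV MSE {ga_result.best_fitness:.4g}"
            )

        ld_before = ld_r2_matrix(G, best_members) if len(best_members) >= 1 else None
        ld_after = ld_r2_matrix(G, selected) if selected else None
        if ld_before is not None and ld_after is not None:
            log.append(
                f"ld: mean off-diagonal r^2 {ld_before.mean_offdiagonal():.4f} "
                f"-> {ld_after.mean_offdiagonal():.4f}"
            )

        return SNPSelectionResults(
            model=self,
            seed=seed,
            genotypes=G,
            phenotype=y,
            qc_report=qc_report,
            n_imputed=n_imputed,
            monomorphic_removed=monomorphic,
            stats=stats_table(stats),
            groups=groups,
            evaluations=evaluations,
            tuned_hypers=tuned,
            best_group_index=best_idx,
            best_group_snp_ids=list(best_members),
            best_hyper=best_hyper,
            ga_result=ga_result,
            ga_skipped_reason=ga_skipped_reason,
            selected_snp_ids=list(selected),
            ld_before=ld_before,
            ld_after=ld_after,
            log=log,
        )


@dataclass
class SNPSelectionResults:
    """Everything the fit produced, with tabular views and a summary."""

    model: SNPSelector
    seed: int
    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    qc_report: QCReport | None
    n_imputed: int
    monomorphic_removed: list[str]
    stats: pd.DataFrame
    groups: GroupSeries
    evaluations: dict[str, list[CVResult | None]]
    tuned_hypers: dict[str, list[SVRHyper | None]]
    best_group_index: int
    best_group_snp_ids: list[str]
    best_hyper: SVRHyper | None
    ga_result: GAResult | None
    ga_skipped_reason: str | None
    selected_snp_ids: list[str]
    ld_before: LDMatrix | None
    ld_after: LDMatrix | None
    log: list[str] = field(default_factory=list)

    def evaluation_table(self) -> pd.DataFrame:
        """Per-group, per-kernel mean (SD) CV correlations."""
        rows = []
        for k, (tau, mem) in enumerate(zip(self.groups.thresholds, self.groups.members)):
            row = {"group": k + 1, "threshold": tau, "n_snps": len(mem)}
            for family in self.model.kernels:
                res = self.evaluations[family][k]
                row[f"{family}_mean"] = np.nan if res is None else res.mean
                row[f"{family}_sd"] = np.nan if res is None else res.sd
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Two-stage SNP selection (Spearman ranking + SVR groups + GA wrapper)",
            "=" * 70,
            f"samples: {self.genotypes.n_samples}   SNPs after preprocessing: "
            f"{self.genotypes.n_snps}",
            f"p-values: {'Bonferroni-adjusted' if self.groups.use_adjusted else 'raw'}"
            f"   CV: {self.model.cv_folds}-fold x {self.model.cv_repeats} repeats"
            f"   seed: {self.seed}",
            "",
            "group  threshold   n_snps  " + "  ".join(f"{f:>14s}" for f in self.model.kernels),
        ]
        for k, (tau, mem) in enumerate(zip(self.groups.thresholds, self.groups.members)):
            cells = []
            for family in self.model.kernels:
                res = self.evaluations[family][k]
                cells.append("      --      " if res is None else f"{res.mean:6.2f}({res.sd:4.2f}) ")
            marker = " <- best" if k == self.best_group_index else ""
            lines.append(
                f"{k + 1:>5d}  {tau:<10.2g}  {len(mem):>6d}  " + "  ".join(cells) + marker
            )
        lines.append("")
        if self.ga_result is not None:
            lines.append(
                f"GA second selection: {len(self.best_group_snp_ids)} -> "
                f"{len(self.selected_snp_ids)} SNPs (CV MSE {self.ga_result.best_fitness:.4g})"
            )
        else:
            lines.append(f"GA second selection skipped: {self.ga_skipped_reason}")
        if self.ld_before is not None and self.ld_after is not None:
            lines.append(
                f"mean off-diagonal LD r^2: before GA {self.ld_before.mean_offdiagonal():.4f}, "
                f"after GA {self.ld_after.mean_offdiagonal():.4f}"
            )
        lines.append(f"selected SNPs: {', '.join(self.selected_snp_ids[:20])}"
                     + (" ..." if len(self.selected_snp_ids) > 20 else ""))
        return "\n".join(lines)
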