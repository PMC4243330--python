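"""File-level orchestration of the selection pipeline.

``run_pipeline`` executes ingest -> optional QC -> imputation -> ranking ->
group evaluation -> best-group choice -> GA second selection -> LD
diagnostics, persisting every intermediate product (stats.csv, groups.json,
group_evaluations.csv, ga_result.json, ld_before.csv, ld_after.csv,
run.log and a config echo with the resolved child seeds) so each reported
number can be recomputed from files.  A stage failure aborts with the
stage name; whatever was produced up to that point stays on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .data import GenotypeMatrix, PhenotypeVector
from .io import read_genotypes, read_phenotype
from .model import SNPSelector, derive_seed
from .qc import QCThresholds
from .simulate import SimSpec, simulate_dataset


@dataclass
class PipelineConfig:
    """One reproducible run: exactly one input source plus method settings."""

    genotype_path: str | None = None
    genotype_dialect: str = "csv"
    genotype_coding: str = "dosage012"
    phenotype_path: str | None = None
    sim_spec: SimSpec | None = None
    qc: QCThresholds | None = None
    adjust: str = "raw"
    ladder: str = "real"
    kernels: tuple[str, ...] = ("linear", "rbf", "puk")
    selection_kernel: str = "puk"
    cv_folds: int = 10
    cv_repeats: int = 10
    tuning_repeats: int = 1
    grid_preset: str = "coarse"
    tie_tolerance: float = 0.005
    min_ga_size: int = 10
    ga_population: int = 20
    ga_generations: int = 20
    ga_p_crossover: float = 0.6
    ga_p_mutation: float = 0.033
    ga_elitism: int = 1
    ga_fitness_folds: int = 10
    master_seed: int = 0
    outdir: str = "snpsel_run"

    def __post_init__(self) -> None:
        file_input = self.genotype_path is not None and self.phenotype_path is not None
        sim_input = self.sim_spec is not None
        if file_input == sim_input:
            raise ValueError(
                "configure exactly one input source: genotype+phenotype paths "
                "or a simulation spec"
            )

    def echo(self) -> dict:
        d = {
            "genotype_path": self.genotype_path,
            "genotype_dialect": self.genotype_dialect,
            "genotype_coding": self.genotype_coding,
            "phenotype_path": self.phenotype_path,
            "sim_spec": None if self.sim_spec is None else self.sim_spec.to_dict(),
            "adjust": self.adjust,
            "ladder": self.ladder,
            "kernels": list(self.kernels),
            "selection_kernel": self.selection_kernel,
            "cv_folds": self.cv_folds,
            "cv_repeats": self.cv_repeats,
            "tuning_repeats": self.tuning_repeats,
            "grid_preset": self.grid_preset,
            "tie_tolerance": self.tie_tolerance,
            "min_ga_size": self.min_ga_size,
            "ga": {
                "population": self.ga_population,
                "generations": self.ga_generations,
                "p_crossover": self.ga_p_crossover,
                "p_mutation": self.ga_p_mutation,
                "elitism": self.ga_elitism,
                "fitness_folds": self.ga_fitness_folds,
            },
            "master_seed": self.master_seed,
            "resolved_seeds": {
                "cv": derive_seed(self.master_seed, 1),
                "ga": derive_seed(self.master_seed, 2),
            },
            "qc": None
            if self.qc is None
            else {
                "min_call_rate": self.qc.min_call_rate,
                "min_maf": self.qc.min_maf,
                "hwe_alpha": self.qc.hwe_alpha,
                "n_snps_for_bonferroni": self.qc.n_snps_for_bonferroni,
                "apply_mode": self.qc.apply_mode,
            },
            "outdir": self.outdir,
        }
        return d


def _load_inputs(config: PipelineConfig) -> tuple[GenotypeMatrix, PhenotypeVector]:
    if config.sim_spec is not None:
        return simulate_dataset(config.sim_spec)
    G = read_genotypes(config.genotype_path, config.genotype_dialect, config.genotype_coding)
    y = read_phenotype(config.phenotype_path)
    return G, y


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full method and persist all artifacts under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def _persist_log() -> None:
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    (outdir / "config.json").write_text(json.dumps(config.echo(), indent=2))

    stage = "ingest"
    try:
        G, y = _load_inputs(config)
        log_lines.append(f"[ingest] {G.n_samples} samples x {G.n_snps} SNPs")

        stage = "fit"
        model = SNPSelector(
            G,
            y,
            qc_thresholds=config.qc,
            adjust=config.adjust,
            ladder=config.ladder,
            kernels=config.kernels,
            selection_kernel=config.selection_kernel,
            cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats,
            tuning_repeats=config.tuning_repeats,
            grid_preset=config.grid_preset,
            tie_tolerance=config.tie_tolerance,
            min_ga_size=config.min_ga_size,
            ga_population=config.ga_population,
            ga_generations=config.ga_generations,
            ga_p_crossover=config.ga_p_crossover,
            ga_p_mutation=config.ga_p_mutation,
            ga_elitism=config.ga_elitism,
            ga_fitness_folds=config.ga_fitness_folds,
        )
        results = model.fit(seed=config.master_seed)
        log_lines.extend(f"[fit] {line}" for line in results.log)

        stage = "persist"
        results.stats.to_csv(outdir / "stats.csv", index=False)
        (outdir / "groups.json").write_text(json.dumps(results.groups.to_dict(), indent=2))
        results.evaluation_table().to_csv(outdir / "group_evaluations.csv", index=False)
        if results.qc_report is not None:
            (outdir / "qc_report.json").write_text(
                json.dumps(results.qc_report.to_dict(), indent=2)
            )
        ga_payload = {
            "skipped": results.ga_result is None,
            "reason": results.ga_skipped_reason,
            "best_group_index": results.best_group_index + 1,
            "best_group_snp_ids": results.best_group_snp_ids,
            "selected_snp_ids": results.selected_snp_ids,
        }
        if results.ga_result is not None:
            ga_payload["result"] = results.ga_result.to_dict()
        (outdir / "ga_result.json").write_text(json.dumps(ga_payload, indent=2))
        if results.ld_before is not None:
            results.ld_before.to_dataframe().to_csv(outdir / "ld_before.csv")
        if results.ld_after is not None:
            results.ld_after.to_dataframe().to_csv(outdir / "ld_after.csv")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        _persist_log()
    except Exception as exc:
        log_lines.append(f"[{stage}] FAILED: {exc}")
        _persist_log()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "outdir": str(outdir),
        "best_group_index": results.best_group_index + 1,
        "n_selected": len(results.selected_snp_ids),
        "selected_snp_ids": results.selected_snp_ids,
        "ga_skipped": results.ga_result is None,
        "results": results,
    }
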