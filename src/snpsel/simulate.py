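"""Genotype/phenotype simulators used as the package's test bed.

Genotypes: each SNP j gets a minor-allele frequency q_j ~ Uniform(maf_low,
maf_high); genotype classes (1, 2, 3) = (hom. reference, heterozygote,
hom. variant) are drawn i.i.d. per subject under Hardy-Weinberg proportions
((1-q)^2, 2q(1-q), q^2).  SNPs are sampled independently, so linkage
disequilibrium arises only from finite-sample noise.

Phenotypes: a linear model on binary indicator terms,

    Y_i = beta_0 + sum_k beta_k * L_k(i) + e_i,   e_i ~ N(0, error_sd^2),

where each L_k is a conjunction of genotype-class conditions, possibly
negated (e.g. "SNP4 is not heterozygous AND SNP3 is not homozygous
reference").  Two stock designs are provided:

* additive: 1,000 SNPs x 250 subjects; seven single-SNP terms on SNPs
  1, 10, 20, 30, 40, 50, 60 with effects (200, 200, 200, 900, 200, 200,
  200) and noise SD 5;
* epistatic: 10,000 SNPs x 600 subjects; terms
  L1 = [SNP4 != 2 and SNP3 != 1] (effect 150), L2 = [SNP5 == 3]
  (effect 150), L3 = [SNP12 != 1 and SNP9 == 3] (effect 40), noise SD 1.

One master seed is split into independent genotype and noise streams, so
the same genotypes can be reused across phenotype redraws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector


@dataclass(frozen=True)
class Condition:
    """Atomic genotype-class condition on one SNP (1-based index)."""

    snp_index: int
    genotype_class: int
    negated: bool = False

    def __post_init__(self) -> None:
        if self.genotype_class not in (1, 2, 3):
            raise ValueError("genotype_class must be 1, 2 or 3")
        if self.snp_index < 1:
            raise ValueError("snp_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class IndicatorTerm:
    """Conjunction of genotype-class conditions; evaluates to 0/1 per subject."""

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("an indicator term needs at least one condition")

    @classmethod
    def single(cls, snp_index: int, genotype_class: int, negated: bool = False):
        return cls((Condition(snp_index, genotype_class, negated),))

    def evaluate(self, G: GenotypeMatrix) -> np.ndarray:
        """0/1 vector over subjects; raises if a SNP index is out of range."""
        classes = G.genotype_classes()
        out = np.ones(G.n_samples, dtype=bool)
        for cond in self.conditions:
            j = cond.snp_index - 1
            if j >= G.n_snps:
                raise IndexError(
                    f"indicator term references SNP{cond.snp_index} but the "
                    f"matrix has only {G.n_snps} SNPs"
                )
            hit = classes[:, j] == cond.genotype_class
            out &= ~hit if cond.negated else hit
        return out.astype(float)


def additive_terms() -> list[IndicatorTerm]:
    """The seven single-SNP terms of the additive design."""
    spec = [(1, 2), (10, 1), (20, 3), (30, 3), (40, 3), (50, 2), (60, 2)]
    return [IndicatorTerm.single(i, g) for i, g in spec]


def epistatic_terms() -> list[IndicatorTerm]:
    """The three terms of the epistatic design (two are conjunctions)."""
    return [
        IndicatorTerm((Condition(4, 2, negated=True), Condition(3, 1, negated=True))),
        IndicatorTerm.single(5, 3),
        IndicatorTerm((Condition(12, 1, negated=True), Condition(9, 3))),
    ]


@dataclass
class SimSpec:
    """Full description of one simulated data set."""

    n_subjects: int
    n_snps: int
    maf_low: float = 0.10
    maf_high: float = 0.40
    model: str = "additive"
    betas: tuple[float, ...] = ()
    error_sd: float = 1.0
    causal_terms: tuple[IndicatorTerm, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.model not in ("additive", "epistatic"):
            raise ValueError("model must be 'additive' or 'epistatic'")
        if self.error_sd < 0:
            raise ValueError("error_sd must be nonnegative")
        if len(self.betas) != len(self.causal_terms) + 1:
            raise ValueError("need one beta per causal term plus the intercept")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_snps": self.n_snps,
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
            "model": self.model,
            "betas": list(self.betas),
            "error_sd": self.error_sd,
            "causal_terms": [
                [
                    {
                        "snp_index": c.snp_index,
                        "genotype_class": c.genotype_class,
                        "negated": c.negated,
                    }
                    for c in term.conditions
                ]
                for term in self.causal_terms
            ],
            "seed": self.seed,
        }


def additive_sim_spec(seed: int = 0, n_subjects: int = 250, n_snps: int = 1000) -> SimSpec:
    """Stock additive design: seven main effects, one of them large (900)."""
    return SimSpec(
        n_subjects=n_subjects,
        n_snps=n_snps,
        model="additive",
        betas=(0.0, 200.0, 200.0, 200.0, 900.0, 200.0, 200.0, 200.0),
        error_sd=5.0,
        causal_terms=tuple(additive_terms()),
        seed=seed,
    )


def epistatic_sim_spec(seed: int = 0, n_subjects: int = 600, n_snps: int = 10000) -> SimSpec:
    """Stock epistatic design: two interaction terms plus one main effect."""
    return SimSpec(
        n_subjects=n_subjects,
        n_snps=n_snps,
        model="epistatic",
        betas=(0.0, 150.0, 150.0, 40.0),
        error_sd=1.0,
        causal_terms=tuple(epistatic_terms()),
        seed=seed,
    )


def _split_rng(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    geno_ss, err_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(geno_ss), np.random.default_rng(err_ss)


def simulate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_low: float = 0.10,
    maf_high: float = 0.40,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Draw a genotype matrix under HWE with per-SNP uniform MAF.

    ``maf_low == maf_high`` fixes every SNP's MAF (useful in tests).
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else _split_rng(seed)[0]
    q = rng.uniform(maf_low, maf_high, size=n_snps)
    p_het = 2 * q * (1 - q)
    p_hom_var = q**2
    u = rng.random(size=(n_subjects, n_snps))
    # classes: 1 with prob (1-q)^2, 2 with prob 2q(1-q), 3 with prob q^2
    dosage = (u < p_hom_var + p_het).astype(np.int8) + (u < p_hom_var).astype(np.int8)
    snp_ids = np.asarray([f"SNP{j + 1}" for j in range(n_snps)], dtype=object)
    sample_ids = np.asarray([f"S{i + 1}" for i in range(n_subjects)], dtype=object)
    return GenotypeMatrix(
        dosage, np.zeros(dosage.shape, dtype=bool), snp_ids, sample_ids, "simulated123"
    )


def _indicator_design(G: GenotypeMatrix, terms) -> np.ndarray:
    return np.column_stack([t.evaluate(G) for t in terms])


def _simulate_phenotype(G: GenotypeMatrix, spec: SimSpec, rng) -> PhenotypeVector:
    L = _indicator_design(G, spec.causal_terms)
    betas = np.asarray(spec.betas, dtype=float)
    mean = betas[0] + L @ betas[1:]
    noise = rng.normal(0.0, spec.error_sd, size=G.n_samples) if spec.error_sd else 0.0
    return PhenotypeVector(mean + noise, G.sample_ids.copy())


def simulate_phenotype_additive(
    G: GenotypeMatrix, spec: SimSpec, rng: np.random.Generator | None = None
) -> PhenotypeVector:
    if spec.model != "additive":
        raise ValueError("spec.model must be 'additive'")
    if rng is None:
        rng = _split_rng(spec.seed)[1]
    return _simulate_phenotype(G, spec, rng)


def simulate_phenotype_epistatic(
    G: GenotypeMatrix, spec: SimSpec, rng: np.random.Generator | None = None
) -> PhenotypeVector:
    if spec.model != "epistatic":
        raise ValueError("spec.model must be 'epistatic'")
    if rng is None:
        rng = _split_rng(spec.seed)[1]
    return _simulate_phenotype(G, spec, rng)


def simulate_dataset(spec: SimSpec) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes and phenotype from one master seed (independent sub-streams)."""
    geno_rng, err_rng = _split_rng(spec.seed)
    G = simulate_genotypes(
        spec.n_subjects, spec.n_snps, spec.maf_low, spec.maf_high, geno_rng
    )
    y = _simulate_phenotype(G, spec, err_rng)
    return G, y


def true_signal(G: GenotypeMatrix, spec: SimSpec) -> np.ndarray:
    """Noise-free phenotype mean for each subject (for diagnostics)."""
    betas = np.asarray(spec.betas, dtype=float)
    return betas[0] + _indicator_design(G, spec.causal_terms) @ betas[1:]
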