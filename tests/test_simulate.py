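import numpy as np
import pytest

from snpsel.simulate import (
    Condition,
    IndicatorTerm,
    SimSpec,
    additive_sim_spec,
    additive_terms,
    epistatic_sim_spec,
    epistatic_terms,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotype_additive,
    simulate_phenotype_epistatic,
    true_signal,
)

from conftest import make_geno


class TestGenotypeSimulation:
    def test_same_seed_reproduces_matrix(self):
        a = simulate_genotypes(40, 60, seed=11)
        b = simulate_genotypes(40, 60, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        assert list(a.snp_ids) == list(b.snp_ids)

    def test_degenerate_maf_half_gives_hwe_class_frequencies(self):
        # q = 0.5 fixed: expected class probabilities (0.25, 0.5, 0.25)
        G = simulate_genotypes(20000, 5, maf_low=0.5, maf_high=0.5, seed=3)
        freqs = [(G.values == d).mean() for d in (0, 1, 2)]
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / G.values.size)
        for f, expected, s in zip(freqs, (0.25, 0.5, 0.25), se):
            assert abs(f - expected) < 4 * s

    def test_homozygous_variant_rate_matches_binomial_oracle(self):
        # q fixed at 0.2 -> P(class 3) = q^2 = 0.04; binomial SE at n draws
        n = 50000
        G = simulate_genotypes(n, 1, maf_low=0.2, maf_high=0.2, seed=7)
        p_hat = (G.values[:, 0] == 2).mean()
        se = np.sqrt(0.04 * 0.96 / n)
        assert abs(p_hat - 0.04) < 3 * se

    def test_empirical_maf_stays_within_configured_band(self):
        n = 400
        G = simulate_genotypes(n, 200, maf_low=0.10, maf_high=0.40, seed=5)
        dosage = G.values.astype(float)
        p_b = dosage.mean(axis=0) / 2
        maf = np.minimum(p_b, 1 - p_b)
        se = np.sqrt(0.40 * 0.60 / (2 * n))  # widest SE in the band
        assert np.all(maf > 0.10 - 4 * se)
        assert np.all(maf < 0.40 + 4 * se)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, maf_low=0.4, maf_high=0.1)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, maf_low=0.0, maf_high=0.3)


def _classes_matrix(n_snps, assignments, n_samples=1):
    """Genotype matrix (simulated123) with explicit classes, default class 1."""
    classes = np.ones((n_samples, n_snps), dtype=int)
    for (i, snp_1based), cls in assignments.items():
        classes[i, snp_1based - 1] = cls
    return make_geno(classes - 1, origin="simulated123")


class TestAdditivePhenotype:
    """Expected values of the seven-term additive model, noise off."""

    @pytest.mark.parametrize(
        "assignments,expected",
        [
            ({(0, 30): 3}, 900.0),          # only the large effect fires
            ({}, 0.0),                       # no condition met (intercept 0)
            ({(0, 1): 2, (0, 40): 3}, 400.0),  # two 200-effects fire
        ],
    )
    def test_expected_value_cases(self, assignments, expected):
        G = _classes_matrix(60, assignments)
        # class 1 everywhere satisfies L2 = [SNP10 == 1]; force it off
        if (0, 10) not in assignments:
            G.values[0, 9] = 1  # class 2
        y = simulate_phenotype_additive(G, _with_zero_noise(additive_sim_spec()))
        assert y.values[0] == pytest.approx(expected)

    def test_reference_subject_scores_the_hom10_effect(self):
        # all-class-1 subject fires only L2 = [SNP10 == 1]
        G = _classes_matrix(60, {})
        y = simulate_phenotype_additive(G, _with_zero_noise(additive_sim_spec()))
        assert y.values[0] == pytest.approx(200.0)

    def test_term_outside_matrix_raises(self):
        G = _classes_matrix(30, {})
        with pytest.raises(IndexError, match="SNP40"):
            simulate_phenotype_additive(G, _with_zero_noise(additive_sim_spec()))


def _with_zero_noise(spec):
    return SimSpec(
        n_subjects=spec.n_subjects,
        n_snps=spec.n_snps,
        maf_low=spec.maf_low,
        maf_high=spec.maf_high,
        model=spec.model,
        betas=spec.betas,
        error_sd=0.0,
        causal_terms=spec.causal_terms,
        seed=spec.seed,
    )


class TestEpistaticPhenotype:
    @pytest.mark.parametrize(
        "assignments,expected",
        [
            # SNP5 hom variant fires L2 alone; SNP4 het blocks L1; SNP12 ref blocks L3
            ({(0, 5): 3, (0, 4): 2, (0, 12): 1}, 150.0),
            # L1 fires (SNP4 != 2 and SNP3 != 1); L3 fires (SNP12 != 1, SNP9 == 3)
            ({(0, 4): 1, (0, 3): 3, (0, 9): 3, (0, 12): 2}, 190.0),
            # nothing fires: SNP4 het, SNP12 ref, SNP5 not hom variant
            ({(0, 4): 2, (0, 12): 1, (0, 5): 2}, 0.0),
        ],
    )
    def test_conjunction_and_negation_semantics(self, assignments, expected):
        G = _classes_matrix(12, assignments)
        y = simulate_phenotype_epistatic(G, _with_zero_noise(epistatic_sim_spec()))
        assert y.values[0] == pytest.approx(expected)

    def test_model_mismatch_rejected(self):
        G = _classes_matrix(12, {})
        with pytest.raises(ValueError):
            simulate_phenotype_additive(G, epistatic_sim_spec())


class TestIndicatorTerm:
    def test_negated_condition(self):
        term = IndicatorTerm((Condition(1, 2, negated=True),))
        G = make_geno(np.array([[0], [1], [2]]), origin="simulated123")
        np.testing.assert_array_equal(term.evaluate(G), [1.0, 0.0, 1.0])

    def test_requires_a_condition(self):
        with pytest.raises(ValueError):
            IndicatorTerm(())

    def test_stock_designs_have_expected_shapes(self):
        assert len(additive_terms()) == 7
        assert len(epistatic_terms()) == 3
        assert len(epistatic_terms()[0].conditions) == 2


class TestSignalToNoise:
    def test_zero_noise_phenotype_is_deterministic_in_genotype(self):
        spec = _with_zero_noise(additive_sim_spec(seed=21, n_subjects=120, n_snps=80))
        G, y = simulate_dataset(spec)
        np.testing.assert_allclose(y.values, true_signal(G, spec))

    def test_true_indicator_regression_explains_additive_design(self):
        # OLS of Y on the true indicator design: R^2 > 0.99 (beta 900 vs SD 5)
        spec = additive_sim_spec(seed=13)
        G, y = simulate_dataset(spec)
        L = np.column_stack([t.evaluate(G) for t in spec.causal_terms])
        X = np.column_stack([np.ones(len(y.values)), L])
        coef, *_ = np.linalg.lstsq(X, y.values, rcond=None)
        resid = y.values - X @ coef
        r2 = 1 - resid.var() / y.values.var()
        assert r2 > 0.99

    def test_genotypes_reusable_across_phenotype_redraws(self):
        spec = additive_sim_spec(seed=2, n_subjects=50, n_snps=80)
        G1, _ = simulate_dataset(spec)
        G2 = simulate_genotypes(50, 80, seed=2)
        np.testing.assert_array_equal(G1.values, G2.values)
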