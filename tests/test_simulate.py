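"""Synthetic cohort generator: genotypes, LD, outcome model, perturbations."""

import numpy as np
import pytest
from scipy.stats import kstest

from relapsekit import (
    DuplicateErrorModel,
    SimConfig,
    SimulationError,
    inject_duplicates,
    inject_missingness,
    simulate_cohort,
    simulate_imputed_dosages,
)
from relapsekit.assoc import logistic_scan


class TestSimConfigValidation:
    def test_bad_maf_range(self):
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.1, 0.6))

    def test_bad_rho(self):
        with pytest.raises(ValueError):
            SimConfig(ld_rho=1.0)

    def test_too_many_causal(self):
        with pytest.raises(ValueError):
            SimConfig(n_variants=10, n_causal=11)


class TestSimulateCohort:
    def test_reproducible(self):
        cfg = SimConfig(n_samples=60, n_variants=100, seed=4, n_causal=5,
                        causal_beta=0.5, prevalence_target=0.31)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a[0].dosages, b[0].dosages)
        assert np.array_equal(a[0].call_gq, b[0].call_gq)
        assert a[1].table.equals(b[1].table)
        assert a[2] == b[2]

    def test_dosages_in_range(self, small_cohort):
        gm, _, _ = small_cohort
        assert set(np.unique(gm.dosages)).issubset({0, 1, 2})

    def test_null_intercept_zero_gives_half(self):
        cfg = SimConfig(n_samples=4000, n_variants=20, seed=8,
                        prevalence_target=None, intercept_beta0=0.0)
        _, meta, truth = simulate_cohort(cfg)
        # expit(0) = 0.5 up to binomial error
        assert truth.realized_prevalence == pytest.approx(0.5, abs=3 * 0.5 / 63)

    def test_prevalence_calibration(self):
        n = 2000
        cfg = SimConfig(n_samples=n, n_variants=50, seed=9, prevalence_target=0.31)
        _, _, truth = simulate_cohort(cfg)
        tol = 3 * np.sqrt(0.31 * 0.69 / n)
        assert truth.realized_prevalence == pytest.approx(0.31, abs=tol)

    def test_prevalence_calibration_with_effects(self):
        cfg = SimConfig(
            n_samples=3000, n_variants=60, seed=10, n_causal=6, causal_beta=0.8,
            covariate_effects={"donor_age": 0.4, "graft_type": -0.3},
            prevalence_target=0.31,
        )
        _, _, truth = simulate_cohort(cfg)
        assert truth.realized_prevalence == pytest.approx(0.31, abs=0.035)

    def test_realized_prevalence_exact_bookkeeping(self, small_cohort):
        _, meta, truth = small_cohort
        assert truth.realized_prevalence == meta.relapse.mean()

    def test_maf_close_to_target(self):
        cfg = SimConfig(n_samples=800, n_variants=300, seed=12,
                        prevalence_target=0.31, ld_rho=0.3)
        gm, _, _ = simulate_cohort(cfg)
        ss = np.random.SeedSequence(12)
        variant_ss, _ = ss.spawn(2)
        targets = np.random.default_rng(variant_ss).uniform(0.05, 0.5, 300)
        freqs = np.array([v.alt_frequency for v in gm.variants])
        tol = 4 * np.sqrt(targets * (1 - targets) / (2 * 800))
        assert np.all(np.abs(freqs - targets) <= tol)

    def test_ld_blocks_raise_adjacent_correlation(self):
        cfg = SimConfig(n_samples=10_000, n_variants=60, ld_block_size=10,
                        ld_rho=0.9, seed=13, prevalence_target=0.31)
        gm, _, _ = simulate_cohort(cfg)
        G = gm.dosages.astype(float)
        within, across = [], []
        for j in range(59):
            r = abs(np.corrcoef(G[:, j], G[:, j + 1])[0, 1])
            (within if (j % 10) != 9 else across).append(r)
        assert np.mean(within) > np.mean(across) + 0.2

    def test_null_association_pvalues_uniform(self):
        cfg = SimConfig(n_samples=500, n_variants=2000, seed=14,
                        prevalence_target=0.31, ld_rho=0.0)
        gm, meta, _ = simulate_cohort(cfg)
        X = np.ones((500, 1))
        res = logistic_scan(meta.relapse.astype(float), X,
                            gm.dosages.astype(float), prescreen=False)
        p = res.pvalue[~np.isnan(res.pvalue)]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_infeasible_prevalence_reports_range(self):
        cfg = SimConfig(
            n_samples=100, n_variants=20, seed=15, n_causal=2,
            causal_beta=[40.0, 40.0], maf_range=(0.45, 0.5),
            prevalence_target=0.01,
        )
        with pytest.raises(SimulationError, match="achievable range"):
            simulate_cohort(cfg)

    def test_sample_seed_keeps_variants_fixed(self):
        cfg = SimConfig(n_samples=80, n_variants=50, seed=16, n_causal=5,
                        causal_beta=0.7, prevalence_target=0.31)
        gm1, _, t1 = simulate_cohort(cfg)
        gm2, _, t2 = simulate_cohort(cfg, sample_seed=999)
        assert [v.id for v in gm1.variants] == [v.id for v in gm2.variants]
        assert t1.causal_indices == t2.causal_indices
        assert not np.array_equal(gm1.dosages, gm2.dosages)


class TestInjectDuplicates:
    def test_zero_error_identical(self, small_cohort):
        gm, _, _ = small_cohort
        model = DuplicateErrorModel([0], [0.0])
        dup = inject_duplicates(gm, gm.sample_ids[:3], model, seed=1)
        assert dup.n_samples == gm.n_samples + 3
        for k, s in enumerate(gm.sample_ids[:3]):
            i, j = gm.sample_index(s), gm.n_samples + k
            assert np.array_equal(dup.dosages[i], dup.dosages[j])

    def test_error_one_all_discordant(self, small_cohort):
        gm, _, _ = small_cohort
        model = DuplicateErrorModel([0], [1.0])
        dup = inject_duplicates(gm, gm.sample_ids[:2], model, seed=2)
        for k, s in enumerate(gm.sample_ids[:2]):
            i, j = gm.sample_index(s), gm.n_samples + k
            assert not np.any(dup.dosages[i] == dup.dosages[j])

    def test_unknown_sample_named(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(KeyError, match="nope"):
            inject_duplicates(gm, ["nope"], DuplicateErrorModel([0], [0.1]), seed=3)

    def test_gq_dependent_concordance_expectation(self, small_cohort):
        gm, _, _ = small_cohort
        model = DuplicateErrorModel([0, 18], [0.05, 0.001])
        ids = gm.sample_ids[:20]
        dup = inject_duplicates(gm, ids, model, seed=4)
        rows = [gm.sample_index(s) for s in ids]
        dup_rows = list(range(gm.n_samples, gm.n_samples + 20))
        concordant = dup.dosages[rows] == dup.dosages[dup_rows]
        frac_low = (gm.call_gq[rows] < 18).mean()
        expected = frac_low * 0.95 + (1 - frac_low) * 0.999
        assert concordant.mean() == pytest.approx(expected, abs=0.01)

    def test_monotonicity_validated(self):
        with pytest.raises(ValueError):
            DuplicateErrorModel([0, 18], [0.01, 0.05])


class TestInjectMissingness:
    def test_zero_counts_identity(self, small_cohort):
        gm, _, _ = small_cohort
        out = inject_missingness(gm, {0: 0, 5: 0}, seed=1)
        assert np.array_equal(out.dosages, gm.dosages)

    def test_full_column_missing(self, small_cohort):
        gm, _, _ = small_cohort
        out = inject_missingness(gm, {3: gm.n_samples}, seed=2)
        assert out.missing[:, 3].all()

    def test_exact_requested_counts(self):
        cfg = SimConfig(n_samples=151, n_variants=3, seed=17, prevalence_target=0.31)
        gm, _, _ = simulate_cohort(cfg)
        out = inject_missingness(gm, [0, 1, 151], seed=3)
        assert out.missing.sum(axis=0).tolist() == [0, 1, 151]

    def test_count_exceeding_n_rejected(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(ValueError):
            inject_missingness(gm, {0: gm.n_samples + 1}, seed=4)


class TestImputedDosages:
    def test_infinite_concentration_point_mass(self, small_cohort):
        gm, _, _ = small_cohort
        table = simulate_imputed_dosages(gm, np.inf, seed=1)
        np.testing.assert_allclose(table.sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(table.dosage, gm.dosages, atol=1e-12)

    def test_moment_arithmetic(self):
        # posterior (0.25, 0.5, 0.25): E[g]=1, E[g^2]=1.5, sd=sqrt(0.5)
        p = np.array([0.25, 0.5, 0.25])
        dosage = p[1] + 2 * p[2]
        sd = np.sqrt(p[1] + 4 * p[2] - dosage**2)
        assert dosage == pytest.approx(1.0)
        assert sd == pytest.approx(np.sqrt(0.5), abs=1e-12)
        # the generator's arithmetic agrees with the closed form
        from relapsekit.datatypes import DosageTable, VariantRecord

        table = DosageTable(
            ["s0"], [VariantRecord("1", 1, "v", "A", ("G",))],
            p.reshape(1, 1, 3), np.array([[dosage]]), np.array([[sd]]),
        )
        assert table.variant_quality()[0] == pytest.approx(sd)

    def test_mean_sd_decreases_with_concentration(self, small_cohort):
        gm, _, _ = small_cohort
        means = [
            simulate_imputed_dosages(gm, conc, seed=5).sd.mean()
            for conc in (1.0, 5.0, 25.0)
        ]
        assert means[0] > means[1] > means[2]

    def test_concentration_positive(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(ValueError):
            simulate_imputed_dosages(gm, 0.0, seed=1)

    def test_probs_sum_to_one(self, small_cohort):
        gm, _, _ = small_cohort
        table = simulate_imputed_dosages(gm, 10.0, seed=6)
        np.testing.assert_allclose(table.probs.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(table.dosage >= 0) and np.all(table.dosage <= 2)
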