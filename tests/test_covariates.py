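"""Covariate screen: PCA, scree rule, collinearity pruning, nominal screen."""

import numpy as np
import pandas as pd
import pytest

from relapsekit import (
    CohortMetadata,
    GenotypeMatrix,
    VariantRecord,
    collinearity_prune,
    compute_pcs,
    nominal_screen,
    pc_loading_report,
    select_pc_count,
)

from conftest import make_matrix, make_metadata


class TestComputePcs:
    def test_two_clusters_separated_by_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 2, (40, 30)).astype(np.int8)
        base[:20] += 1  # cluster offset along every variant
        gm = make_matrix(np.clip(base, 0, 2))
        pca = compute_pcs(gm, 3)
        pc1 = pca.scores[:, 0]
        assert abs(np.mean(pc1[:20]) - np.mean(pc1[20:])) > 2 * pc1.std() / 2
        assert pca.eigenvalues[0] > 2 * pca.eigenvalues[1]

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(2)
        gm = make_matrix(rng.integers(0, 3, (25, 15)).astype(np.int8))
        pca = compute_pcs(gm, 15)
        # standardized matrix has per-column variance n/(n-1) under ddof=1
        expected_total = 15 * 25 / 24
        assert pca.eigenvalues.sum() == pytest.approx(expected_total, rel=1e-10)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        gm = make_matrix(rng.integers(0, 3, (20, 50)).astype(np.int8))
        pca = compute_pcs(gm, 10)
        X = gm.dosages.astype(float)
        keep = X.std(axis=0) > 1e-12
        X = X[:, keep]
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        lam = np.linalg.eigvalsh(X @ X.T / (20 - 1))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, lam[:10], atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        gm = make_matrix(rng.integers(0, 3, (30, 40)).astype(np.int8))
        pca = compute_pcs(gm, 5)
        gram = pca.scores.T @ pca.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_scores_equal_matrix_times_loadings(self):
        rng = np.random.default_rng(5)
        gm = make_matrix(rng.integers(0, 3, (30, 40)).astype(np.int8))
        pca = compute_pcs(gm, 5)
        X = gm.dosages.astype(float)[:, pca.variant_indices]
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_allclose(pca.scores, X @ pca.loadings, atol=1e-8)

    def test_zero_variance_excluded(self):
        rng = np.random.default_rng(6)
        dosages = rng.integers(0, 3, (20, 10)).astype(np.int8)
        dosages[:, 4] = 1
        pca = compute_pcs(make_matrix(dosages), 3)
        assert pca.n_zero_variance == 1
        assert 4 not in pca.variant_indices

    def test_mean_imputation_of_missing(self):
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, (20, 10)).astype(np.int8)
        dosages[3, 2] = -1
        pca = compute_pcs(make_matrix(dosages), 3)
        assert np.all(np.isfinite(pca.scores))


class TestSelectPcCount:
    def test_worked_example(self):
        assert select_pc_count([10, 5, 2, 1, 1, 1, 1], tol=0.02) == 4

    def test_flat_scree(self):
        assert select_pc_count([3.0, 3.0, 3.0, 3.0]) == 1

    def test_geometric_decay_closed_form(self):
        lam = [2.0**-j for j in range(1, 16)]
        # independent evaluation of the gap rule on the closed-form sequence
        span = lam[0] - lam[-1]
        gaps = [(lam[j] - lam[j + 1]) / span for j in range(len(lam) - 1)]
        expected = next(
            k for k in range(1, len(lam)) if all(g < 0.02 for g in gaps[k - 1 :])
        )
        assert select_pc_count(lam, tol=0.02) == expected

    def test_needs_two_eigenvalues(self):
        with pytest.raises(ValueError):
            select_pc_count([1.0])

    def test_requires_sorted(self):
        with pytest.raises(ValueError):
            select_pc_count([1.0, 2.0])


class TestCollinearityPrune:
    def test_identical_columns_drop_one(self):
        rng = np.random.default_rng(8)
        age = rng.normal(50, 10, 100).round(1)
        meta = make_metadata(rng.integers(0, 2, 100), rng=rng)
        meta.table["donor_age"] = age
        meta.table["recipient_age"] = age  # identical copy
        res = collinearity_prune(meta, r_threshold=0.45)
        dropped = {d for d, _, _ in res.dropped_collinear}
        assert "recipient_age" in dropped
        triple = next(t for t in res.dropped_collinear if t[0] == "recipient_age")
        assert triple[1] == "donor_age"
        assert triple[2] == pytest.approx(1.0)

    def test_correlated_ages_keep_donor(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(400)
        donor = 49 + 12 * z
        recipient = 51 + 12 * (0.8 * z + 0.6 * rng.standard_normal(400))
        meta = make_metadata(rng.integers(0, 2, 400), rng=rng)
        meta.table["donor_age"] = donor.round(1)
        meta.table["recipient_age"] = recipient.round(1)
        res = collinearity_prune(meta, r_threshold=0.45)
        assert "donor_age" in res.kept_covariates
        assert "recipient_age" not in res.kept_covariates

    def test_nothing_dropped_below_threshold(self):
        rng = np.random.default_rng(10)
        meta = make_metadata(rng.integers(0, 2, 500), rng=rng)
        res = collinearity_prune(meta, r_threshold=0.9)
        assert res.dropped_collinear == []

    def test_no_remaining_pair_above_threshold(self):
        rng = np.random.default_rng(11)
        n = 300
        meta = make_metadata(rng.integers(0, 2, n), rng=rng)
        # engineer several entangled covariates
        base = rng.standard_normal(n)
        meta.table["donor_age"] = (49 + 10 * base).round(1)
        meta.table["recipient_age"] = (51 + 10 * (0.9 * base)).round(1)
        meta = CohortMetadata(meta.table, pcs=np.column_stack([base + 0.1 * rng.standard_normal(n)]))
        res = collinearity_prune(meta, r_threshold=0.45)
        from relapsekit.covariates import _covariate_columns, _pair_correlation

        cols = _covariate_columns(meta)
        kept = res.kept_covariates
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert _pair_correlation(cols[a], cols[b]) < 0.45


class TestNominalScreen:
    def test_strong_covariate_selected(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 300)
        meta = make_metadata(y, rng=rng)
        meta.table["donor_age"] = (49 + 10 * y + rng.standard_normal(300)).round(1)
        res = nominal_screen(meta, alpha=0.1, covariates=["donor_age", "sex"])
        assert "donor_age" in res.kept_covariates
        assert res.nominal_pvalues["donor_age"] < 1e-6

    def test_covariate_equal_to_outcome_selected(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 100)
        meta = make_metadata(y, rng=rng)
        meta.table["mirror"] = y.astype(float)
        res = nominal_screen(meta, alpha=0.1, covariates=["mirror"])
        assert "mirror" in res.kept_covariates
        assert res.flags.get("mirror") == "separation_or_extreme"

    def test_constant_covariate_flagged(self):
        rng = np.random.default_rng(14)
        meta = make_metadata(rng.integers(0, 2, 80), rng=rng)
        meta.table["constant"] = 1.0
        res = nominal_screen(meta, covariates=["constant"])
        assert "constant" not in res.kept_covariates
        assert res.flags["constant"] == "zero_variance"

    def test_alpha_one_keeps_everything_alpha_zero_none(self):
        rng = np.random.default_rng(15)
        meta = make_metadata(rng.integers(0, 2, 150), rng=rng)
        names = ["donor_age", "sex", "graft_type"]
        assert set(nominal_screen(meta, alpha=1.0, covariates=names).kept_covariates) == set(names)
        assert nominal_screen(meta, alpha=0.0, covariates=names).kept_covariates == []

    def test_null_selection_rate_near_alpha(self):
        # independent covariate: p uniform, selected w.p. ~alpha
        rng = np.random.default_rng(16)
        hits = 0
        reps = 120
        n = 400
        for _ in range(reps):
            y = rng.integers(0, 2, n)
            table = pd.DataFrame(
                {"relapse": y, "x": rng.standard_normal(n)},
                index=[f"s{i}" for i in range(n)],
            )
            res = nominal_screen(CohortMetadata(table), alpha=0.1, covariates=["x"])
            hits += "x" in res.kept_covariates
        rate = hits / reps
        assert abs(rate - 0.1) < 4 * np.sqrt(0.1 * 0.9 / reps)

    def test_determinism(self):
        rng = np.random.default_rng(17)
        meta = make_metadata(rng.integers(0, 2, 100), rng=rng)
        a = nominal_screen(meta, covariates=["donor_age", "diagnosis"])
        b = nominal_screen(meta, covariates=["donor_age", "diagnosis"])
        assert a.nominal_pvalues == b.nominal_pvalues
        assert a.kept_covariates == b.kept_covariates


class TestPcLoadingReport:
    def _pca_with_concentrated_loadings(self, m=50, chrom6=10):
        rng = np.random.default_rng(18)
        variants = []
        for j in range(m):
            if j < chrom6:
                variants.append(VariantRecord("6", 29_000_000 + j * 1000, f"v{j}", "A", ("G",)))
            else:
                variants.append(VariantRecord(str(1 + j % 5), 10_000 + j, f"v{j}", "A", ("G",)))
        loadings = np.zeros((m, 2))
        loadings[:chrom6, 0] = rng.uniform(0.5, 1.0, chrom6)
        loadings[chrom6:, 0] = rng.uniform(0.0, 0.01, m - chrom6)
        loadings[:, 1] = rng.uniform(0, 1, m)
        from relapsekit.covariates import PCAResult

        pca = PCAResult(
            scores=np.zeros((5, 2)),
            loadings=loadings,
            eigenvalues=np.array([2.0, 1.0]),
            variant_indices=np.arange(m),
        )
        return pca, variants

    def test_concentrated_block_fraction_one(self):
        pca, variants = self._pca_with_concentrated_loadings()
        rep = pc_loading_report(pca, variants, component=1, top_q=10)
        assert rep["fraction_in_region"] == 1.0
        assert rep["per_chromosome_counts"] == {"6": 10}

    def test_uniform_loadings_fraction_matches_share(self):
        rng = np.random.default_rng(19)
        m = 4000
        variants = [
            VariantRecord("6" if j < 400 else "1",
                          29_000_000 + j if j < 400 else 10_000 + j,
                          f"v{j}", "A", ("G",))
            for j in range(m)
        ]
        from relapsekit.covariates import PCAResult

        pca = PCAResult(
            scores=np.zeros((5, 1)),
            loadings=rng.uniform(0, 1, (m, 1)),
            eigenvalues=np.array([1.0]),
            variant_indices=np.arange(m),
        )
        rep = pc_loading_report(pca, variants, component=1, top_q=1000)
        assert rep["fraction_in_region"] == pytest.approx(0.1, abs=0.04)

    def test_top_q_truncation_noted(self):
        pca, variants = self._pca_with_concentrated_loadings()
        rep = pc_loading_report(pca, variants, component=1, top_q=500)
        assert rep["truncated"] is True
        assert rep["top_q"] == 50
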