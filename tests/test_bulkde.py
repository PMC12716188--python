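"""NB differential-expression engine: normalization, dispersion, GLM,
Wald/LRT, BH, Z-scores and Venn overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tregseq.bulkde import (
    ALPHA_MIN,
    NegativeBinomialDE,
    bh_adjust,
    contrast_overlap_sets,
    default_contrasts,
    estimate_dispersions,
    fit_nb_glm,
    likelihood_ratio_test,
    size_factors_median_of_ratios,
    wald_contrast_test,
    zscore_expression,
)
from tregseq.simulate import BulkSimConfig, nb_counts, simulate_bulk_dataset


class TestSizeFactors:
    def test_hand_computed_doubling_case(self):
        counts = np.array([[2, 1], [4, 2], [8, 4]], float)  # A = 2B
        sf = size_factors_median_of_ratios(counts)
        assert sf[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert sf[1] == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[3], [7], [1]], (1, 5))
        assert np.allclose(size_factors_median_of_ratios(counts), 1.0, atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            counts = rng.poisson(50, size=(200, 6)) + 1
            sf = size_factors_median_of_ratios(counts)
            # brute force: per-gene geometric mean then per-sample median ratio
            gm = np.exp(np.log(counts).mean(axis=1))
            expected = np.median(counts / gm[:, None], axis=0)
            assert np.allclose(sf, expected, atol=1e-12)

    def test_matches_pydeseq2_reference(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = rng.poisson(40, size=(300, 8)) + 1
        sf = size_factors_median_of_ratios(counts)
        _, ref = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))
        # the reference works in log space, so agreement is to float noise
        assert np.allclose(sf, np.asarray(ref).ravel(), rtol=1e-5)

    def test_no_reference_genes_raises(self):
        counts = np.array([[0, 5], [5, 0]], float)
        with pytest.raises(ValueError, match="reference genes"):
            size_factors_median_of_ratios(counts)


def design_12():
    X = np.column_stack(
        [
            np.ones(12),
            np.tile([0, 1], 6),               # sex
            np.repeat([0, 1, 0], 4),          # cd25 low
            np.repeat([0, 0, 1], 4),          # cd25 high
        ]
    )
    return X


class TestDispersion:
    def test_poisson_data_floored_near_zero(self, rng):
        mu = rng.uniform(50, 500, 2000)
        counts = rng.poisson(np.tile(mu[:, None], (1, 12)))
        alpha = estimate_dispersions(counts, np.ones(12), design_12())
        assert np.median(alpha) <= 0.01

    def test_nb_alpha_half_recovered(self, rng):
        mu = rng.uniform(50, 500, 2000)
        counts = nb_counts(rng, np.tile(mu[:, None], (1, 12)), 0.5)
        alpha = estimate_dispersions(counts, np.ones(12), design_12())
        assert 0.3 <= np.median(alpha) <= 0.7

    def test_constant_gene_hits_floor(self):
        counts = np.full((1, 12), 9.0)
        alpha = estimate_dispersions(counts, np.ones(12), design_12())
        assert alpha[0] == ALPHA_MIN


class TestNBGLM:
    def test_poisson_limit_recovers_group_mean_ratio(self, rng):
        y = np.concatenate([rng.poisson(50, 6), rng.poisson(200, 6)]).astype(float)
        X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        sf = np.ones(12)
        fit = fit_nb_glm(y, sf, X, 1e-8)
        ratio = y[6:].mean() / y[:6].mean()
        assert np.exp(fit.beta[1]) == pytest.approx(ratio, abs=1e-6)

    def test_intercept_only_fits_weighted_mean(self, rng):
        y = rng.poisson(30, 8).astype(float)
        sf = rng.uniform(0.5, 2.0, 8)
        fit = fit_nb_glm(y, sf, np.ones((8, 1)), 0.1)
        # score equation: sum w_j (y_j - mu_j)/mu_j = 0 with mu_j = s_j exp(b0)
        mu = sf * np.exp(fit.beta[0])
        w = mu / (1 + 0.1 * mu)
        assert abs((w * (y - mu) / mu).sum()) < 1e-6

    def test_duplicated_design_column_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(np.arange(6.0) + 1, np.ones(6), X, 0.1)

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_nb_glm(np.zeros(6), np.ones(6), np.ones((6, 1)), 0.1)

    def test_matches_statsmodels_glm_oracle(self, rng):
        import statsmodels.api as sm

        y = nb_counts(rng, np.repeat([40.0, 120.0], 6), 0.2).astype(float)
        X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        sf = rng.uniform(0.7, 1.4, 12)
        fit = fit_nb_glm(y, sf, X, 0.2)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=0.2),
            offset=np.log(sf),
        ).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(fit.cov)), ref.bse, rtol=1e-4)


class TestWald:
    def test_zero_contrast_is_null(self, rng):
        y = rng.poisson(20, 6).astype(float)
        fit = fit_nb_glm(y, np.ones(6), np.ones((6, 1)), 0.1)
        lfc, stat, p = wald_contrast_test(fit, [0.0])
        assert (lfc, stat, p) == (0.0, 0.0, 1.0)

    def test_nonconverged_fit_flagged_na(self, rng):
        y = rng.poisson(20, 6).astype(float)
        fit = fit_nb_glm(y, np.ones(6), np.ones((6, 1)), 0.1)
        fit.converged = False
        _, stat, p = wald_contrast_test(fit, [1.0])
        assert np.isnan(stat) and np.isnan(p)


class TestLRT:
    def test_identical_designs_give_zero_stat(self, rng):
        y = rng.poisson(25, 8).astype(float)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        a = fit_nb_glm(y, np.ones(8), X, 0.1)
        b = fit_nb_glm(y, np.ones(8), X, 0.1)
        stat, p = likelihood_ratio_test(a, b)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_nesting_violation_rejected(self, rng):
        y = rng.poisson(25, 8).astype(float)
        X1 = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        X2 = np.column_stack([np.ones(8), np.tile([0, 1], 4)])
        a = fit_nb_glm(y, np.ones(8), X1, 0.1)
        b = fit_nb_glm(y, np.ones(8), X2, 0.1)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)

    def test_mismatched_alpha_rejected(self, rng):
        y = rng.poisson(25, 8).astype(float)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        a = fit_nb_glm(y, np.ones(8), X, 0.1)
        b = fit_nb_glm(y, np.ones(8), np.ones((8, 1)), 0.2)
        with pytest.raises(ValueError, match="alpha"):
            likelihood_ratio_test(a, b)

    def test_stat_never_negative_on_simulated_genes(self, bulk_null):
        counts, meta, _ = bulk_null
        res = NegativeBinomialDE(counts, meta).fit()
        assert (res.lrt["lrt_stat"].dropna() >= 0).all()


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestZscore:
    def test_hand_case_and_centering(self):
        z = zscore_expression(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeros(self):
        z = zscore_expression(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_rows_sum_to_zero(self, rng):
        z = zscore_expression(pd.DataFrame(rng.random((20, 3))))
        assert np.allclose(z.sum(axis=1), 0.0, atol=1e-10)


class TestVenn:
    def test_disjoint_sets_have_empty_intersections(self):
        out = contrast_overlap_sets({"a": {1, 2}, "b": {3}, "c": {4, 5}})
        assert out["counts"]["a"] == 2
        assert out["counts"]["a+b"] == 0
        assert out["counts"]["a+b+c"] == 0

    def test_identical_sets_fill_triple_region_only(self):
        s = {1, 2, 3}
        out = contrast_overlap_sets({"a": s, "b": set(s), "c": set(s)})
        assert out["counts"]["a+b+c"] == 3
        assert sum(out["counts"].values()) == 3

    def test_matches_set_algebra_oracle(self, rng):
        universe = list(range(30))
        a = set(rng.choice(universe, 5, replace=False).tolist())
        b = set(rng.choice(universe, 4, replace=False).tolist())
        c = set(rng.choice(universe, 3, replace=False).tolist())
        out = contrast_overlap_sets({"a": a, "b": b, "c": c}, universe)
        assert out["counts"]["a"] == len(a - b - c)
        assert out["counts"]["a+b"] == len((a & b) - c)
        assert out["counts"]["b+c"] == len((b & c) - a)
        assert sum(out["counts"].values()) == len(a | b | c)


class TestModelResults:
    def test_normalization_removes_planted_library_size(self):
        counts, meta, _ = simulate_bulk_dataset(
            BulkSimConfig(n_genes=500, dispersion=0.05, size_factor_sigma=0.5, seed=6)
        )
        res = NegativeBinomialDE(counts, meta).fit(moderate=False)
        q = res.normalized_counts()
        # per-sample totals of normalized counts agree to sampling noise
        totals = q.sum(axis=0)
        assert totals.max() / totals.min() < 1.15

    def test_missing_sample_metadata_rejected(self, bulk_null):
        counts, meta, _ = bulk_null
        with pytest.raises(ValueError, match="missing"):
            NegativeBinomialDE(counts, meta.drop(index=meta.index[0]))

    def test_wald_and_lrt_rank_correlated_on_alternatives(self, rng):
        lfc_high = rng.uniform(-3, 3, 300)
        counts, meta, _ = simulate_bulk_dataset(
            BulkSimConfig(n_genes=300, dispersion=0.1, lfc_high=lfc_high, seed=4)
        )
        res = NegativeBinomialDE(counts, meta).fit()
        t = res.tables["high_vs_negative"]
        logp = lambda s: np.log(np.maximum(s.to_numpy(float), 1e-300))
        rho = sps.spearmanr(logp(t["p_wald"]), logp(t["p_lrt"])).statistic
        assert rho > 0.9

    def test_padj_monotone_in_p_within_contrast(self, bulk_null):
        counts, meta, _ = bulk_null
        res = NegativeBinomialDE(counts, meta).fit()
        t = res.tables["high_vs_negative"].dropna().sort_values("p_wald")
        assert t["padj"].is_monotonic_increasing
        assert (t["padj"] >= t["p_wald"] - 1e-12).all()

    def test_summary_mentions_design_and_contrasts(self, bulk_null):
        counts, meta, _ = bulk_null
        res = NegativeBinomialDE(counts, meta).fit()
        s = res.summary()
        assert "~ sex + CD25" in s and "high_vs_negative" in s

    def test_full_pipeline_sensitivity_and_fdr(self, rng):
        n = 2000
        lfc = np.zeros(n)
        de = rng.choice(n, n // 10, replace=False)
        lfc[de[: n // 20]] = 2.0
        lfc[de[n // 20:]] = -2.0
        counts, meta, _ = simulate_bulk_dataset(
            BulkSimConfig(n_genes=n, dispersion=0.1, lfc_high=lfc, seed=13)
        )
        res = NegativeBinomialDE(counts, meta).fit()
        t = res.tables["high_vs_negative"]
        sig = (t["padj"] <= 0.05).to_numpy()
        truth_de = np.zeros(n, bool)
        truth_de[de] = True
        sens = (sig & truth_de).sum() / truth_de.sum()
        fdr = (sig & ~truth_de).sum() / max(sig.sum(), 1)
        assert sens >= 0.7
        assert fdr <= 0.1
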