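"""Statistical operations: summaries, QC, single-marker scans, HWE, GRM,
relatedness pruning — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from genomat import (MISSING, GrmOptions, find_related, get_g, gwas_logistic,
                     gwas_ols, gwas_rayols, hwe_chisq, hwe_chisq_scan, link,
                     open_bed, qc_mask, summarize, write_bed)
from genomat.geno_stats import benjamini_hochberg
from genomat.synthetic_data import plant_relatives, simulate_genotypes


class TestSummarize:
    def test_hand_computed_column(self):
        col = np.array([[0], [1], [2], [MISSING]], dtype=np.int8)
        s = summarize(col).iloc[0]
        assert s["allele_freq_a1"] == 0.5
        assert s["maf"] == 0.5
        assert s["freq_missing"] == 0.25
        assert s["sd"] == 1.0
        assert s["n_nonmissing"] == 3

    def test_constant_column(self):
        s = summarize(np.full((4, 1), 1, dtype=np.int8)).iloc[0]
        assert s["sd"] == 0.0 and s["allele_freq_a1"] == 0.5 and s["freq_missing"] == 0.0

    def test_all_missing_column(self):
        s = summarize(np.full((4, 1), MISSING, dtype=np.int8)).iloc[0]
        assert s["freq_missing"] == 1.0
        assert np.isnan(s["allele_freq_a1"]) and np.isnan(s["sd"])

    def test_empty_row_subset_rejected(self):
        with pytest.raises(ValueError, match="row subset"):
            summarize(np.zeros((3, 2), dtype=np.int8), rows=[])

    def test_simulated_maf_concentration(self):
        """Empirical MAF concentrates around the target within the binomial
        bound 4*sqrt(q(1-q)/2n) for at least 99% of 500 variants."""
        n = 1000
        geno, q = simulate_genotypes(n, 500, maf_law=(0.05, 0.5), seed=77)
        s = summarize(geno)
        bound = 4 * np.sqrt(q * (1 - q) / (2 * n))
        freq = s["allele_freq_a1"].to_numpy()
        within = np.abs(freq - q) <= bound
        assert within.mean() >= 0.99

    def test_chunk_and_backing_invariance(self, tmp_path):
        geno, _ = simulate_genotypes(60, 90, missing_rate=0.05, seed=5)
        write_bed(geno, tmp_path / "b")
        bm = open_bed(tmp_path / "b")
        lm = link([bm], axis="columns")
        ref = summarize(geno)
        for backing in (bm, lm):
            for cs in (1, 17, 1000):
                out = summarize(backing, chunk_size=cs)
                for col in ["allele_freq_a1", "maf", "freq_missing", "sd"]:
                    assert np.allclose(out[col], ref[col], equal_nan=True)


class TestQcMask:
    def test_boundary_is_strict(self):
        summ = pd.DataFrame({"maf": [0.01, 0.0100001], "freq_missing": [0.0, 0.0]})
        assert qc_mask(summ, maf_min=0.01).tolist() == [1]

    def test_call_rate_boundary_is_strict(self):
        summ = pd.DataFrame({"maf": [0.3, 0.3], "freq_missing": [0.05, 0.0499]})
        assert qc_mask(summ, call_rate_min=0.95).tolist() == [1]

    def test_all_missing_variant_always_excluded(self):
        summ = pd.DataFrame({"maf": [np.nan], "freq_missing": [1.0]})
        assert qc_mask(summ, maf_min=0.0, call_rate_min=0.5).size == 0

    def test_planted_failures_detected(self, fixture_suite):
        import json
        from pathlib import Path
        fx = fixture_suite["fixtures"]["qc"]
        truth = json.loads(
            (Path(fx["root"]).parent / "qc_truth.json").read_text())
        bm = open_bed(fx["root"])
        excluded = np.setdiff1d(np.arange(bm.n_variants), qc_mask(summarize(bm)))
        assert sorted(excluded.tolist()) == sorted(
            truth["maf_fail"] + truth["call_rate_fail"])


class TestRayOLS:
    def test_exact_fit(self):
        res = gwas_rayols(np.array([[0], [1], [2]], dtype=np.int8),
                          np.array([0.0, 1.0, 2.0]))
        assert res["estimate"][0] == pytest.approx(1.0)
        assert res["std_error"][0] == pytest.approx(0.0)

    def test_monomorphic_flagged_not_raised(self):
        res = gwas_rayols(np.full((5, 1), 2, dtype=np.int8), np.arange(5.0))
        assert np.isnan(res["estimate"][0]) and res["flag"][0] == "monomorphic"

    def test_too_few_samples_flagged(self):
        res = gwas_rayols(np.array([[0], [1]], dtype=np.int8), np.array([0.0, 1.0]))
        assert res["flag"][0] == "too_few_samples"

    def test_per_variant_least_squares_oracle(self):
        """estimate/SE/p equal the slope row of an intercept+slope fit run
        independently per variant on the same complete cases."""
        geno, _ = simulate_genotypes(150, 40, missing_rate=0.05, seed=21)
        rng = np.random.default_rng(22)
        y = rng.normal(size=150)
        y[rng.choice(150, 5, replace=False)] = np.nan
        res = gwas_rayols(geno, y)
        for j in range(40):
            x = geno[:, j].astype(float)
            x[x == MISSING] = np.nan
            use = ~np.isnan(x) & ~np.isnan(y)
            fit = sps.linregress(x[use], y[use])
            assert res["estimate"][j] == pytest.approx(fit.slope, rel=1e-10)
            assert res["std_error"][j] == pytest.approx(fit.stderr, rel=1e-10)
            assert res["p_value"][j] == pytest.approx(fit.pvalue, rel=1e-8)
            assert res["n_used"][j] == use.sum()

    def test_statistic_monotone_in_p_value(self):
        geno, _ = simulate_genotypes(200, 100, seed=31)
        y = np.random.default_rng(32).normal(size=200)
        res = gwas_rayols(geno, y).dropna(subset=["p_value"])
        order = np.argsort(np.abs(res["statistic"].to_numpy()))[::-1]
        p_sorted = res["p_value"].to_numpy()[order]
        assert np.all(np.diff(p_sorted) >= -1e-15)

    def test_causal_effect_recovery(self):
        """With one causal variant of effect 0.3 and unit noise at n=10,000,
        the estimate lands within 3 SE of the truth."""
        n = 10_000
        geno, _ = simulate_genotypes(n, 50, maf_law=0.3, seed=41)
        rng = np.random.default_rng(42)
        beta = 0.3
        y = beta * geno[:, 0].astype(float) + rng.normal(size=n)
        res = gwas_rayols(geno, y, cols=np.array([0]))
        assert abs(res["estimate"][0] - beta) <= 3 * res["std_error"][0]

    def test_chunk_and_backing_invariance(self, tmp_path):
        geno, _ = simulate_genotypes(80, 60, missing_rate=0.03, seed=51)
        y = np.random.default_rng(52).normal(size=80)
        write_bed(geno, tmp_path / "g")
        bm = open_bed(tmp_path / "g")
        ref = gwas_rayols(geno, y)
        for backing in (bm, link([bm], axis="columns")):
            for cs in (7, 1000):
                out = gwas_rayols(backing, y, chunk_size=cs)
                assert np.allclose(out["estimate"], ref["estimate"], equal_nan=True)
                assert np.allclose(out["p_value"], ref["p_value"], equal_nan=True)


class TestOLS:
    def test_no_covariates_equals_rayols(self):
        geno, _ = simulate_genotypes(120, 25, missing_rate=0.04, seed=61)
        y = np.random.default_rng(62).normal(size=120)
        pheno = pd.DataFrame({"y": y})
        a = gwas_rayols(geno, y)
        b = gwas_ols(geno, pheno, "y")
        ok = ~a["estimate"].isna()
        assert np.allclose(a.loc[ok, "estimate"], b.loc[ok, "estimate"], rtol=1e-10)
        assert np.allclose(a.loc[ok, "std_error"], b.loc[ok, "std_error"], rtol=1e-10)
        assert np.allclose(a.loc[ok, "p_value"], b.loc[ok, "p_value"], rtol=1e-8)

    def test_covariate_equal_to_variant_is_rank_deficient(self):
        geno, _ = simulate_genotypes(50, 3, seed=63)
        pheno = pd.DataFrame({
            "y": np.random.default_rng(64).normal(size=50),
            "cov": geno[:, 1].astype(float),
        })
        res = gwas_ols(geno, pheno, "y", covariates=["cov"])
        assert res["flag"][1] == "rank_deficient"

    def test_confounder_adjustment_removes_planted_bias(self):
        """A sex-linked phenotype biases the unadjusted variant estimate; the
        adjusted fit recovers the true (zero) effect within 3 SE."""
        rng = np.random.default_rng(65)
        n = 4000
        sex = rng.integers(0, 2, size=n).astype(float)
        # variant frequency differs by sex -> confounding
        q = np.where(sex == 1, 0.5, 0.2)
        x = rng.binomial(2, q).astype(np.int8).reshape(-1, 1)
        y = 1.0 * sex + rng.normal(size=n)
        pheno = pd.DataFrame({"y": y, "sex": sex})
        unadj = gwas_ols(x, pheno, "y")
        adj = gwas_ols(x, pheno, "y", covariates=["sex"])
        assert abs(unadj["estimate"][0]) > 3 * unadj["std_error"][0]  # biased
        assert abs(adj["estimate"][0]) <= 3 * adj["std_error"][0]     # unbiased


class TestLogistic:
    def test_two_by_two_closed_form(self):
        x = np.array([1] * 30 + [0] * 70, dtype=np.int8).reshape(-1, 1)
        y = np.array([1] * 10 + [0] * 20 + [1] * 30 + [0] * 40, dtype=float)
        res = gwas_logistic(x, pd.DataFrame({"y": y}), "y")
        assert res["estimate"][0] == pytest.approx(np.log(10 * 40 / (20 * 30)), abs=1e-6)

    def test_constant_response_flagged(self):
        geno, _ = simulate_genotypes(40, 2, seed=71)
        res = gwas_logistic(geno, pd.DataFrame({"y": np.zeros(40)}), "y")
        assert (res["flag"] == "degenerate").all()

    def test_agreement_with_generic_glm(self):
        """IRLS coefficients match statsmodels' GLM to 1e-6 on 50 variants."""
        sm = pytest.importorskip("statsmodels.api")
        geno, _ = simulate_genotypes(400, 50, maf_law=(0.2, 0.5), seed=72)
        rng = np.random.default_rng(73)
        logit = -0.5 + 0.4 * geno[:, 0].astype(float)
        y = (rng.random(400) < 1 / (1 + np.exp(-logit))).astype(float)
        res = gwas_logistic(geno, pd.DataFrame({"y": y}), "y")
        for j in range(50):
            x = geno[:, j].astype(float)
            fit = sm.GLM(y, np.column_stack([np.ones(400), x]),
                         family=sm.families.Binomial()).fit()
            assert res["estimate"][j] == pytest.approx(fit.params[1], abs=1e-6)
            assert res["std_error"][j] == pytest.approx(fit.bse[1], abs=1e-6)


class TestHWE:
    def test_exact_equilibrium_counts(self):
        stat, p, df = hwe_chisq((25, 50, 25))
        assert stat == 0.0 and df == 1

    def test_hand_computed_counts(self):
        stat, p, df = hwe_chisq((10, 10, 10))
        assert stat == pytest.approx(10 / 3)
        assert p == pytest.approx(sps.chi2.sf(10 / 3, 1))

    def test_monomorphic_convention(self):
        stat, p, _ = hwe_chisq(np.zeros(10, dtype=np.int8))
        assert stat == 0.0 and p == 1.0

    def test_vector_and_counts_agree(self):
        geno = np.array([0, 0, 1, 1, 1, 2, MISSING], dtype=np.int8)
        assert hwe_chisq(geno) == hwe_chisq((2, 3, 1))

    def test_scan_equals_per_column_calls(self):
        geno, _ = simulate_genotypes(200, 60, missing_rate=0.05, seed=81)
        scan = hwe_chisq_scan(geno, chunk_size=13)
        for j in range(60):
            stat, p, _ = hwe_chisq(geno[:, j])
            assert scan["statistic"][j] == pytest.approx(stat, abs=1e-12)
            assert scan["p_value"][j] == pytest.approx(p, abs=1e-12)


def _dense_grm(geno, center=True, scale=True, avg_diag=True):
    X = geno.astype(float)
    X[geno == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    X = np.where(np.isnan(X), mu[None, :], X)
    keep = sd > 0 if scale else np.ones(X.shape[1], bool)
    W = X[:, keep]
    if center:
        W = W - mu[keep]
    if scale:
        W = W / sd[keep]
    if avg_diag:
        k = keep.sum() if scale else np.sum(sd[keep] ** 2)
    else:
        k = 1.0
    return W @ W.T / k


class TestGetG:
    def test_raw_crossproduct(self):
        geno, _ = simulate_genotypes(20, 30, seed=91)
        opts = GrmOptions(center=False, scale=False, scale_to_avg_diag_one=False)
        G = get_g(geno, opts)
        X = geno.astype(float)
        assert np.allclose(G, X @ X.T, rtol=0, atol=1e-12)

    def test_duplicate_rows_share_relationship(self):
        geno, _ = simulate_genotypes(30, 200, seed=92)
        dup = np.vstack([geno, geno[0]])
        for opts in (GrmOptions(), GrmOptions(scale=False),
                     GrmOptions(center=False, scale=False, scale_to_avg_diag_one=False)):
            G = get_g(dup, opts)
            assert G[0, 30] == pytest.approx(G[0, 0], rel=1e-12)

    @pytest.mark.parametrize("center,scale,avg_diag", [
        (True, True, True), (True, False, True), (True, True, False),
        (False, False, False),
    ])
    def test_equals_dense_oracle_across_options(self, center, scale, avg_diag):
        geno, _ = simulate_genotypes(50, 120, missing_rate=0.03, seed=93)
        geno[:, 5] = 1  # plant a constant column
        opts = GrmOptions(center=center, scale=scale, scale_to_avg_diag_one=avg_diag)
        G = get_g(geno, opts, chunk_size=17)
        Go = _dense_grm(geno, center, scale, avg_diag)
        assert np.max(np.abs(G - Go)) <= 1e-10 * max(1.0, np.max(np.abs(Go)))

    def test_unrelated_samples_sanity(self):
        """Default-scaled GRM on 200 unrelated HWE samples x 5000 variants:
        mean diagonal near 1, off-diagonal near 0, PSD."""
        geno, _ = simulate_genotypes(200, 5000, maf_law=(0.05, 0.5), seed=94)
        G = get_g(geno)
        diag = np.diag(G)
        off = G[np.triu_indices(200, 1)]
        assert 0.95 <= diag.mean() <= 1.05
        assert abs(off.mean()) <= 0.02
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_block_stitching_equals_dense(self):
        """(i, i2) blocks over a partition, with frozen column statistics,
        reassemble into the dense GRM."""
        from genomat.geno_stats import grm_column_stats
        from genomat.sym_block import make_partition
        geno, _ = simulate_genotypes(63, 150, missing_rate=0.02, seed=95)
        rows = np.arange(63)
        stats = grm_column_stats(geno, rows, np.arange(150))
        dense = get_g(geno)
        sets = make_partition(63, 20)
        out = np.zeros((63, 63))
        for a, sa in enumerate(sets):
            for b, sb in enumerate(sets):
                out[np.ix_(sa, sb)] = get_g(geno, rows=sa, rows2=sb,
                                            cols=np.arange(150), col_stats=stats)
        assert np.max(np.abs(out - dense)) <= 1e-10

    def test_all_constant_columns_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            get_g(np.ones((5, 3), dtype=np.int8))

    def test_missing_strict_mode_raises(self):
        from genomat.chunked_compute import ChunkError
        geno = np.array([[0, 1], [1, MISSING], [2, 0], [1, 1]], dtype=np.int8)
        with pytest.raises((ValueError, ChunkError), match="missing"):
            get_g(geno, GrmOptions(impute_missing_to_mean=False))


class TestFindRelated:
    def test_identity_matrix_removes_nobody(self):
        assert find_related(np.eye(5), 0.03).size == 0

    def test_single_pair_removes_one(self):
        G = np.eye(4)
        G[1, 3] = G[3, 1] = 0.5
        removed = find_related(G, 0.03)
        assert removed.size == 1 and removed[0] in (1, 3)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            find_related(np.zeros((2, 3)))

    def test_tie_break_is_lowest_index(self):
        G = np.eye(4)
        for a, b in [(0, 1), (2, 3)]:
            G[a, b] = G[b, a] = 0.9
        assert find_related(G, 0.03).tolist() == [0, 2]

    def test_planted_pairs_all_broken_and_no_kept_pair_exceeds_cutoff(self):
        """Gene-dropped relatives: every planted pair is split, and an
        exhaustive scan of the retained pairs finds none at or above the
        cutoff."""
        geno, _ = simulate_genotypes(200, 20_000, maf_law=(0.1, 0.5), seed=96)
        aug, registry = plant_relatives(geno, n_duplicate_pairs=8, n_po_pairs=6,
                                        seed=97)
        G = get_g(aug)
        removed = set(find_related(G, 0.03).tolist())
        for _, row in registry.iterrows():
            assert row["row_a"] in removed or row["row_b"] in removed
        kept = np.array(sorted(set(range(aug.shape[0])) - removed))
        sub = G[np.ix_(kept, kept)]
        assert sub[np.triu_indices(kept.size, 1)].max() < 0.03


def test_benjamini_hochberg_step_up():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = benjamini_hochberg(p)
    assert adj[0] == pytest.approx(0.04)
    assert adj[3] == pytest.approx(0.5)
    assert np.all(adj >= p - 1e-15)
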