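"""Fold change, moderated t (with empirical-Bayes prior), rank product and
the composite significance rule, checked against independent oracles."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma, polygamma

from tritrend.diffexpr import (
    ConfigurationError,
    ContrastSpec,
    ModeratedTPrior,
    ModeratedTTest,
    compute_fold_change,
    fit_f_dist,
    fit_moderated_prior,
    moderated_t_test,
    per_replicate_log2fc,
    rank_product_test,
    rank_product_two_sided,
    run_contrast,
)
from tritrend.synthetic_data import SimulationConfig, simulate_dataset

from conftest import make_matrix


# --------------------------------------------------------------------------
# oracles


def ordinary_t_oracle(a, b):
    """Textbook pooled two-sample t, coded independently of the package."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def rank_product_enum_oracle(grid, direction):
    """Exhaustive (m!)^k column-permutation null, brute force."""
    grid = np.asarray(grid, float)
    m, k = grid.shape
    sgn = -1 if direction == "up" else 1
    ranks = np.column_stack([stats.rankdata(sgn * grid[:, j]) for j in range(k)])
    obs = np.exp(np.log(ranks).mean(axis=1))
    cols = [list(itertools.permutations(ranks[:, j])) for j in range(k)]
    counts = np.zeros(m)
    total = 0
    for combo in itertools.product(*cols):
        null = np.exp(np.log(np.column_stack(combo)).mean(axis=1))
        counts += null <= obs + 1e-9
        total += 1
    return obs, counts / total


# --------------------------------------------------------------------------
# fold change


class TestComputeFoldChange:
    def test_equal_means_give_unity(self):
        m = make_matrix([[8, 8, 8, 8, 8, 8]], ["L"] * 3 + ["H"] * 3)
        fc = compute_fold_change(m, ContrastSpec("L", "H"))
        assert fc["fc_ratio"].iloc[0] == pytest.approx(1.0)
        assert fc["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_exact_ratio_without_pseudocount(self):
        m = make_matrix([[4, 4, 4, 1, 1, 1]], ["L"] * 3 + ["H"] * 3)
        fc = compute_fold_change(m, ContrastSpec("L", "H"), pseudocount=0.0)
        assert fc["fc_ratio"].iloc[0] == pytest.approx(4.0)
        assert fc["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_pseudocount_applied_when_a_group_mean_is_zero(self):
        m = make_matrix([[0, 0, 0, 3, 5, 4]], ["L"] * 3 + ["H"] * 3)
        fc = compute_fold_change(m, ContrastSpec("L", "H"), pseudocount=0.5)
        assert fc["fc_ratio"].iloc[0] == pytest.approx(0.5 / 4.5)

    def test_zero_denominator_with_zero_pseudocount_is_missing_not_error(self):
        m = make_matrix([[3, 5, 4, 0, 0, 0]], ["L"] * 3 + ["H"] * 3)
        fc = compute_fold_change(m, ContrastSpec("L", "H"), pseudocount=0.0)
        assert np.isnan(fc["fc_ratio"].iloc[0])

    def test_min_obs_gate(self):
        m = make_matrix(
            [[4, np.nan, np.nan, 1, 1, 1]], ["L"] * 3 + ["H"] * 3
        )
        fc = compute_fold_change(m, ContrastSpec("L", "H"), min_obs=2)
        assert np.isnan(fc["fc_ratio"].iloc[0])
        assert fc["n_num"].iloc[0] == 1


# --------------------------------------------------------------------------
# moderated prior


class TestFitModeratedPrior:
    def test_identical_variances_give_infinite_d0_and_that_variance(self):
        prior = fit_f_dist(np.full(20, 2.5), 4.0)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.5)

    def test_two_close_variances_collapse_to_common_variance(self):
        """Variances 1 and 2 at 4 df are within the sampling noise of a single
        common variance (var of log-variances below trigamma(df/2)), so the
        moment fit returns an infinite d0 with s0_sq between the two."""
        s2 = np.array([1.0, 2.0])
        d = 4.0
        e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
        assert np.var(e, ddof=1) - polygamma(1, d / 2) < 0  # no finite solution
        prior = fit_f_dist(s2, d)
        assert math.isinf(prior.d0)
        assert 1.0 < prior.s0_sq < 2.0
        assert prior.s0_sq == pytest.approx(1.5)

    def test_finite_d0_matches_brute_force_moment_equations(self):
        """Widely spread variances yield a finite d0; an independent bisection
        solve of the trigamma moment equation must agree."""
        s2 = np.array([0.05, 0.3, 1.0, 4.0, 20.0])
        d = 4.0
        e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
        evar = np.var(e, ddof=1) - polygamma(1, d / 2)
        assert evar > 0
        lo, hi = 1e-6, 1e6  # bisection for trigamma(y) = evar (decreasing)
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0_expect = 2 * lo
        s0_expect = math.exp(e.mean() + digamma(d0_expect / 2) - np.log(d0_expect / 2))
        prior = fit_f_dist(s2, d)
        assert np.isfinite(prior.d0) and prior.d0 > 0
        assert prior.d0 == pytest.approx(d0_expect, rel=1e-5)
        assert prior.s0_sq == pytest.approx(s0_expect, rel=1e-5)

    def test_parameter_recovery_from_simulated_variances(self):
        rng = np.random.default_rng(123)
        d0_true, s0_true, d = 4.0, 1.0, 4.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        prior = fit_f_dist(s2, d)
        assert prior.d0 == pytest.approx(d0_true, abs=1.0)
        assert prior.s0_sq == pytest.approx(s0_true, abs=0.1)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="variance"):
            fit_f_dist(np.zeros(10), 4.0)

    def test_matrix_entry_point(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, size=(200, 6))
        prior = fit_moderated_prior(values, np.array([0, 0, 0, 1, 1, 1]))
        assert prior.s0_sq == pytest.approx(1.0, abs=0.2)


# --------------------------------------------------------------------------
# moderated t


class TestModeratedT:
    def test_equal_means_give_t_zero_p_one(self):
        prior = ModeratedTPrior(d0=4.0, s0_sq=1.0)
        t, p = moderated_t_test([3.0, 4.0, 5.0], [5.0, 4.0, 3.0], prior)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_d0_zero_equals_ordinary_t_on_random_instances(self):
        rng = np.random.default_rng(99)
        prior = ModeratedTPrior(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.normal(), 1, nb)
            t, p = moderated_t_test(a, b, prior)
            t0, p0 = ordinary_t_oracle(a, b)
            assert abs(t - t0) < 1e-10
            assert abs(p - p0) < 1e-10

    def test_d0_infinite_closed_form(self):
        prior = ModeratedTPrior(d0=math.inf, s0_sq=2.0)
        a, b = np.array([5.0, 6.0, 7.0]), np.array([4.0, 4.0, 4.0])
        t, p = moderated_t_test(a, b, prior)
        expect_t = (a.mean() - b.mean()) / math.sqrt(2.0 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expect_t)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expect_t)))

    def test_single_observation_group_gives_missing(self):
        prior = ModeratedTPrior(d0=4.0, s0_sq=1.0)
        t, p = moderated_t_test([3.0], [1.0, 2.0, 3.0], prior)
        assert np.isnan(t) and np.isnan(p)

    def test_estimator_fit_attributes(self):
        rng = np.random.default_rng(17)
        X = rng.normal(0, 1, size=(6, 30))
        y = np.array([0, 0, 0, 1, 1, 1])
        est = ModeratedTTest().fit(X, y)
        assert est.statistic_.shape == (30,)
        assert est.pvalue_.shape == (30,)
        assert np.all((est.pvalue_ >= 0) & (est.pvalue_ <= 1))
        assert est.prior_s0_sq_ > 0
        assert est.get_params()["prior"] is None

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_bioconductor_limma(self, tmp_path):
        """Independent cross-check: statistics and p-values match limma's
        lmFit + eBayes on a heteroskedastic instance."""
        rng = np.random.default_rng(7)
        sigma2 = 4.0 / rng.chisquare(4.0, 60)
        X = np.vstack([rng.normal(0, math.sqrt(s), 6) for s in sigma2])
        pd.DataFrame(X).to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path / "x.tsv"}"))\n'
            'design <- model.matrix(~ factor(c(0,0,0,1,1,1), levels=c(1,0)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n'
            '                  d0=fit$df.prior, s0=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path / "out.tsv"}", sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        est = ModeratedTTest().fit(X.T, np.array([0, 0, 0, 1, 1, 1]))
        assert est.prior_d0_ == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert est.prior_s0_sq_ == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(est.statistic_, ref["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(est.pvalue_, ref["p"].to_numpy(), atol=1e-8)


# --------------------------------------------------------------------------
# rank product


class TestRankProduct:
    def test_top_ranked_everywhere_gets_minimal_rp_and_closed_form_p(self):
        m, k = 5, 3
        rng = np.random.default_rng(2)
        grid = rng.normal(0, 1, size=(m, k))
        grid[0] = 10.0  # protein 0 largest in every replicate
        rp, p = rank_product_test(grid, "up")
        assert rp[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx((1 / m) ** k)

    def test_single_replicate_p_is_rank_over_m(self):
        grid = np.array([[3.0], [1.0], [2.0], [0.5]])
        rp, p = rank_product_test(grid, "up")
        # descending order: 3.0 -> rank 1, 2.0 -> 2, 1.0 -> 3, 0.5 -> 4
        np.testing.assert_allclose(rp, [1.0, 3.0, 2.0, 4.0], rtol=1e-12)
        np.testing.assert_allclose(p, [0.25, 0.75, 0.5, 1.0], rtol=1e-12)

    def test_three_by_two_matches_36_permutation_enumeration(self):
        grid = np.array([[2.0, 1.5], [0.1, 0.3], [-1.0, 0.2]])
        for direction in ("up", "down"):
            rp, p = rank_product_test(grid, direction)
            rp_o, p_o = rank_product_enum_oracle(grid, direction)
            np.testing.assert_allclose(rp, rp_o, atol=1e-12)
            np.testing.assert_allclose(p, p_o, atol=1e-12)

    @pytest.mark.parametrize("m,k", [(2, 1), (3, 2), (4, 2), (4, 3), (3, 3)])
    def test_exact_matches_enumeration_on_small_instances(self, m, k):
        rng = np.random.default_rng(m * 10 + k)
        for trial in range(3):
            grid = np.round(rng.normal(0, 1, size=(m, k)), 1)  # rounding makes ties
            for direction in ("up", "down"):
                rp, p = rank_product_test(grid, direction)
                _, p_o = rank_product_enum_oracle(grid, direction)
                np.testing.assert_allclose(p, p_o, atol=1e-12)

    def test_monte_carlo_close_to_exact_null_tail(self):
        from tritrend.diffexpr import _exact_p, _log_rank_product, _rank_columns

        rng = np.random.default_rng(8)
        grid = rng.normal(0, 1, size=(30, 3))  # 30^3 > 10,000 forces Monte Carlo
        _, p_mc = rank_product_test(grid, "up", n_permutations=4000, seed=1)
        ranks = _rank_columns(grid, "up")
        p_exact = _exact_p(ranks, _log_rank_product(ranks))
        assert np.max(np.abs(p_mc - p_exact)) < 0.03

    def test_monte_carlo_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(3)
        grid = rng.normal(0, 1, size=(40, 3))
        _, p1 = rank_product_test(grid, "up", n_permutations=500, seed=11)
        _, p2 = rank_product_test(grid, "up", n_permutations=500, seed=11)
        _, p3 = rank_product_test(grid, "up", n_permutations=500, seed=12)
        np.testing.assert_array_equal(p1, p2)
        assert not np.array_equal(p1, p3)

    def test_too_few_permutations_rejected(self):
        grid = np.random.default_rng(0).normal(size=(200, 3))
        with pytest.raises(ConfigurationError, match="100"):
            rank_product_test(grid, "up", n_permutations=50)

    def test_two_sided_is_symmetric_under_negation(self):
        rng = np.random.default_rng(21)
        grid = rng.normal(0, 1, size=(50, 3))
        _, p = rank_product_two_sided(grid, n_permutations=300, seed=5)
        _, p_neg = rank_product_two_sided(-grid, n_permutations=300, seed=5)
        np.testing.assert_allclose(p, p_neg, atol=1e-12)

    def test_missing_replicate_handled(self):
        grid = np.array([[2.0, np.nan], [0.5, 1.0], [-1.0, -0.5]])
        rp, p = rank_product_test(grid, "up")
        assert np.isfinite(rp).all()
        assert np.isfinite(p).all()


# --------------------------------------------------------------------------
# composite contrast


def _sim(n=120, seed=5, **kw):
    cfg = SimulationConfig(n_proteins=n, seed=seed, **kw)
    return simulate_dataset(cfg)


class TestRunContrast:
    def test_composite_rule_invariant(self):
        intensity, counts, _ = _sim(missing_rate=0.05)
        res = run_contrast(intensity, counts, ContrastSpec("L", "H"),
                           n_permutations=200, seed=2)
        sig = res["significant"].to_numpy()
        min_p = res["min_p"].to_numpy()
        fc = res["fc_ratio"].to_numpy()
        gate = (fc >= 2.0) | (fc <= 0.5)
        expected = res["tested"].to_numpy() & (min_p < 0.05) & gate
        np.testing.assert_array_equal(sig, expected)

    def test_p_gate_and_fold_gate(self):
        # strong 2.5-fold change with tiny noise -> significant;
        # 1.8-fold change with tiny noise -> blocked by the fold gate
        values = np.array(
            [
                [2.5, 2.51, 2.49, 1.0, 1.01, 0.99],
                [1.8, 1.81, 1.79, 1.0, 1.01, 0.99],
            ]
        ) * 100
        m = make_matrix(values, ["L"] * 3 + ["H"] * 3,
                        replicate_ids=["rep1", "rep2", "rep3"] * 2)
        res = run_contrast(m, None, ContrastSpec("L", "H"), seed=0)
        assert bool(res["significant"].iloc[0])
        assert res["min_p"].iloc[1] < 0.05
        assert not bool(res["significant"].iloc[1])

    def test_large_fold_change_with_large_p_not_significant(self):
        # huge within-group variance: no test reaches p < 0.05
        rng = np.random.default_rng(0)
        values = np.abs(rng.normal(0, 1, size=(30, 6))) * 1000 + 1
        values[0, :3] = [10000, 1, 1]
        values[0, 3:] = [1, 1, 1]
        m = make_matrix(values, ["L"] * 3 + ["H"] * 3,
                        replicate_ids=["rep1", "rep2", "rep3"] * 2)
        res = run_contrast(m, None, ContrastSpec("L", "H"),
                           n_permutations=400, seed=1)
        row = res.iloc[0]
        if row["min_p"] >= 0.05:
            assert not bool(row["significant"])

    def test_antisymmetry_under_contrast_reversal(self):
        intensity, counts, _ = _sim(n=80, seed=9)
        fwd = run_contrast(intensity, counts, ContrastSpec("L", "H"),
                           n_permutations=300, seed=4)
        rev = run_contrast(intensity, counts, ContrastSpec("H", "L"),
                           n_permutations=300, seed=4)
        np.testing.assert_allclose(
            fwd["fc_ratio"], 1.0 / rev["fc_ratio"], rtol=1e-12
        )
        for col in ("p_modt_intensity", "p_modt_count", "p_rankprod"):
            np.testing.assert_allclose(fwd[col], rev[col], atol=1e-12)
        np.testing.assert_array_equal(fwd["significant"], rev["significant"])

    def test_fc_threshold_monotonicity(self):
        intensity, counts, _ = _sim(n=100, seed=13)
        n_sig = []
        for thr in (1.5, 2.0, 3.0, 4.0):
            res = run_contrast(intensity, counts, ContrastSpec("L", "H"),
                               fc_threshold=thr, n_permutations=200, seed=6)
            n_sig.append(int(res["significant"].sum()))
        assert n_sig == sorted(n_sig, reverse=True)

    def test_missing_count_channel_recorded_as_skipped(self):
        intensity, _, _ = _sim(n=40, seed=3)
        res = run_contrast(intensity, None, ContrastSpec("L", "H"),
                           n_permutations=200, seed=0)
        assert "modt_count" in res.attrs["skipped_tests"]
        assert res["p_modt_count"].isna().all()
        assert res["p_modt_intensity"].notna().any()

    def test_per_replicate_log2fc_pairs_by_replicate(self):
        m = make_matrix(
            [[8.0, 4.0, 2.0, 2.0, 2.0, 2.0]],
            ["L", "L", "L", "H", "H", "H"],
            replicate_ids=["rep1", "rep2", "rep3", "rep1", "rep2", "rep3"],
        )
        grid = per_replicate_log2fc(m, ContrastSpec("L", "H"))
        assert grid.iloc[0].tolist() == [2.0, 1.0, 0.0]
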