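"""Interaction models, resampling inference and outlier-excess tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoscan.selection_inference import (
    InteractionModel,
    binomial_excess_p,
    block_bootstrap_se,
    cooks_outlier_excess,
    cross_metric_overlap,
    fisher_combine,
    fit_interaction_model,
    intervals_frame,
    permutation_test,
    tajima_class_comparison,
)
from mitoscan.windowing import GenomicWindow, ROHInterval, classify, tile_windows


def frame_from_arrays(y, n_flag, g, chrom=None):
    n = len(y)
    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n,
            "start": np.arange(n) * 1000,
            "response": y,
            "n_interact": n_flag,
            "gene_number": g,
        }
    )


class TestInteractionModel:
    def test_exact_interpolation_of_noiseless_response(self):
        rng = np.random.default_rng(0)
        n_flag = rng.integers(0, 2, size=40)
        g = rng.integers(1, 8, size=40)
        y = 2 + 1 * n_flag + 0 * g + 0 * n_flag * g
        res = InteractionModel(frame_from_arrays(y, n_flag, g)).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), [2.0, 1.0, 0.0, 0.0], atol=1e-10
        )

    def test_class_gap_is_beta1_plus_beta3_g(self):
        rng = np.random.default_rng(1)
        n_flag = rng.integers(0, 2, size=60)
        g = rng.integers(1, 10, size=60)
        y = rng.normal(size=60)
        res = InteractionModel(frame_from_arrays(y, n_flag, g)).fit()
        gap = res.class_gap(5.0)
        assert gap == pytest.approx(
            res.params["n_interact"] + 5.0 * res.params["n_interact:gene_number"]
        )

    def test_single_class_refused(self):
        with pytest.raises(ValueError, match="class"):
            InteractionModel(
                frame_from_arrays(np.ones(20), np.ones(20, int), np.ones(20, int))
            )

    def test_roh_response_is_log_length_in_100kb(self):
        rohs = [
            ROHInterval(sample="s", chrom="chr1", start=0, end=200_000,
                        gene_number=2, window_class="N_INTERACT"),
            ROHInterval(sample="s", chrom="chr1", start=300_000, end=400_000,
                        gene_number=1, window_class="NON_N_INTERACT"),
        ]
        frame = intervals_frame(rohs, "log_roh_length")
        assert frame["response"].tolist() == pytest.approx(
            [math.log(2.0), math.log(1.0)]
        )

    def test_marginal_means_span_percentile_grid(self):
        rng = np.random.default_rng(2)
        n_flag = rng.integers(0, 2, size=300)
        g = rng.integers(1, 30, size=300)
        y = 1.0 + 0.5 * n_flag + 0.1 * g + rng.normal(scale=0.1, size=300)
        res = InteractionModel(frame_from_arrays(y, n_flag, g)).fit()
        mm = res.marginal_means((1, 90))
        lo = mm["gene_number"].min()
        hi = mm["gene_number"].max()
        assert lo >= 1 and hi <= 30
        assert set(mm["window_class"]) == {"N_INTERACT", "NON_N_INTERACT"}
        assert (mm["ci_low"] <= mm["predicted"]).all()
        assert (mm["predicted"] <= mm["ci_high"]).all()

    def test_planted_longer_n_interact_rohs_detected(self):
        """ROHs drawn longer when N_interact give a positive fitted
        class gap with significant bootstrap inference in most seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            n = 400
            n_flag = rng.integers(0, 2, size=n)
            g = rng.integers(1, 10, size=n)
            length = np.exp(rng.normal(0.0 + 0.4 * n_flag, 0.5))
            frame = frame_from_arrays(np.log(length), n_flag, g)
            res = InteractionModel(frame).fit(
                cov_type="block-bootstrap", block_size=10, n_boot=200, seed=seed
            )
            gap, _, p_gap = res.class_gap_test(float(np.mean(g)))
            if gap > 0 and p_gap < 0.05:
                wins += 1
        assert wins >= int(0.9 * n_seeds)


class TestBlockBootstrap:
    def test_iid_se_close_to_analytic(self):
        rng = np.random.default_rng(4)
        n = 3000
        n_flag = rng.integers(0, 2, size=n)
        g = rng.integers(1, 12, size=n)
        y = 0.5 + 0.2 * n_flag + 0.05 * g + rng.normal(size=n)
        frame = frame_from_arrays(y, n_flag, g)
        analytic = InteractionModel(frame).fit(cov_type="analytic")
        boot = InteractionModel(frame).fit(
            cov_type="block-bootstrap", block_size=30, n_boot=500, seed=1
        )
        for term in analytic.params.index:
            ratio = boot.bse[term] / analytic.bse[term]
            assert 0.8 < ratio < 1.2, term

    def test_autocorrelated_response_inflates_block_se(self):
        """AR(1) rho=0.8 errors: the block SE exceeds the (wrong)
        analytic OLS SE for the intercept in nearly all seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 1200
            n_flag = rng.integers(0, 2, size=n)
            g = rng.integers(1, 12, size=n)
            eps = np.empty(n)
            eps[0] = rng.normal()
            for i in range(1, n):
                eps[i] = 0.8 * eps[i - 1] + rng.normal() * math.sqrt(1 - 0.8**2)
            y = 0.5 + 0.2 * n_flag + eps
            frame = frame_from_arrays(y, n_flag, g)
            analytic = InteractionModel(frame).fit(cov_type="analytic")
            boot = InteractionModel(frame).fit(
                cov_type="block-bootstrap", block_size=30, n_boot=150, seed=seed
            )
            wins += boot.bse["const"] > analytic.bse["const"]
        assert wins >= int(0.95 * n_seeds)

    def test_constant_response_reports_na(self):
        rng = np.random.default_rng(5)
        n_flag = rng.integers(0, 2, size=60)
        g = rng.integers(1, 5, size=60)
        frame = frame_from_arrays(np.ones(60), n_flag, g)
        res = block_bootstrap_se(frame, block_size=5, n_boot=50, seed=0)
        assert res.bse["n_interact"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.pvalues["n_interact"])

    def test_too_few_replicates_rejected(self):
        rng = np.random.default_rng(6)
        frame = frame_from_arrays(
            rng.normal(size=40), rng.integers(0, 2, 40), rng.integers(1, 5, 40)
        )
        with pytest.raises(ValueError):
            block_bootstrap_se(frame, n_boot=1)


class TestPermutationTest:
    def test_add_one_convention_bounds_p(self):
        values = np.r_[np.full(10, 100.0), np.zeros(90)]
        labels = np.r_[np.ones(10, bool), np.zeros(90, bool)]
        res = permutation_test(values, labels, tail="upper",
                               n_permutations=1000, seed=0)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_constant_values_give_p_one(self):
        res = permutation_test(
            np.ones(30), np.r_[np.ones(10, bool), np.zeros(20, bool)],
            tail="upper", n_permutations=200, seed=0,
        )
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_invariant_to_adding_constant(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        a = permutation_test(values, labels, tail="upper",
                             n_permutations=300, seed=3)
        b = permutation_test(values + 17.5, labels, tail="upper",
                             n_permutations=300, seed=3)
        assert a.p_value == b.p_value

    def test_lower_tail_mirrors_upper(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        up = permutation_test(values, labels, "upper", 500, seed=9)
        lo = permutation_test(-values, labels, "lower", 500, seed=9)
        assert up.p_value == lo.p_value

    def test_both_classes_required(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones(5), np.ones(5, bool), "upper", 10, 0)


class TestCooksOutlierExcess:
    @staticmethod
    def windows_with_stat(values, classes, stat="fst[a:b]"):
        wins = []
        for i, (v, c) in enumerate(zip(values, classes)):
            w = GenomicWindow(chrom="chr1", start=i * 1000, end=(i + 1) * 1000)
            w.gene_number = 2
            w.window_class = c
            w.stats[stat] = v
            wins.append(w)
        return wins

    def test_binomial_excess_example(self):
        # 10 outliers, 2 N_interact, baseline 5%
        expected = 1 - 0.95**10 - 10 * 0.05 * 0.95**9
        assert binomial_excess_p(10, 2, 0.05) == pytest.approx(expected)
        assert binomial_excess_p(10, 2, 0.05) == pytest.approx(0.0861, abs=5e-4)

    def test_cooks_distance_matches_leave_one_out_refits(self):
        """Cook's D equals sum of squared fitted-value shifts under
        leave-one-out refits divided by p * MSE, on a 20-point fixture."""
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        rng = np.random.default_rng(10)
        g = rng.integers(1, 10, size=20).astype(float)
        y = 0.3 + 0.1 * g + rng.normal(scale=0.2, size=20)
        y[3] += 2.0  # one gross outlier
        x = sm.add_constant(g)
        fit = sm.OLS(y, x).fit()
        cooks = OLSInfluence(fit).cooks_distance[0]
        p = x.shape[1]
        s2 = fit.mse_resid
        yhat = fit.fittedvalues
        for i in range(20):
            keep = np.arange(20) != i
            fit_i = sm.OLS(y[keep], x[keep]).fit()
            yhat_i = x @ fit_i.params
            d_i = np.sum((yhat - yhat_i) ** 2) / (p * s2)
            assert cooks[i] == pytest.approx(d_i, rel=1e-8), i

    def test_identical_statistic_no_outliers(self):
        wins = self.windows_with_stat(
            np.full(50, 0.3), ["N_INTERACT"] * 10 + ["NON_N_INTERACT"] * 40
        )
        rep = cooks_outlier_excess(wins, "fst[a:b]", "upper")
        assert rep.n_outliers == 0
        assert rep.p_value == 1.0

    def test_directional_filtering(self):
        rng = np.random.default_rng(11)
        values = rng.normal(0.2, 0.01, size=60)
        values[5] = 0.9   # upper outlier
        values[6] = -0.5  # lower outlier
        classes = ["N_INTERACT" if i < 20 else "NON_N_INTERACT" for i in range(60)]
        upper = cooks_outlier_excess(
            self.windows_with_stat(values, classes), "fst[a:b]", "upper"
        )
        lower = cooks_outlier_excess(
            self.windows_with_stat(values, classes), "fst[a:b]", "lower"
        )
        assert "chr1:5000-6000" in upper.outlier_ids
        assert "chr1:5000-6000" not in lower.outlier_ids
        assert "chr1:6000-7000" in lower.outlier_ids


class TestFisherCombine:
    def test_four_and_five_pvalue_degrees_of_freedom(self):
        _, df4, _ = fisher_combine([0.2, 0.5, 0.01, 0.9])
        _, df5, _ = fisher_combine([0.2, 0.5, 0.01, 0.9, 0.3])
        assert df4 == 8
        assert df5 == 10

    def test_two_half_pvalues(self):
        x2, df, p = fisher_combine([0.5, 0.5])
        assert x2 == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.596, abs=1e-3)

    def test_all_ones_is_null(self):
        x2, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert x2 == 0.0 and p == 1.0

    def test_matches_scipy_combination(self):
        rng = np.random.default_rng(12)
        ps = rng.uniform(0.01, 1, size=6)
        x2, df, p = fisher_combine(ps)
        ref = sps.combine_pvalues(ps, method="fisher")
        assert x2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_decreasing_in_p(self):
        ps = [0.9, 0.5, 0.2, 0.05]
        combined = [fisher_combine([p] * 3)[2] for p in ps]
        assert all(a > b for a, b in zip(combined, combined[1:]))

    def test_zero_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="mitoscan"):
            x2, df, p = fisher_combine([0.0, 0.5])
        assert math.isfinite(x2) and p > 0
        assert any("clamp" in r.message for r in caplog.records)


class TestTajimaComparison:
    def test_identical_distributions_zero_difference(self):
        wins = []
        for i, cls in enumerate(["N_INTERACT", "NON_N_INTERACT"] * 10 + ["NONGENIC"] * 4):
            w = GenomicWindow(chrom="chr1", start=i * 1000, end=(i + 1) * 1000)
            w.window_class = cls
            w.gene_number = 0 if cls == "NONGENIC" else 1
            w.stats["tajima_d[g]"] = -0.3
            wins.append(w)
        out = tajima_class_comparison(wins, "g", n_permutations=100, seed=0)
        assert out["observed_difference"] == 0.0
        assert out["n_nongenic"] == 4
        assert out["mean_nongenic"] == pytest.approx(-0.3)


class TestCrossMetricOverlap:
    def test_outlier_counts_and_roh_residence(self):
        wins = []
        for i in range(4):
            w = GenomicWindow(chrom="chr1", start=i * 1000, end=(i + 1) * 1000)
            w.gene_number = 1
            w.window_class = "N_INTERACT"
            wins.append(w)
        reports = []
        from mitoscan.selection_inference import OutlierReport

        for k, stat in enumerate(["fst[a:b]", "fst[a:c]", "pi[a]", "pi[b]"]):
            reports.append(
                OutlierReport(
                    statistic=stat, direction="upper" if "fst" in stat else "lower",
                    outlier_ids=["chr1:0-1000"], n_outliers=1,
                    n_outliers_n_interact=1, n_windows=4, n_windows_n_interact=4,
                    p_value=0.5, cooks_threshold=1.0,
                )
            )
        rohs = [
            ROHInterval(sample="s", chrom="chr1", start=500, end=1_200,
                        window_class="N_INTERACT")
        ]
        table = cross_metric_overlap(reports, rohs, wins)
        first = table[table.window_id == "chr1:0-1000"].iloc[0]
        assert first["n_comparisons_outlier"] == 4
        assert bool(first["in_roh"])
        last = table[table.window_id == "chr1:3000-4000"].iloc[0]
        assert last["n_comparisons_outlier"] == 0
        assert not bool(last["in_roh"])

    def test_disjoint_window_sets_empty(self):
        table = cross_metric_overlap([], [], [])
        assert len(table) == 0
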