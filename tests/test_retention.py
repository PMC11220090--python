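import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saltgrip.retention import (
    SaltToleranceModel,
    compute_sscore,
    cumulative_rank_curve,
    curve_auc,
    rank_metric_comparison,
    signal_matched_sampling,
    sscore_matched_grouping,
)


def _matrix(values, conditions=("75", "150", "225")):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr, index=[f"m{i}" for i in range(len(arr))], columns=list(conditions)
    )


class TestSScore:
    def test_rank_one_matrix_recovers_factor(self):
        rng = np.random.default_rng(0)
        c = rng.random(40) * 10
        v = np.array([1.0, 2.0, 3.0])
        m = _matrix(np.outer(c, v))
        res = compute_sscore(m, log_transform=False)
        rho = stats.spearmanr(res.sscore, c).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_pc1_matches_independent_eigendecomposition(self):
        """PC1 scores equal the leading-eigenvector projection of the
        standardized covariance, up to sign, to 1e-8."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = _matrix(rng.random((50, 3)) * 20)
            res = compute_sscore(m)
            x = np.log2(1 + m.to_numpy())
            z = (x - x.mean(0)) / x.std(0, ddof=1)
            cov = z.T @ z / (len(z) - 1)
            w, v = np.linalg.eigh(cov)
            lead = v[:, np.argmax(w)]
            oracle = z @ lead
            diff = min(
                np.abs(res.sscore.to_numpy() - oracle).max(),
                np.abs(res.sscore.to_numpy() + oracle).max(),
            )
            assert diff < 1e-8

    def test_toy_matrix_scores_strictly_decreasing(self):
        m = _matrix([[10, 10, 10], [10, 8, 6], [10, 4, 1], [10, 1, 0]])
        with pytest.raises(ValueError, match="zero-variance"):
            compute_sscore(m)  # first column is constant
        # minimally perturbed full-rank variant keeps the retention ordering
        m = _matrix([[10.5, 10, 10], [10.2, 8, 6], [9.8, 4, 1], [9.5, 1, 0]])
        res = compute_sscore(m)
        s = res.sscore.to_numpy()
        assert np.all(np.diff(s) < 0)

    def test_orientation_highest_stringency_loading_positive(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.random((30, 3)) * 5 + 0.1)
        res = compute_sscore(m)
        assert res.loadings.loc["225", "PC1"] > 0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.random((20, 3)) * 9)
        perm = rng.permutation(20)
        res_a = compute_sscore(m)
        res_b = compute_sscore(m.iloc[perm])
        pd.testing.assert_series_equal(
            res_a.sscore.loc[res_b.sscore.index], res_b.sscore
        )

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.random((20, 3)) * 9)
        res_a = compute_sscore(m)
        m2 = m[["150", "75", "225"]]
        res_b = compute_sscore(m2)
        np.testing.assert_allclose(
            res_a.loadings.loc[["150", "75", "225"], "PC1"],
            res_b.loadings["PC1"],
            atol=1e-10,
        )
        np.testing.assert_allclose(res_a.sscore, res_b.sscore, atol=1e-10)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="3 motifs"):
            SaltToleranceModel(_matrix([[1, 2, 3], [2, 3, 4]]))

    def test_summary_mentions_preprocessing(self):
        rng = np.random.default_rng(5)
        res = compute_sscore(_matrix(rng.random((10, 3)) + 0.1))
        assert "log2(1+x)" in res.summary()


class TestMatchedSampling:
    def test_identical_distributions_keep_count_equalization_only(self):
        idx = [f"m{i}" for i in range(200)]
        groups = pd.Series(["a"] * 100 + ["b"] * 100, index=idx)
        sig = pd.Series(np.tile(np.arange(100), 2), index=idx, dtype=float)
        kept = signal_matched_sampling(groups, sig, n_bins=10, seed=0)
        assert len(kept["a"]) == len(kept["b"])
        assert len(kept["a"]) >= 90  # barely anything dropped

    def test_mean_differences_shrink(self):
        rng = np.random.default_rng(1)
        idx = [f"m{i}" for i in range(600)]
        groups = pd.Series(["a"] * 300 + ["b"] * 300, index=idx)
        sig = pd.Series(
            np.concatenate([rng.normal(0, 1, 300), rng.normal(1, 1, 300)]),
            index=idx,
        )
        kept = signal_matched_sampling(groups, sig, n_bins=20, seed=0)
        pre = abs(sig[groups == "a"].mean() - sig[groups == "b"].mean())
        post = abs(sig[kept["a"]].mean() - sig[kept["b"]].mean())
        assert post <= pre

    def test_disjoint_supports_error(self):
        idx = [f"m{i}" for i in range(40)]
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        sig = pd.Series(np.r_[np.zeros(20), np.ones(20) * 100], index=idx)
        with pytest.raises(ValueError, match="no quantile bin"):
            signal_matched_sampling(groups, sig, n_bins=40, seed=0)


class TestGrouping:
    def test_assignment_matches_brute_force_resort(self):
        rng = np.random.default_rng(2)
        idx = [f"m{i}" for i in range(600)]
        ss = pd.Series(rng.normal(size=600), index=idx)
        sig = pd.Series(rng.random(600), index=idx)
        k, n_bins = 6, 10
        g = sscore_matched_grouping(ss, sig, k=k, n_bins=n_bins)
        edges = g.bin_edges
        bins = np.clip(
            np.searchsorted(edges, sig.to_numpy(), side="right") - 1,
            0, len(edges) - 2,
        )
        for b in np.unique(bins):
            ids = ss.index[bins == b]
            if len(ids) < k:
                continue
            order = np.argsort(-ss.loc[ids].to_numpy(), kind="stable")
            ids_sorted = ids[order]
            q, r = divmod(len(ids_sorted), k)
            ids_sorted = ids_sorted[r // 2 : r // 2 + q * k]
            for gi in range(k):
                block = ids_sorted[gi * q : (gi + 1) * q]
                assert (g.assignments.loc[block] == gi + 1).all()

    def test_constant_sscore_gives_equal_group_medians(self):
        idx = [f"m{i}" for i in range(120)]
        ss = pd.Series(1.0, index=idx)
        sig = pd.Series(np.arange(120, dtype=float), index=idx)
        g = sscore_matched_grouping(ss, sig, k=4, n_bins=2)
        med = [ss[g.members(i)].median() for i in range(1, 5)]
        assert len(set(med)) == 1

    def test_group_medians_strictly_ordered(self):
        rng = np.random.default_rng(3)
        idx = [f"m{i}" for i in range(1200)]
        ss = pd.Series(rng.normal(size=1200), index=idx)
        sig = pd.Series(rng.random(1200), index=idx)
        g = sscore_matched_grouping(ss, sig, k=6, n_bins=20)
        med = [ss[g.members(i)].median() for i in range(1, 7)]
        assert all(a > b for a, b in zip(med, med[1:]))

    def test_all_strata_too_small_is_error(self):
        idx = [f"m{i}" for i in range(8)]
        ss = pd.Series(np.arange(8.0), index=idx)
        sig = pd.Series(np.arange(8.0), index=idx)
        with pytest.raises(ValueError, match="fewer motifs than k"):
            sscore_matched_grouping(ss, sig, k=6, n_bins=8)


class TestCumulativeCurve:
    def test_perfect_metric_reaches_one_at_positive_fraction(self):
        idx = [f"m{i}" for i in range(100)]
        metric = pd.Series(np.arange(100, 0, -1, dtype=float), index=idx)
        feature = pd.Series([True] * 10 + [False] * 90, index=idx)
        curve = cumulative_rank_curve(metric, feature)
        xs = curve["x"].to_numpy()
        ys = curve["y"].to_numpy()
        assert ys[np.searchsorted(xs, 10 / 100)] == 1.0
        assert curve_auc(curve) == pytest.approx(1 - 10 / (2 * 100))

    def test_curve_non_decreasing_and_ends_at_one(self):
        rng = np.random.default_rng(5)
        idx = [f"m{i}" for i in range(500)]
        metric = pd.Series(rng.normal(size=500), index=idx)
        feature = pd.Series(rng.random(500) < 0.3, index=idx)
        curve = cumulative_rank_curve(metric, feature)
        assert (np.diff(curve["y"]) >= 0).all()
        assert curve["y"].iloc[-1] == 1.0

    def test_independent_metric_tracks_diagonal(self):
        rng = np.random.default_rng(6)
        n = 10_000
        idx = [f"m{i}" for i in range(n)]
        metric = pd.Series(rng.normal(size=n), index=idx)
        feature = pd.Series(rng.random(n) < 0.2, index=idx)
        curve = cumulative_rank_curve(metric, feature)
        dev = np.abs(curve["y"] - curve["x"]).mean()
        assert dev < 0.03

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(7)
        n = 1000
        idx = [f"m{i}" for i in range(n)]
        metric = pd.Series(rng.normal(size=n), index=idx)
        feature = pd.Series(rng.random(n) < 0.25, index=idx)
        a = curve_auc(cumulative_rank_curve(metric, feature))
        b = curve_auc(cumulative_rank_curve(-metric, feature))
        assert a + b == pytest.approx(1.0, abs=5 / n)

    def test_no_positives_is_error(self):
        idx = list("abc")
        with pytest.raises(ValueError, match="positive"):
            cumulative_rank_curve(
                pd.Series([1.0, 2.0, 3.0], index=idx),
                pd.Series([False] * 3, index=idx),
            )


class TestMetricComparison:
    def test_identical_metrics_equal_auc_and_unit_p(self):
        rng = np.random.default_rng(8)
        idx = [f"m{i}" for i in range(300)]
        m = pd.Series(rng.normal(size=300), index=idx)
        feature = pd.Series(rng.random(300) < 0.3, index=idx)
        table = rank_metric_comparison({"a": m, "b": m.copy()}, feature)
        assert table.loc["a", "auc"] == table.loc["b", "auc"]
        assert table.loc["a", "p_vs_b"] == pytest.approx(1.0)

    def test_mismatched_motif_sets_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        b = pd.Series([1.0, 2.0], index=["x", "z"])
        feature = pd.Series([True, False], index=["x", "y"])
        with pytest.raises(ValueError, match="same motif set"):
            rank_metric_comparison({"a": a, "b": b}, feature)

    def test_half_split_reports_both_halves(self):
        rng = np.random.default_rng(9)
        idx = [f"m{i}" for i in range(400)]
        m = pd.Series(rng.normal(size=400), index=idx)
        feature = pd.Series(rng.random(400) < 0.4, index=idx)
        table = rank_metric_comparison({"a": m}, feature, half_split=True)
        assert {"auc_upper", "auc_lower"} <= set(table.columns)
        assert np.isfinite(table.loc["a", "auc_upper"])
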