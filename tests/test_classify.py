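import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plvnet.classify import (
    _l1_logistic_path, _lambda_grid, _standardize, bca_interval, bolasso,
    confusion_metrics, lasso_cv, permutation_test, roc_auc, run_comparison,
    sparsity_label,
)


def _planted(rng, n0=24, n1=18, p=40, effect=2.0, idx=(3, 7)):
    X = rng.standard_normal((n0 + n1, p))
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    X[y == 1, idx[0]] += effect
    X[y == 1, idx[1]] -= effect
    return X, y


class TestLassoPath:
    def test_lambda_max_zeroes_every_coefficient(self, rng):
        X, y = _planted(rng)
        xs, _, _ = _standardize(X)
        lams = _lambda_grid(xs, y, 30, 1e-2)
        coefs, _ = _l1_logistic_path(xs, y.astype(float), lams)
        assert np.all(coefs[0] == 0.0)

    def test_kkt_conditions_along_path(self, rng):
        # independent optimality oracle: at a solution of
        # (1/n) sum NLL + lam*|beta|_1 the score s = (1/n) X'(y - p) must
        # satisfy |s_j| <= lam for zero coefs and s_j = lam*sign(beta_j)
        # for active coefs
        X, y = _planted(rng, effect=1.0)
        xs, _, _ = _standardize(X)
        lams = _lambda_grid(xs, y, 10, 1e-2)
        coefs, icpts = _l1_logistic_path(xs, y.astype(float), lams)
        n = len(y)
        for li in (0, 4, 9):
            eta = xs @ coefs[li] + icpts[li]
            prob = 1 / (1 + np.exp(-eta))
            score = xs.T @ (y - prob) / n
            active = coefs[li] != 0
            assert np.all(np.abs(score[~active]) <= lams[li] + 1e-5)
            assert np.allclose(score[active],
                               lams[li] * np.sign(coefs[li][active]), atol=1e-5)
            assert abs(np.mean(y - prob)) < 1e-6  # unpenalized intercept

    def test_objective_not_worse_than_liblinear(self, rng):
        from sklearn.linear_model import LogisticRegression

        X, y = _planted(rng, effect=1.0)
        xs, _, _ = _standardize(X)
        lams = _lambda_grid(xs, y, 5, 1e-1)
        coefs, icpts = _l1_logistic_path(xs, y.astype(float), lams)

        def objective(beta, b0, lam):
            eta = xs @ beta + b0
            nll = np.mean(np.log1p(np.exp(-np.where(y == 1, eta, -eta))))
            return nll + lam * np.abs(beta).sum()

        for li in range(len(lams)):
            ref = LogisticRegression(l1_ratio=1.0, C=1 / (len(y) * lams[li]),
                                     solver="liblinear", tol=1e-9,
                                     max_iter=10000).fit(xs, y)
            ours = objective(coefs[li], icpts[li], lams[li])
            theirs = objective(ref.coef_[0], ref.intercept_[0], lams[li])
            assert ours <= theirs + 1e-6


class TestLassoCv:
    def test_planted_feature_selected_at_lambda_min(self, rng):
        X, y = _planted(rng, effect=3.0)
        res = lasso_cv(X, y, rng=1)
        assert res.coef_min[3] != 0.0
        assert res.coef_min[7] != 0.0

    def test_lambda_1se_is_sparser_and_larger(self, rng):
        X, y = _planted(rng)
        res = lasso_cv(X, y, rng=2)
        assert res.lambda_1se >= res.lambda_min
        assert res.k_1se <= res.k_min

    @pytest.mark.parametrize("k,label", [
        (0, "intercept_only"), (1, "single_feature"), (2, "sparse_multivariate"),
        (5, "sparse_multivariate"), (6, "compact_multivariate"),
        (7, "compact_multivariate"),
    ])
    def test_sparsity_terminology(self, k, label):
        assert sparsity_label(k) == label

    def test_out_of_fold_scores_have_no_leakage(self, rng):
        # recompute one fold's model from scratch on its training subjects
        # only and confirm it reproduces the stored out-of-fold scores
        X, y = _planted(rng)
        res = lasso_cv(X, y, rng=3)
        fold = res.fold_assignments
        te = np.flatnonzero(fold == 0)
        tr = np.flatnonzero(fold != 0)
        assert set(te) & set(tr) == set()
        xs_tr, mu, sd = _standardize(X[tr])
        lam_idx = int(np.argmin(np.abs(res.lambda_path - res.lambda_min)))
        coefs, icpts = _l1_logistic_path(xs_tr, y[tr].astype(float),
                                         res.lambda_path)
        xs_te = (X[te] - mu) / sd
        prob = 1 / (1 + np.exp(-(xs_te @ coefs[lam_idx] + icpts[lam_idx])))
        assert np.allclose(prob, res.oof_scores[te], atol=1e-10)

    def test_constant_feature_dropped_with_warning(self, rng, caplog):
        X, y = _planted(rng)
        X[:, 11] = 2.5
        with caplog.at_level("WARNING"):
            res = lasso_cv(X, y, rng=4)
        assert res.coef_min[11] == 0.0
        assert any("constant" in r.message for r in caplog.records)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="two classes"):
            lasso_cv(X, np.zeros(20, int), rng=0)


class TestBolasso:
    def test_strong_feature_stably_selected(self, rng):
        X, y = _planted(rng, effect=4.0)
        res = bolasso(X, y, B=30, rng=5)
        assert res.selection_frequency[3] >= 0.85
        assert "x3" in res.retained

    def test_threshold_zero_retains_everything_ever_selected(self, rng):
        X, y = _planted(rng)
        res = bolasso(X, y, B=10, threshold=0.0, rng=6)
        ever = res.selection_frequency > 0
        assert set(res.retained) == {f"x{i}" for i in np.flatnonzero(ever)}

    def test_pure_noise_rarely_stable(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 40))
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            res = bolasso(X, y, B=25, rng=rng)
            hits += len(res.retained) > 0
        assert hits <= 1

    def test_frequencies_are_multiples_of_one_over_B(self, rng):
        X, y = _planted(rng)
        res = bolasso(X, y, B=20, rng=7)
        assert np.allclose(res.selection_frequency * 20,
                           np.round(res.selection_frequency * 20))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=50, rng=0)
        assert res.auc == pytest.approx(1.0)

    def test_mann_whitney_pair_count_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs concordant
        res = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], n_boot=50, rng=0)
        assert res.auc == pytest.approx(0.75)

    def test_trapezoid_equals_mann_whitney_on_random_scores(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scores = rng.uniform(size=30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            res = roc_auc(scores, labels, n_boot=10, rng=rng)
            u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0])
            expected = u.statistic / (np.sum(labels == 1) * np.sum(labels == 0))
            assert res.auc == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_null_centers_at_half(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(size=40)
        aucs = [roc_auc(scores, rng.permutation([0] * 20 + [1] * 20),
                        n_boot=10, rng=rng).auc for _ in range(100)]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1], n_boot=10, rng=0)


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        m = confusion_metrics(tp=9, fp=2, fn=1, tn=8)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.80)
        assert m["precision"] == pytest.approx(9 / 11)
        assert m["f1"] == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_all_correct_gives_ones(self):
        m = confusion_metrics(tp=5, fp=0, fn=0, tn=5)
        assert all(v == 1.0 for v in m.values())

    def test_undefined_precision_reported_missing(self):
        m = confusion_metrics(tp=0, fp=0, fn=3, tn=7)
        assert np.isnan(m["precision"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 1)


class TestPermutation:
    @staticmethod
    def _stat(d, lab):
        return float(d[lab == 1].mean() - d[lab == 0].mean())

    def test_extreme_statistic_printed_and_smoothed_forms(self):
        data = np.r_[np.zeros(10), np.ones(10) + 100.0]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        res = permutation_test(self._stat, data, labels, M=200, rng=0)
        assert res.p_raw <= 1 / 200  # identity permutation may recur
        assert res.p_smoothed >= 1 / 201

    def test_label_invariant_statistic_gives_p_one(self):
        res = permutation_test(lambda d, l: 1.0, np.arange(10.0),
                               np.r_[np.zeros(5, int), np.ones(5, int)],
                               M=100, rng=1)
        assert res.p_raw == 1.0

    def test_exhaustive_matches_independent_enumeration(self):
        # oracle: enumerate all C(8,4) assignments by hand
        from itertools import combinations

        rng = np.random.default_rng(2)
        data = rng.normal(size=8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = permutation_test(self._stat, data, labels, exhaustive=True)
        obs = self._stat(data, labels)
        null = []
        for pos in combinations(range(8), 4):
            lab = np.zeros(8, int)
            lab[list(pos)] = 1
            null.append(self._stat(data, lab))
        expected = np.mean(np.asarray(null) >= obs)
        assert res.M == 70
        assert res.p_raw == pytest.approx(expected, abs=1e-15)

    def test_calibration_under_exchangeability(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            data = rng.standard_normal(30)
            res = permutation_test(
                lambda d, l: abs(self._stat(d, l)), data, labels, M=100, rng=rng)
            rejections += res.p_raw <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_small_M_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            permutation_test(self._stat, np.arange(6.0),
                             np.array([0, 0, 0, 1, 1, 1]), M=50, rng=0)


class TestBcaInterval:
    def test_degenerate_data_zero_width(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_interval(np.mean, np.full(10, 3.3), n_boot=100, rng=0)
        assert lo == hi == pytest.approx(3.3)

    def test_symmetric_case_close_to_percentile(self):
        rng = np.random.default_rng(4)
        sample = rng.normal(5, 1, 60)
        lo, hi = bca_interval(np.mean, sample, n_boot=2000, rng=5)
        # independent percentile oracle
        boots = np.array([rng.choice(sample, 60).mean() for _ in range(2000)])
        plo, phi = np.quantile(boots, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.1)
        assert hi == pytest.approx(phi, abs=0.1)

    def test_two_sample_statistic(self, rng):
        a, b = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        lo, hi = bca_interval(lambda x, y: np.mean(x) - np.mean(y), (a, b),
                              n_boot=500, rng=6)
        assert lo < np.mean(a) - np.mean(b) < hi

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bca_interval(np.mean, np.arange(3.0), n_boot=100, rng=0)


class TestRunComparison:
    def _features(self, rng):
        n0, n1 = 14, 12
        rows = []
        for gi, (group, n) in enumerate((("HC", n0), ("PDD", n1))):
            for i in range(n):
                row = {"subject": f"{group}{i}", "group": group}
                for j in range(8):
                    shift = -0.15 if (gi == 1 and j < 2) else 0.0
                    row[f"P{j}"] = 0.4 + shift + rng.normal(0, 0.05)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_report_schema_covers_summary_columns(self, rng):
        report = run_comparison(self._features(rng), "HC_vs_PDD", "delta",
                                rng=1, cv_folds=5, n_lambda=40, bolasso_B=15,
                                n_boot=50, n_perm=100)
        row = report.summary_row()
        for col in ("f1", "precision", "sensitivity", "specificity",
                    "lambda_min", "lambda_1se", "K_min", "K_1se",
                    "auc_overall", "auc_ci_low", "auc_ci_high"):
            assert col in row
        assert set(report.feature_table.columns) >= {
            "feature", "coefficient", "auc_mean", "auc_sd", "perm_p", "perm_q"}

    def test_planted_features_dominate_report(self, rng):
        report = run_comparison(self._features(rng), "HC_vs_PDD", "delta",
                                rng=2, cv_folds=5, n_lambda=40, bolasso_B=15,
                                n_boot=50, n_perm=100)
        top = list(report.feature_table["feature"][:2])
        assert set(top) & {"P0", "P1"}
        assert report.roc.auc > 0.8

    def test_unknown_comparison_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown comparison"):
            run_comparison(self._features(rng), "HC_vs_XX", "delta")
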