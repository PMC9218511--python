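import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxgnet import classify
from toxgnet.classify import (
    KernelSpec,
    _fit_decision,
    accuracy,
    auc,
    kernel_grid,
    loocv_sweep,
    per_chemical_report,
    random_baseline,
    rank_features_ttest,
    significance_test,
    transfer_predict,
    welch_t,
)
from toxgnet.io import CATEGORIES, DataError

FAST = [KernelSpec("linear", 1.0)]


class TestRanking:
    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 5))
        x[:, 2] = 4.0  # identical across classes -> t = 0
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        assert rank_features_ttest(x, y)[-1] == 2

    def test_separating_low_variance_feature_ranked_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 5))
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        x[:, 3] = np.where(y == 1, 10.0, -10.0) + rng.normal(0, 1e-6, 10)
        assert rank_features_ttest(x, y)[0] == 3

    def test_matches_brute_force_welch(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 8))
        y = np.array([1, 0, 1, 0, 1, 0])
        t_mine = welch_t(x, y)
        t_oracle = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False).statistic
        np.testing.assert_allclose(t_mine, t_oracle, atol=1e-12)
        order = rank_features_ttest(x, y)
        expected = np.lexsort((np.arange(8), -np.abs(t_oracle)))
        np.testing.assert_array_equal(order, expected)

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="both classes"):
            welch_t(np.ones((4, 2)), np.ones(4))


class TestMetrics:
    def test_accuracy_formula(self):
        assert abs(accuracy(10, 10, 2, 2) - 83.33333333) < 1e-6
        assert accuracy(24, 0, 0, 0) == 100.0

    def test_accuracy_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pred = rng.integers(0, 2, 30)
            truth = rng.integers(0, 2, 30)
            tp = int(((pred == 1) & (truth == 1)).sum())
            tn = int(((pred == 0) & (truth == 0)).sum())
            fp = int(((pred == 1) & (truth == 0)).sum())
            fn = int(((pred == 0) & (truth == 1)).sum())
            assert abs(accuracy(tp, tn, fp, fn) - 100.0 * (pred == truth).mean()) < 1e-9

    def test_accuracy_zero_total_rejected(self):
        with pytest.raises(DataError, match="zero"):
            accuracy(0, 0, 0, 0)

    def test_auc_extremes(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    def test_auc_ties_match_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 4, 40).astype(float)  # heavy ties
        y = rng.integers(0, 2, 40)
        got = auc(d, y)
        pos, neg = d[y == 1], d[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert abs(got - wins / (len(pos) * len(neg))) < 1e-12
        # independent library oracle
        from sklearn.metrics import roc_auc_score

        assert abs(got - roc_auc_score(y, d)) < 1e-12

    def test_auc_one_class_rejected(self):
        with pytest.raises(DataError, match="both classes"):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))


def test_fast_libsvm_agrees_with_svc():
    """The low-level solver path must reproduce SVC decision values
    (sign and magnitude) across random problems and C values."""
    from sklearn.svm import SVC

    rng = np.random.default_rng(5)
    for trial in range(10):
        n = rng.integers(10, 20)
        x = rng.normal(size=(n, 6))
        y = rng.integers(0, 2, n)
        if y[:-1].sum() in (0, n - 1):
            continue
        k = x @ x.T
        c = float(rng.choice([0.1, 1.0, 10.0]))
        mine = _fit_decision(k[:-1, :-1], y[:-1], k[-1:, :-1], c)
        ref = SVC(kernel="precomputed", C=c).fit(k[:-1, :-1], y[:-1])
        np.testing.assert_allclose(mine, ref.decision_function(k[-1:, :-1]), atol=1e-8)


class TestLoocvSweep:
    def test_planted_separating_edge_gives_100(self):
        rng = np.random.default_rng(6)
        y = (np.arange(20) < 10).astype(int)
        x = rng.normal(0, 0.1, (20, 30))
        x[:, 7] = np.where(y == 1, 5.0, -5.0) + rng.normal(0, 0.1, 20)
        run = loocv_sweep(x, y, kernels=FAST)
        assert run.max_accuracy == 100.0
        assert run.auc_at_max == 1.0

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DataError, match="per class"):
            loocv_sweep(np.ones((6, 3)), np.ones(6), kernels=FAST)

    def test_max_accuracy_monotone_in_grid_size(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, (16, 25))
        y = (np.arange(16) < 8).astype(int)
        small = kernel_grid("reduced")[:2]
        large = small + kernel_grid("reduced")[2:]
        acc_small = loocv_sweep(x, y, kernels=small).max_accuracy
        acc_large = loocv_sweep(x, y, kernels=large).max_accuracy
        assert acc_large >= acc_small

    def test_reported_auc_equals_mann_whitney_on_decisions(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(14, 10))
        y = (np.arange(14) < 7).astype(int)
        run = loocv_sweep(x, y, kernels=FAST)
        assert abs(run.auc_at_max - auc(run.decisions, y)) < 1e-12

    def test_permuted_labels_match_random_feature_baseline(self):
        """Label permutation and uniform-random features are equivalent
        nulls: their mean max accuracies agree within sampling error."""
        rng = np.random.default_rng(9)
        y = (np.arange(20) < 10).astype(int)
        perm_accs, rand_accs = [], []
        for rep in range(4):
            x = rng.normal(size=(20, 40))
            perm_accs.append(
                loocv_sweep(x, rng.permutation(y), kernels="reduced").max_accuracy
            )
            rand_accs.append(
                loocv_sweep(rng.uniform(-1, 1, (20, 40)), y, kernels="reduced").max_accuracy
            )
        assert abs(np.mean(perm_accs) - np.mean(rand_accs)) < 15.0


def test_leakage_guard():
    """A feature that encodes the held-out label but is constant in every
    training fold must leave all decisions untouched: fold-internal ranking
    puts a zero-variance training column last, so it can never enter the
    top-k, and standardization statistics never see the held-out row."""
    rng = np.random.default_rng(10)
    n, p = 18, 24
    x = rng.uniform(-1, 1, (n, p))
    y = (np.arange(n) < 9).astype(int)
    k_grid = np.arange(1, p + 1)
    base = loocv_sweep(x, y, kernels="reduced", k_grid=k_grid)

    decisions = np.empty(n)
    specs = classify._resolve_grid("reduced")
    for i in range(n):
        mask = np.arange(n) != i
        x_train = np.hstack([x[mask], np.zeros((n - 1, 1))])  # leak column: constant in train
        x_test = np.hstack([x[i:i + 1], [[2.0 * y[i] - 1.0]]])  # encodes own label
        dec = classify._fold_decisions(x_train, y[mask], x_test, specs, k_grid)
        decisions[i] = dec[0, 0, 0]

    # recompute the same cell without the planted column
    plain = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        plain[i] = classify._fold_decisions(
            x[mask], y[mask], x[i:i + 1], specs, k_grid
        )[0, 0, 0]
    np.testing.assert_allclose(decisions, plain, atol=1e-10)
    # consequently the sweep's accuracy is byte-identical with or without
    # the planted column
    acc_leak = 100.0 * ((decisions > 0).astype(int) == y).mean()
    acc_plain = 100.0 * ((plain > 0).astype(int) == y).mean()
    assert acc_leak == acc_plain
    assert base.max_accuracy >= acc_plain - 1e-9  # sanity: cell is in the sweep


class TestTransfer:
    def _es_frame(self, seed=11, n=16, p=20):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"chem{i}" for i in range(n)], name="chemical")
        cols = [f"e{i}" for i in range(p)]
        return pd.DataFrame(rng.normal(size=(n, p)), index=idx, columns=cols)

    def test_identical_domains_reduce_to_plain_loocv(self):
        es = self._es_frame()
        y = (np.arange(16) < 8).astype(int)
        stacked = transfer_predict(es, es.copy(), y, mode="stacked", kernels=FAST)
        plain = loocv_sweep(es, y, kernels=FAST)
        np.testing.assert_allclose(stacked.decisions, plain.decisions, atol=1e-10)
        assert stacked.max_accuracy == plain.max_accuracy

    def test_concat_mode_uses_double_feature_space(self):
        es = self._es_frame()
        ips = self._es_frame(seed=12)
        y = (np.arange(16) < 8).astype(int)
        run = transfer_predict(es, ips, y, mode="concat", kernels=FAST,
                               k_grid=np.array([2 * es.shape[1]]))
        assert run.best_k == 2 * es.shape[1]
        assert run.mode == "transfer-concat"

    def test_edge_mismatch_rejected(self):
        es = self._es_frame()
        ips = es.copy()
        ips.columns = [c + "_x" for c in ips.columns]
        with pytest.raises(DataError, match="mismatch"):
            transfer_predict(es, ips, (np.arange(16) < 8).astype(int))

    def test_transferable_signal_recovered(self):
        """Shared category signal plus a small domain shift: predictions of
        the unlabeled domain reach high AUC."""
        rng = np.random.default_rng(13)
        n, p = 20, 30
        y = (np.arange(n) < 10).astype(int)
        signal = np.outer(2 * y - 1, rng.normal(1.0, 0.2, 5))
        base = rng.normal(size=(n, p))
        base[:, :5] += signal
        es = pd.DataFrame(base + rng.normal(0, 0.3, (n, p)),
                          index=[f"c{i}" for i in range(n)],
                          columns=[f"e{i}" for i in range(p)])
        ips = pd.DataFrame(base + 0.5 + rng.normal(0, 0.3, (n, p)),
                           index=es.index, columns=es.columns)
        run = transfer_predict(es, ips, y, mode="stacked", kernels="reduced")
        assert run.auc_at_max > 0.9


class TestBaselineAndSignificance:
    def test_baseline_deterministic_under_seed(self):
        y = (np.arange(12) < 6).astype(int)
        b1 = random_baseline(y, n_features=15, n_rep=3, seed=42, kernels=FAST)
        b2 = random_baseline(y, n_features=15, n_rep=3, seed=42, kernels=FAST)
        assert b1.max_accuracies == b2.max_accuracies
        assert len(
            random_baseline(y, n_features=15, n_rep=10, seed=0, kernels=FAST).max_accuracies
        ) == 10

    def test_significance_symmetric_null(self):
        res = significance_test(80.0, [70, 75, 80, 85, 90, 80, 80, 80, 80, 80])
        assert abs(res.p_one_sided - 0.5) < 1e-12
        assert res.df == 9

    def test_significance_one_sided_direction(self):
        res = significance_test(60.0, [70, 75, 80, 85, 90, 72, 78, 81, 79, 83])
        assert res.p_one_sided > 0.5
        assert not res.significant_05

    def test_printed_worked_example(self):
        """actual 91.7 against a 10-replicate baseline with mean 83.7 and
        SD 6.92 is significant at the 1% level (t about 3.66 on 9 df)."""
        rng = np.random.default_rng(14)
        for _ in range(50):
            vals = rng.normal(83.7, 6.92, 10)
            vals = (vals - vals.mean()) / vals.std(ddof=1) * 6.92 + 83.7
            res = significance_test(91.7, vals)
            assert abs(res.t_stat - 3.6556) < 1e-3
            assert res.p_one_sided < 0.01
            # oracle: explicit t tail
            p_oracle = stats.t.sf(res.t_stat, 9)
            assert abs(res.p_one_sided - p_oracle) < 1e-12

    def test_zero_sd_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="zero baseline SD"):
            res = significance_test(90.0, [80.0] * 10)
        assert res.p_one_sided == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(DataError, match=">= 2"):
            significance_test(90.0, [80.0])


class TestPerChemicalReport:
    def _runs(self, correct_map):
        chems = ["a", "b", "c"]
        runs = {}
        for cat in CATEGORIES:
            y = np.array([1, 0, 1])
            pred = y.copy()
            for ci, chem in enumerate(chems):
                if not correct_map[chem][cat]:
                    pred[ci] = 1 - y[ci]
            runs[cat] = classify.PredictionRun(
                category=cat, chemicals=chems, y_true=y,
                decisions=np.where(pred == 1, 1.0, -1.0), predicted=pred,
                best_kernel="linear(C=1)", best_k=1, max_accuracy=0.0, auc_at_max=0.0,
            )
        return runs

    def test_fractions_match_counting_oracle(self):
        correct = {
            "a": {c: True for c in CATEGORIES},
            "b": {c: (c not in ("NT", "HT")) for c in CATEGORIES},
            "c": {c: (c in ("NT", "HT", "CT", "GT")) for c in CATEGORIES},
        }
        report = per_chemical_report(self._runs(correct))
        assert report.loc["a", "percent_correct"] == 100.0
        assert abs(report.loc["b", "percent_correct"] - 100.0 * 4 / 6) < 1e-9
        assert abs(report.loc["c", "percent_correct"] - 100.0 * 4 / 6) < 1e-9

    def test_missing_category_rejected(self):
        runs = self._runs({c: {k: True for k in CATEGORIES} for c in "abc"})
        runs.pop("TT")
        with pytest.raises(DataError, match="TT"):
            per_chemical_report(runs)


def test_lfc_feature_matrix_caps_columns():
    rng = np.random.default_rng(15)
    rows = [(f"c{i}", d) for i in range(4) for d in ("1/2", "1/1")]
    lfc = pd.DataFrame(
        rng.normal(size=(8, 120)),
        index=pd.MultiIndex.from_tuples(rows, names=["chemical", "dose_level"]),
        columns=[f"g{i}" for i in range(120)],
    )
    wide = classify.lfc_feature_matrix(lfc, max_features=190)
    assert wide.shape == (4, 190)  # 120 genes x 2 doses = 240, capped at 190
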