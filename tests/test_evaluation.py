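import numpy as np
import pytest

from triplexpot.cnn import CNNConfig
from triplexpot.evaluation import (
    ConfusionCounts,
    confusion,
    evaluate_scores,
    metrics_from_counts,
    run_cross_validation,
    run_leave_gene_out,
)
from triplexpot.features import fit_class_means
from triplexpot.io import Dataset
from triplexpot.sampling import BaggingConfig

FAST_CNN = CNNConfig(epochs=10, dropout_rate=0.0)


def rank_auroc(y, s):
    """Independent oracle: concordance (rank-statistic) formulation."""
    pos = s[y == 1]
    neg = s[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def tally_metrics(y, p):
    """Independent tally of the five closed-form metrics."""
    tp = sum(a == 1 and b == 1 for a, b in zip(y, p))
    tn = sum(a == 0 and b == 0 for a, b in zip(y, p))
    fp = sum(a == 0 and b == 1 for a, b in zip(y, p))
    fn = sum(a == 1 and b == 0 for a, b in zip(y, p))
    acc = (tp + tn) / len(y)
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    pre = tp / (tp + fp)
    return dict(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, sn=sn, sp=sp,
                hm=2 * sn * sp / (sn + sp), f1=2 * pre * sn / (pre + sn))


class TestConfusion:
    def test_hand_tally(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_on_all_negative(self):
        c = confusion([0, 0, 0], [1, 1, 1])
        assert c.tn == 0 and c.fp == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_derived_example(self):
        c = ConfusionCounts(tp=9, fn=1, tn=8, fp=2)
        r = metrics_from_counts(c)
        assert r.sn == pytest.approx(0.9)
        assert r.sp == pytest.approx(0.8)
        assert r.acc == pytest.approx(0.85)
        assert r.hm == pytest.approx(2 * 0.9 * 0.8 / 1.7)
        assert r.pre == pytest.approx(9 / 11)
        assert r.f1 == pytest.approx(2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9))

    def test_identities_against_independent_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            p = rng.integers(0, 2, size=n)
            if y.min() == y.max() or not ((y == 0) & (p == 0)).any() \
                    or not ((y == 1) & (p == 1)).any() or not (p == 1).any():
                continue
            r = metrics_from_counts(confusion(y, p))
            expect = tally_metrics(y, p)
            for key in ("acc", "sn", "sp", "hm", "f1"):
                assert getattr(r, key) == pytest.approx(expect[key]), key

    def test_acc_is_sn_sp_weighted_average(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            r = metrics_from_counts(confusion(y, p))
            P, N = (y == 1).sum(), (y == 0).sum()
            if r.sn is None or r.sp is None:
                continue
            assert r.acc == pytest.approx((r.sn * P + r.sp * N) / (P + N))

    def test_hm_bounded_by_max_and_equal_case(self):
        r = metrics_from_counts(ConfusionCounts(tp=3, fn=1, tn=6, fp=2))
        assert r.hm <= max(r.sn, r.sp) + 1e-12
        r2 = metrics_from_counts(ConfusionCounts(tp=3, fn=1, tn=3, fp=1))
        assert r2.hm == pytest.approx(r2.sn)

    def test_undefined_denominators_absent_not_zero(self):
        with pytest.warns(UserWarning, match="sn undefined"):
            r = metrics_from_counts(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert r.sn is None and r.hm is None

    def test_auroc_trapezoid_matches_rank_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(6, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = rng.random(n)  # continuous, ties almost surely absent
            r = metrics_from_counts(confusion(y, (s >= 0.5).astype(int)), s, y)
            assert r.auroc == pytest.approx(rank_auroc(y, s), abs=1e-9)

    def test_auroc_with_ties_matches_rank_oracle(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.5, 0.5, 0.1, 0.5, 0.9])
        r = metrics_from_counts(confusion(y, (s >= 0.5).astype(int)), s, y)
        assert r.auroc == pytest.approx(rank_auroc(y, s), abs=1e-9)

    def test_perfect_and_degenerate_scores(self):
        y = np.array([1, 1, 0, 0])
        r = evaluate_scores(y, [0.9, 0.8, 0.2, 0.1])
        assert r.auroc == 1.0 and r.auprc == 1.0
        r2 = evaluate_scores(y, [0.5, 0.5, 0.5, 0.5])
        assert r2.auroc == 0.5

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            evaluate_scores([1, 0], [1.5, 0.2])


class TestCrossValidation:
    def test_partition_and_report_count(self, small_data):
        pos, neg = small_data
        cv = run_cross_validation(pos, neg, n_folds=4, cnn=FAST_CNN, seed=0,
                                  bagging=BaggingConfig(seed=0))
        assert cv.n_folds == 4
        # every record of each class lands in exactly one test fold
        tested = [rid for f in range(4) for rid in cv.split.fold_ids(f)]
        assert sorted(tested) == sorted(pos.ids + neg.ids)
        # test folds keep natural imbalance: per-fold evaluated count
        for rep in cv.per_fold:
            assert rep.counts.total == len(rep.scores)

    def test_profile_leakage_guard(self, small_data):
        """Test-fold sequences never contribute to the fitted class means."""
        from triplexpot.sampling import stratified_kfold
        from triplexpot.io import NEGATIVE, POSITIVE

        pos, neg = small_data
        pos, neg = pos.with_label(POSITIVE), neg.with_label(NEGATIVE)
        combined = Dataset(pos.records + neg.records, name="all")
        plan = stratified_kfold(combined, 4, seed=0)
        train_pos, test_pos = plan.split(pos, 0)
        train_neg, _ = plan.split(neg, 0)
        prof_train = fit_class_means(train_pos, train_neg)
        prof_all = fit_class_means(pos, train_neg)
        assert not np.allclose(prof_train.m_pos[3], prof_all.m_pos[3])
        # and recomputing from the same training records reproduces it exactly
        again = fit_class_means(train_pos, train_neg)
        assert np.array_equal(prof_train.m_pos[3], again.m_pos[3])

    def test_no_bagging_path_runs(self, small_data):
        pos, neg = small_data
        cv = run_cross_validation(pos, neg, n_folds=3, cnn=FAST_CNN, seed=1,
                                  bagging=None)
        assert cv.n_folds == 3

    def test_seeded_reproducibility(self, small_data):
        pos, neg = small_data
        a = run_cross_validation(pos, neg, n_folds=3, cnn=FAST_CNN, seed=5)
        b = run_cross_validation(pos, neg, n_folds=3, cnn=FAST_CNN, seed=5)
        assert np.array_equal(a.per_fold[0].scores, b.per_fold[0].scores)
        assert a.mean("auroc") == b.mean("auroc")

    def test_summary_table_shape(self, small_data):
        pos, neg = small_data
        cv = run_cross_validation(pos, neg, n_folds=3, cnn=FAST_CNN, seed=2)
        df = cv.summary()
        assert list(df.index) == ["fold0", "fold1", "fold2", "mean"]
        assert "auroc" in df.columns


class TestLeaveGeneOut:
    def test_rep_count_and_gene_holdout(self, small_data):
        pos, neg = small_data
        gene = pos[0].gene
        n_variants = sum(r.gene == gene for r in pos)
        reports = run_leave_gene_out(pos, neg, gene, reps=3, cnn=FAST_CNN, seed=0,
                                     bagging=None)
        assert len(reports) == 3
        for rep in reports:
            assert int(rep.y_true.sum()) == n_variants

    def test_unknown_gene_error(self, small_data):
        pos, neg = small_data
        with pytest.raises(ValueError, match="not found"):
            run_leave_gene_out(pos, neg, "NO_SUCH_GENE", reps=2, cnn=FAST_CNN)
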