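"""Fold plans, pooled metrics, ROC/AUC oracle equivalence, DeLong and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepradiomics import (
    CVReport,
    DegenerateInputError,
    SVMConfig,
    bh_adjust,
    compare_models,
    confusion_metrics,
    delong_paired_test,
    holdout_ensemble_eval,
    layer_sweep,
    make_fold_plan,
    permutation_auc_test,
    roc_auc,
    run_nested_cv,
)
from deepradiomics.evalcv import FoldPlan, LeakageError


def brute_force_auc(p, y):
    """All-pairs concordance: P(p_pos > p_neg) + 0.5 P(p_pos = p_neg)."""
    p = np.asarray(p, float)
    pos, neg = p[np.asarray(y) == 1], p[np.asarray(y) == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestFoldPlan:
    def test_206_subjects_five_folds(self):
        y = np.r_[np.ones(146, int), np.zeros(60, int)]
        plan = make_fold_plan(y, K=5, seed=1)
        sizes = sorted(np.bincount(np.asarray(plan.assignments))[1:].tolist())
        assert sizes == [41, 41, 41, 41, 42]
        # stratification: per-fold class counts within 1 of proportional
        for k in range(1, 6):
            idx = np.asarray(plan.assignments) == k
            assert abs(y[idx].sum() - 146 / 5) <= 1

    def test_balanced_ten_forced_assignment(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        plan = make_fold_plan(y, K=5, seed=0)
        for k in range(1, 6):
            idx = np.asarray(plan.assignments) == k
            assert y[idx].sum() == 1 and idx.sum() == 2

    def test_determinism_and_partition(self):
        y = np.r_[np.ones(20, int), np.zeros(15, int)]
        p1 = make_fold_plan(y, K=5, seed=7)
        p2 = make_fold_plan(y, K=5, seed=7)
        assert p1.assignments == p2.assignments
        assert set(p1.assignments) == {1, 2, 3, 4, 5}

    def test_small_class_rejected(self):
        y = np.r_[np.ones(20, int), np.zeros(3, int)]
        with pytest.raises(ValueError):
            make_fold_plan(y, K=5, seed=0)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, sens, spec",
        [
            ((132, 27, 33, 14), 0.904, 0.550),
            ((133, 23, 37, 13), 0.911, 0.617),
            ((135, 26, 34, 11), 0.925, 0.567),
        ],
    )
    def test_pooled_count_rows(self, counts, sens, spec):
        s, p, _ = confusion_metrics(*counts)
        assert round(s, 3) == sens and round(p, 3) == spec

    def test_perfect_classifier(self):
        assert confusion_metrics(7, 0, 5, 0) == (1.0, 1.0, 1.0)

    def test_definitional_ratios_exact(self):
        s, p, _ = confusion_metrics(132, 27, 33, 14)
        assert abs(s - 132 / 146) < 1e-12 and abs(p - 33 / 60) < 1e-12

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            confusion_metrics(5, 0, 0, 0)


class TestRocAuc:
    def test_perfect_equal_and_example(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5
        _, auc = roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == 0.75  # 3 of 4 concordant pairs

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = rng.integers(4, 50)
            y = np.r_[np.ones(2, int), np.zeros(2, int),
                      (rng.random(n - 4) < 0.5).astype(int)]
            p = np.round(rng.random(n), 2)  # rounding forces ties
            _, auc = roc_auc(p, y)
            assert auc == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(18)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        pts, _ = roc_auc(rng.random(40), y)
        assert (pts[0] == [0, 0]).all() and (pts[-1] == [1, 1]).all()
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([0.1, 0.9], [1, 1])


class TestComparisons:
    def _report(self, probs, y, plan):
        return CVReport(
            subject_ids=[f"s{i}" for i in range(len(y))],
            labels=np.asarray(y), probabilities=np.asarray(probs),
            fold_plan=plan, chosen_params=[], models=[],
        )

    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(19)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        p = rng.random(40)
        plan = make_fold_plan(y, K=5, seed=0)
        r = self._report(p, y, plan)
        res = compare_models([r, r], [(0, 1)])
        assert res[0].p_value == 1.0 and res[0].auc_difference == 0.0

    def test_delong_detects_a_real_difference(self):
        rng = np.random.default_rng(20)
        y = np.r_[np.ones(60, int), np.zeros(60, int)]
        good = np.r_[rng.normal(0.8, 0.1, 60), rng.normal(0.2, 0.1, 60)]
        noise = rng.random(120)
        _, p = delong_paired_test(np.clip(good, 0, 1), noise, y)
        assert p < 0.001

    def test_delong_and_permutation_agree_roughly(self):
        rng = np.random.default_rng(21)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        p1 = np.clip(np.r_[rng.normal(0.6, 0.2, 30), rng.normal(0.4, 0.2, 30)], 0, 1)
        p2 = np.clip(p1 + rng.normal(0, 0.1, 60), 0, 1)
        _, pd_ = delong_paired_test(p1, p2, y)
        _, pp = permutation_auc_test(p1, p2, y, n_permutations=400, seed=1)
        assert (pd_ < 0.05) == (pp < 0.05) or abs(pd_ - pp) < 0.2

    def test_bh_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=20))
    def test_bh_dominates_raw_and_preserves_order(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        # monotone: the order of raw p-values is preserved by the adjustment
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_unpaired_reports_rejected(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        plan_a = make_fold_plan(y, K=2, seed=0)
        plan_b = make_fold_plan(y, K=2, seed=99)
        ra = self._report(np.random.default_rng(0).random(20), y, plan_a)
        rb = self._report(np.random.default_rng(1).random(20), y, plan_b)
        with pytest.raises(ValueError, match="paired"):
            compare_models([ra, rb], [(0, 1)])


SMALL_SVM = SVMConfig(C_grid=(0.5, 2.0), gamma_grid=(0.01, 0.1), seed=0,
                      inner_folds=3)


class TestNestedCV:
    def _features(self, n=60, informative=True, seed=22):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        X = rng.normal(size=(n, 12))
        if informative:
            X[y == 1, :4] += 1.8
        return X, y

    def test_pooled_predictions_cover_cohort(self):
        X, y = self._features()
        plan = make_fold_plan(y, K=5, seed=3)
        rep = run_nested_cv(X, y, SMALL_SVM, plan)
        assert len(rep.probabilities) == len(y)
        assert rep.tp + rep.fp + rep.tn + rep.fn == len(y)
        assert abs(rep.sensitivity - rep.tp / (rep.tp + rep.fn)) < 1e-12
        assert abs(rep.specificity - rep.tn / (rep.tn + rep.fp)) < 1e-12

    def test_reproducible_bit_for_bit(self):
        X, y = self._features(40)
        plan = make_fold_plan(y, K=4, seed=3)
        r1 = run_nested_cv(X, y, SMALL_SVM, plan)
        r2 = run_nested_cv(X, y, SMALL_SVM, plan)
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)
        assert r1.chosen_params == r2.chosen_params

    def test_report_json_round_trip(self, tmp_path):
        import json

        X, y = self._features(40)
        rep = run_nested_cv(X, y, SMALL_SVM, make_fold_plan(y, K=4, seed=3))
        rep.to_json(tmp_path / "r.json")
        d = json.loads((tmp_path / "r.json").read_text())
        assert d["confusion"]["tp"] == rep.tp
        assert len(d["probabilities"]) == len(y)

    def test_layer_sweep_shares_fold_plan(self):
        X, y = self._features(40)
        plan = make_fold_plan(y, K=4, seed=3)
        mats = {0: X[:, :4], 1: X[:, :8], 2: X}
        rows = layer_sweep(mats, y, SMALL_SVM, plan)
        assert [r["L"] for r in rows] == [0, 1, 2]
        for r in rows:
            assert r["report"].fold_plan.assignments == plan.assignments


class TestHoldout:
    def test_metrics_and_leakage_guard(self):
        from deepradiomics import fit_calibrated

        rng = np.random.default_rng(23)
        X = rng.normal(size=(60, 6))
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        X[y == 1] += 3.0
        cfg = SVMConfig(C_grid=(1.0,), gamma_grid=(0.05,), inner_folds=3, seed=0)
        models = [fit_calibrated(X, y, cfg)]
        Xh = rng.normal(size=(20, 6))
        yh = np.r_[np.ones(10, int), np.zeros(10, int)]
        Xh[yh == 1] += 3.0
        res = holdout_ensemble_eval(models, Xh, yh,
                                    [f"h{i}" for i in range(20)],
                                    [f"t{i}" for i in range(60)])
        assert res["tp"] + res["fn"] == 10 and res["tn"] + res["fp"] == 10
        assert res["sensitivity"] == 1.0
        with pytest.raises(LeakageError):
            holdout_ensemble_eval(models, Xh, yh, ["t0"], ["t0"])
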