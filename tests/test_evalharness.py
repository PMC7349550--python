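"""Split-plan invariants, metric correctness and permutation nulls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from physioemo.evalharness import (NN_HIDDEN_LAYERS, SIGNAL_SETS,
                                   binary_metrics, evaluate_cell,
                                   inner_validation, make_classifier,
                                   make_split, per_class_metrics,
                                   train_and_score)

CONDS = ("neutral", "fear", "happy")


def synthetic_frames(n_subjects=12, frames_per_cond=10, seed=0,
                     informative=True):
    """Labelled feature table with a planted class signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        subj_shift = rng.standard_normal(2)
        for ci, cond in enumerate(CONDS):
            for fi in range(frames_per_cond):
                f1 = ci + 0.5 * subj_shift[0] + 0.3 * rng.standard_normal()
                f2 = -ci + 0.5 * subj_shift[1] + 0.3 * rng.standard_normal()
                if not informative:
                    f1, f2 = rng.standard_normal(2)
                rows.append({"subject_id": f"S{si:02d}", "condition": cond,
                             "frame_idx": fi, "f1": f1, "f2": f2})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def frames():
    return synthetic_frames()


class TestMakeSplit:

    @pytest.mark.parametrize("cond", ["a", "b", "c"])
    def test_train_test_disjoint_and_balanced(self, frames, cond):
        for seed in range(5):
            plan = make_split(frames, cond, 4, seed)
            assert np.intersect1d(plan.train_idx, plan.test_idx).size == 0
            for idx in (plan.train_idx, plan.test_idx):
                counts = frames.iloc[idx]["condition"].value_counts()
                assert counts.nunique() == 1  # class-balanced

    def test_condition_a_subject_independent(self, frames):
        plan = make_split(frames, "a", 4, 3)
        train_subjects = set(frames.iloc[plan.train_idx]["subject_id"])
        assert not train_subjects & set(plan.test_subjects)

    def test_condition_b_one_emotion_transferred(self, frames):
        plan = make_split(frames, "b", 4, 3)
        for s in plan.test_subjects:
            chosen = plan.transfers[s]
            tr = frames.iloc[plan.train_idx]
            te = frames.iloc[plan.test_idx]
            tr_emos = set(tr[tr.subject_id == s]["condition"])
            te_emos = set(te[te.subject_id == s]["condition"])
            assert tr_emos <= {chosen}
            assert chosen not in te_emos
            assert len(te_emos) == 2

    def test_condition_c_exact_30_percent_per_emotion(self, frames):
        plan = make_split(frames, "c", 4, 3)
        tr = frames.iloc[plan.train_idx]
        for s in plan.test_subjects:
            for cond in CONDS:
                n = int(np.sum((tr.subject_id == s) & (tr.condition == cond)))
                assert n == 3  # floor(0.3 * 10)

    def test_not_enough_subjects_rejected(self, frames):
        with pytest.raises(ValueError):
            make_split(frames, "a", 12, 0)

    def test_plans_differ_across_seeds(self, frames):
        p1 = make_split(frames, "a", 4, 1)
        p2 = make_split(frames, "a", 4, 2)
        assert p1.test_subjects != p2.test_subjects


class TestInnerValidation:
    def test_fold_sizes_and_coverage(self):
        folds = inner_validation(100, seed=0)
        assert len(folds) == 10
        for tr, val in folds:
            assert len(val) == 20
            assert len(tr) == 80
            assert set(tr) | set(val) == set(range(100))
        assert len({tuple(sorted(v)) for _, v in folds}) > 1

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            inner_validation(5, seed=0)


class TestClassifierConfig:
    def test_rf_tree_counts_follow_signal_set(self):
        assert make_classifier("rf", "all", 0).n_estimators == 10_000
        for sset in ("ecg", "emgz", "emgmf", "emg", "eda"):
            assert make_classifier("rf", sset, 0).n_estimators == 8_000
        assert make_classifier("rf", "all", 0, rf_trees=500).n_estimators == 500

    def test_nn_layer_widths(self):
        assert make_classifier("nn", "all", 0).hidden_layer_sizes == (28,)
        assert make_classifier("nn", "emgmf", 0).hidden_layer_sizes == (8, 9)
        assert make_classifier("nn", "emg", 0).hidden_layer_sizes == (10, 24)
        for sset in ("ecg", "emgz", "eda"):
            assert NN_HIDDEN_LAYERS[sset] == (12, 9, 6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("svm", "all", 0)


class TestMetrics:
    def test_hand_computed_confusion_row(self):
        m = binary_metrics(tp=8, fn=2, fp=2, tn=18)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = np.array(["fear", "happy", "neutral"] * 10)
        pc = per_class_metrics(y, y, sorted(set(y)))
        assert (pc[["f1", "sensitivity", "specificity"]] == 1.0).all().all()

    def test_per_class_matches_manual_confusion(self):
        y_true = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        y_pred = y_true.copy()
        y_pred[:2] = "b"  # 2 'a' misclassified as 'b'
        pc = per_class_metrics(y_true, y_pred, ["a", "b", "c"])
        assert pc.loc["a", "sensitivity"] == pytest.approx(0.8)
        assert pc.loc["a", "specificity"] == pytest.approx(1.0)
        assert pc.loc["b", "specificity"] == pytest.approx(18 / 20)

    def test_absent_class_flagged(self):
        y_true = np.array(["a", "b", "a", "b"])
        y_pred = np.array(["a", "b", "b", "b"])
        pc = per_class_metrics(y_true, y_pred, ["a", "b", "c"])
        assert bool(pc.loc["c", "absent_from_test"])


class TestTrainAndScore:
    def test_informative_features_scored_high(self):
        frames = synthetic_frames(seed=1)
        plan = make_split(frames, "c", 4, 5)
        factory = lambda s: RandomForestClassifier(n_estimators=60,
                                                   random_state=s, n_jobs=1)
        res = train_and_score(frames, plan, ["f1", "f2"], factory, seed=5)
        assert res.macro_f1 > 0.6  # far above the 1/3 chance level
        assert set(res.per_class.index) == set(CONDS)

    def test_label_shuffle_null_macro_f1_one_third(self):
        rng = np.random.default_rng(42)
        frames = synthetic_frames(seed=2, informative=False)
        macro = []
        for it in range(8):
            shuffled = frames.copy()
            shuffled["condition"] = rng.permutation(
                shuffled["condition"].to_numpy())
            plan = make_split(shuffled, "a", 4, it)
            factory = lambda s: RandomForestClassifier(
                n_estimators=40, random_state=s, n_jobs=1)
            res = train_and_score(shuffled, plan, ["f1", "f2"], factory,
                                  seed=it)
            macro.append(res.macro_f1)
        assert np.mean(macro) == pytest.approx(1 / 3, abs=0.08)

    def test_deterministic_rerun(self):
        frames = synthetic_frames(seed=4)
        plan = make_split(frames, "b", 4, 9)
        factory = lambda s: RandomForestClassifier(n_estimators=40,
                                                   random_state=s, n_jobs=1)
        r1 = train_and_score(frames, plan, ["f1", "f2"], factory, seed=3)
        r2 = train_and_score(frames, plan, ["f1", "f2"], factory, seed=3)
        assert r1.macro_f1 == r2.macro_f1
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)


class TestEvaluateCell:
    def test_selection_uses_train_only_and_results_aggregate(self):
        frames = synthetic_frames(seed=6)
        frames["noise"] = np.random.default_rng(0).standard_normal(len(frames))
        plans = [make_split(frames, "a", 4, s, iteration=s) for s in range(3)]
        # patch a tiny signal set for the toy features
        SIGNAL_SETS["toy"] = ("f1", "f2", "noise")
        try:
            res = evaluate_cell(frames, plans, "toy", "rf", seed=0,
                                rf_trees=40, n_inner=4)
        finally:
            del SIGNAL_SETS["toy"]
        agg = res.aggregate()
        assert agg["min"] <= agg["mean"] <= agg["max"]
        assert 0.0 <= agg["mean"] <= 1.0
        for it in res.iterations:
            assert set(it.selected_features) <= {"f1", "f2", "noise"}
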