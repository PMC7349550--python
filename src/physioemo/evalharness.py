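"""Classifier training and evaluation under three split conditions.

Split conditions (12 of 55 subjects in the test set at full study
scale, configurable for desk-scale cohorts):

(a) subject-independent — no frame of a test subject appears in training;
(b) one randomly chosen emotion per test subject is moved wholesale to
    training, the remaining two stay in test;
(c) 30% (rounded down) of each test subject's frames, per emotion, are
    moved to training — a subject-dependent analysis.

Class counts in train and test are balanced by seeded down-sampling to
the minimum class count.  Ten outer iterations redraw the test subjects;
within each training partition a 10-fold shuffle split holds out 20% for
validation, the classifier fitted on the best fold (by validation
macro-F1) predicts the test set, and per-class F1 / sensitivity /
specificity are aggregated over iterations as mean (sd) [max min].

Classifiers: random forests with 8000 trees for single-signal and
two-EMG inputs and 10000 trees for the all-signal input (a config
override scales trees down for desk runs), and MLPs with fixed
per-input-set hidden-layer widths, ReLU activation, softmax output and
early stopping.  Feature standardization and the feature-selection
cascade are computed from the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, multilabel_confusion_matrix
from sklearn.model_selection import ShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .featsel import run_selection_cascade
from .featx import FEATURE_COLUMNS

__all__ = [
    "SIGNAL_SETS",
    "NN_HIDDEN_LAYERS",
    "SplitPlan",
    "IterationResult",
    "EvalResult",
    "make_split",
    "inner_validation",
    "make_classifier",
    "binary_metrics",
    "per_class_metrics",
    "train_and_score",
    "evaluate_cell",
    "run_matrix",
]

#: Feature columns per evaluated signal combination.
SIGNAL_SETS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_COLUMNS,
    "ecg": tuple(c for c in FEATURE_COLUMNS if c.startswith("ecg_")),
    "eda": tuple(c for c in FEATURE_COLUMNS if c.startswith("eda_")),
    "emgz": tuple(c for c in FEATURE_COLUMNS if c.startswith("emg_z_")),
    "emgmf": tuple(c for c in FEATURE_COLUMNS if c.startswith("emg_mf_")),
    "emg": tuple(c for c in FEATURE_COLUMNS if c.startswith("emg_")),
}

#: Hidden-layer widths per input set (output layer: 3 classes).
NN_HIDDEN_LAYERS: dict[str, tuple[int, ...]] = {
    "all": (28,),
    "ecg": (12, 9, 6),
    "emgz": (12, 9, 6),
    "eda": (12, 9, 6),
    "emgmf": (8, 9),
    "emg": (10, 24),
}

RF_TREES_ALL = 10_000
RF_TREES_SINGLE = 8_000
TRANSFER_FRACTION = 0.30
VALIDATION_FRACTION = 0.20
N_INNER_FOLDS = 10
N_OUTER_ITERATIONS = 10


@dataclass
class SplitPlan:
    """Train/test membership (row positions into the feature table)."""

    condition: str
    iteration: int
    seed: int
    test_subjects: list[str]
    train_idx: np.ndarray
    test_idx: np.ndarray
    transfers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test overlap")


def _balance_classes(idx: np.ndarray, frames: pd.DataFrame, rng) -> np.ndarray:
    """Down-sample every class to the minimum class count (seeded).

    Removal is stratified by subject — frames are dropped round-robin
    from the subjects holding the most frames of the over-represented
    class — so balancing never empties a subject's emotion cell.
    """
    if idx.size == 0:
        return idx
    lab = frames["condition"].to_numpy()[idx]
    subj = frames["subject_id"].to_numpy()[idx]
    counts = pd.Series(lab).value_counts()
    m = int(counts.min())
    kept = []
    for cls in sorted(counts.index):
        mask = lab == cls
        members = idx[mask]
        excess = members.size - m
        if excess > 0:
            groups: dict[str, list[int]] = {}
            for frame_pos, s in zip(members, subj[mask]):
                groups.setdefault(str(s), []).append(int(frame_pos))
            for g in groups.values():
                rng.shuffle(g)
            order = sorted(groups)
            for _ in range(excess):
                largest = max(order, key=lambda s: len(groups[s]))
                groups[largest].pop()
            members = np.concatenate([np.asarray(groups[s], dtype=int)
                                      for s in order])
        kept.append(np.sort(members))
    return np.sort(np.concatenate(kept))


def make_split(frames: pd.DataFrame, condition: str, n_test_subjects: int,
               seed: int, iteration: int = 0) -> SplitPlan:
    """Build one train/test plan for split condition 'a', 'b' or 'c'."""
    if condition not in ("a", "b", "c"):
        raise ValueError("condition must be 'a', 'b' or 'c'")
    rng = default_rng(seed)
    subjects = sorted(frames["subject_id"].unique())
    if len(subjects) < n_test_subjects + 1:
        raise ValueError("not enough subjects for the requested test size")
    for s in subjects:
        if frames.loc[frames["subject_id"] == s, "condition"].nunique() < 3:
            raise ValueError(f"subject {s} lacks one of the 3 conditions")
    test_subjects = sorted(rng.choice(subjects, size=n_test_subjects,
                                      replace=False).tolist())
    pos = np.arange(len(frames))
    is_test_subj = frames["subject_id"].isin(test_subjects).to_numpy()
    train = [pos[~is_test_subj]]
    test = []
    transfers: dict = {}
    if condition == "a":
        test.append(pos[is_test_subj])
    else:
        for s in test_subjects:
            s_mask = (frames["subject_id"] == s).to_numpy()
            emotions = sorted(frames.loc[s_mask, "condition"].unique())
            if condition == "b":
                chosen = str(rng.choice(emotions))
                transfers[s] = chosen
                emo_mask = (frames["condition"] == chosen).to_numpy()
                train.append(pos[s_mask & emo_mask])
                test.append(pos[s_mask & ~emo_mask])
            else:  # condition c
                for emo in emotions:
                    rows = pos[s_mask & (frames["condition"] == emo).to_numpy()]
                    n_move = int(np.floor(TRANSFER_FRACTION * rows.size))
                    moved = np.sort(rng.choice(rows, size=n_move, replace=False))
                    transfers[(s, emo)] = int(n_move)
                    train.append(moved)
                    test.append(np.setdiff1d(rows, moved))
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.sort(np.concatenate(test))
    train_idx = _balance_classes(train_idx, frames, rng)
    test_idx = _balance_classes(test_idx, frames, rng)
    return SplitPlan(condition=condition, iteration=iteration, seed=seed,
                     test_subjects=test_subjects, train_idx=train_idx,
                     test_idx=test_idx, transfers=transfers)


def inner_validation(n_train: int, seed: int,
                     n_folds: int = N_INNER_FOLDS):
    """10 random shuffle-splits of the training partition, each holding
    out 20% for validation.  Yields (train, validation) position arrays
    relative to the training partition."""
    if n_train < n_folds:
        raise ValueError("too few training frames for inner validation")
    ss = ShuffleSplit(n_splits=n_folds, test_size=VALIDATION_FRACTION,
                      random_state=seed)
    return list(ss.split(np.arange(n_train)))


def make_classifier(kind: str, signal_set: str, seed: int,
                    rf_trees: int | None = None):
    """Instantiate the configured classifier for one signal combination."""
    if kind == "rf":
        n = rf_trees if rf_trees is not None else (
            RF_TREES_ALL if signal_set == "all" else RF_TREES_SINGLE)
        return RandomForestClassifier(n_estimators=n, max_features="sqrt",
                                      random_state=seed, n_jobs=1)
    if kind == "nn":
        return MLPClassifier(hidden_layer_sizes=NN_HIDDEN_LAYERS[signal_set],
                             activation="relu", solver="adam", max_iter=500,
                             early_stopping=True, n_iter_no_change=20,
                             random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Sensitivity, specificity and F1 from one class's confusion counts."""
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


def per_class_metrics(y_true, y_pred, classes) -> pd.DataFrame:
    """Per-class confusion-derived metrics; classes absent from the test
    labels are flagged."""
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=list(classes))
    rows = []
    for cls, cm in zip(classes, mcm):
        (tn, fp), (fn, tp) = cm
        m = binary_metrics(int(tp), int(fn), int(fp), int(tn))
        m["class"] = cls
        m["absent_from_test"] = bool(tp + fn == 0)
        rows.append(m)
    return pd.DataFrame(rows).set_index("class")


@dataclass
class IterationResult:
    plan: SplitPlan
    per_class: pd.DataFrame
    macro_f1: float
    validation_f1: float
    selected_features: list[str]


@dataclass
class EvalResult:
    """Aggregate over the outer iterations of one table cell."""

    iterations: list[IterationResult]

    @property
    def macro_f1s(self) -> np.ndarray:
        return np.asarray([it.macro_f1 for it in self.iterations])

    def aggregate(self) -> dict[str, float]:
        f = self.macro_f1s
        return {"mean": float(f.mean()), "sd": float(f.std(ddof=1)) if f.size > 1
                else 0.0, "max": float(f.max()), "min": float(f.min()),
                "best_iteration": int(np.argmax(f))}

    def formatted(self) -> str:
        a = self.aggregate()
        return (f"{100 * a['mean']:.2f} ({100 * a['sd']:.2f}) "
                f"[Max: {100 * a['max']:.2f}%, Min: {100 * a['min']:.2f}%]")


def _assert_no_leakage(plan: SplitPlan) -> None:
    if np.intersect1d(plan.train_idx, plan.test_idx).size:
        raise AssertionError("test frames entered a fitting path")


def train_and_score(frames: pd.DataFrame, plan: SplitPlan,
                    feature_cols, classifier_factory, seed: int,
                    n_inner: int = N_INNER_FOLDS) -> IterationResult:
    """Fit on the training partition (best of ``n_inner`` shuffle-split
    folds by validation macro-F1), predict the test partition and compute
    per-class metrics.  Standardization statistics come from the training
    partition only."""
    _assert_no_leakage(plan)
    cols = list(feature_cols)
    Xtr = frames.iloc[plan.train_idx][cols].to_numpy(dtype=float)
    ytr = frames.iloc[plan.train_idx]["condition"].to_numpy()
    Xte = frames.iloc[plan.test_idx][cols].to_numpy(dtype=float)
    yte = frames.iloc[plan.test_idx]["condition"].to_numpy()
    scaler = StandardScaler().fit(Xtr)
    Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)

    best = None
    for fold_i, (tr, val) in enumerate(inner_validation(len(Xtr), seed,
                                                        n_inner)):
        clf = classifier_factory(seed + fold_i + 1)
        clf.fit(Xtr[tr], ytr[tr])
        vf1 = f1_score(ytr[val], clf.predict(Xtr[val]), average="macro")
        if best is None or vf1 > best[0]:
            best = (vf1, clf)
    val_f1, clf = best
    ypred = clf.predict(Xte)
    classes = sorted(np.unique(np.concatenate([ytr, yte])))
    pc = per_class_metrics(yte, ypred, classes)
    return IterationResult(
        plan=plan,
        per_class=pc,
        macro_f1=float(f1_score(yte, ypred, average="macro")),
        validation_f1=float(val_f1),
        selected_features=cols,
    )


def evaluate_cell(frames: pd.DataFrame, plans: list[SplitPlan],
                  signal_set: str, classifier_kind: str, seed: int,
                  rf_trees: int | None = None,
                  do_selection: bool = True,
                  selection_estimator=None,
                  n_inner: int = N_INNER_FOLDS,
                  selected_by_plan: dict[int, list[str]] | None = None
                  ) -> EvalResult:
    """Evaluate one (signal set, classifier) cell over the given plans.

    Feature selection, when enabled, is recomputed per iteration on the
    training partition only; ``selected_by_plan`` can supply previously
    selected columns (shared between the two classifiers of a cell pair
    so both methods are compared on identical data)."""
    cols_all = list(SIGNAL_SETS[signal_set])
    if do_selection and selection_estimator is None:
        # small seeded forest: the elimination wrapper refits it O(p^2)
        # times per iteration, so it must stay cheap
        selection_estimator = RandomForestClassifier(
            n_estimators=50, random_state=0, n_jobs=1)
    results = []
    for plan in plans:
        if selected_by_plan is not None and plan.iteration in selected_by_plan:
            cols = selected_by_plan[plan.iteration]
        elif do_selection and len(cols_all) >= 2:
            train = frames.iloc[plan.train_idx]
            reduced, _ = run_selection_cascade(
                train[cols_all], train["condition"].to_numpy(),
                estimator=selection_estimator, seed=plan.seed)
            cols = list(reduced.columns)
        else:
            cols = cols_all
        if selected_by_plan is not None:
            selected_by_plan[plan.iteration] = cols
        factory = lambda s: make_classifier(classifier_kind, signal_set, s,
                                            rf_trees=rf_trees)
        results.append(train_and_score(frames, plan, cols, factory,
                                       seed=plan.seed, n_inner=n_inner))
    return EvalResult(results)


def run_matrix(frames_by_len: dict[int, pd.DataFrame],
               signal_sets=("all", "ecg", "emgz", "emgmf", "emg", "eda"),
               conditions=("a", "b", "c"),
               classifiers=("rf", "nn"),
               master_seed: int = 0,
               n_test_subjects: int = 12,
               n_iterations: int = N_OUTER_ITERATIONS,
               rf_trees: int | None = None,
               do_selection: bool = True,
               selection_estimator=None,
               n_inner: int = N_INNER_FOLDS) -> pd.DataFrame:
    """Full factorial evaluation: signal sets x conditions x frame
    lengths x classifiers, 10 outer iterations each.

    The same split plans are shared by every signal set and classifier of
    a (frame, condition) pair so methods are compared on identical data.
    Returns one row per cell with mean/sd/max/min macro-F1, the
    best-iteration macro-F1 and a formatted mean (sd) [max min] string.
    """
    seed_rng = default_rng(master_seed)
    rows = []
    for frame_s, frames in sorted(frames_by_len.items()):
        for cond in conditions:
            plan_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=n_iterations)
            plans = [make_split(frames, cond, n_test_subjects, int(s), it)
                     for it, s in enumerate(plan_seeds)]
            for sset in signal_sets:
                shared: dict[int, list[str]] = {}
                for kind in classifiers:
                    res = evaluate_cell(
                        frames, plans, sset, kind,
                        seed=int(plan_seeds[0]), rf_trees=rf_trees,
                        do_selection=do_selection,
                        selection_estimator=selection_estimator,
                        n_inner=n_inner, selected_by_plan=shared)
                    agg = res.aggregate()
                    rows.append({
                        "signal_set": sset, "condition": cond,
                        "frame_s": frame_s, "classifier": kind,
                        "macro_f1_mean": agg["mean"],
                        "macro_f1_sd": agg["sd"],
                        "macro_f1_max": agg["max"],
                        "macro_f1_min": agg["min"],
                        "macro_f1_best_iteration": float(res.macro_f1s.max()),
                        "formatted": res.formatted(),
                    })
    return pd.DataFrame(rows)
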