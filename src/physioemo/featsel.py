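"""Feature-selection cascade: correlation filter -> variance filter ->
backward elimination.

The three stages are exposed as sklearn-compatible transformers
(``fit`` / ``transform`` / ``get_support``) so they compose with
pipelines, plus a :func:`run_selection_cascade` convenience that chains
them on a labelled feature table and returns a full
:class:`SelectionReport` reconstructing every drop decision.

Correlation filter: for each pair with ``|Pearson r|`` above the
threshold, the member with the larger mean absolute correlation to all
other remaining features is dropped (deterministic order: strongest pair
first, names break ties).  Variance filter: features are min-max scaled
to [0, 1] and those with scaled variance below a threshold — by default
the 25th percentile of the scaled variances, i.e. adapted to the feature
space — are dropped (exactly-constant features always are).  Backward
elimination: starting from all features, repeatedly remove the feature
whose removal minimizes the validation error (1 - macro-F1 on a fixed
seeded held-out split); removal continues while the best candidate does
not increase the error and stops when every removal strictly hurts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

__all__ = [
    "SelectionReport",
    "CorrelationFilter",
    "ScaledVarianceFilter",
    "BackwardElimination",
    "run_selection_cascade",
    "default_elimination_estimator",
]


@dataclass
class SelectionReport:
    """Audit trail of one cascade run."""

    corr_dropped: list[tuple[str, str, str]] = field(default_factory=list)
    #: (kept, dropped, note) triples; note records the deciding |r|
    var_dropped: list[str] = field(default_factory=list)
    var_threshold: float = float("nan")
    elimination_order: list[str] = field(default_factory=list)
    elimination_errors: list[float] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.final_features:
            raise ValueError("selection produced an empty feature set")
        dropped = {d for _, d, _ in self.corr_dropped} | set(self.var_dropped) \
            | set(self.elimination_order)
        if dropped & set(self.final_features):
            raise ValueError("dropped and final feature sets overlap")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Drop one member of every feature pair with ``|r| > threshold``."""

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X, y=None):
        df = _as_frame(X)
        if df.shape[1] < 2:
            raise ValueError("need at least 2 features")
        corr = df.corr().abs()
        corr = corr.fillna(0.0)  # constant features deferred to variance filter
        np.fill_diagonal(corr.values, 0.0)
        kept = list(df.columns)
        dropped: list[tuple[str, str, str]] = []
        while True:
            sub = corr.loc[kept, kept]
            peak = sub.values.max() if len(kept) > 1 else 0.0
            if peak <= self.threshold:
                break
            i, j = np.unravel_index(int(np.argmax(sub.values)), sub.shape)
            a, b = sorted((kept[i], kept[j]))
            mean_a = sub.loc[a].mean()
            mean_b = sub.loc[b].mean()
            loser = b if mean_b >= mean_a else a
            winner = a if loser == b else b
            dropped.append((winner, loser, f"|r|={peak:.3f}"))
            kept.remove(loser)
        self.feature_names_in_ = np.asarray(df.columns)
        self.selected_features_ = list(kept)
        self.dropped_pairs_ = dropped
        self.support_ = np.asarray([c in kept for c in df.columns])
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        df = _as_frame(X)
        return df[self.selected_features_]


class ScaledVarianceFilter(TransformerMixin, BaseEstimator):
    """Drop features with low min-max-scaled variance.

    ``threshold=None`` adapts to the feature space: the 25th percentile
    of the scaled variances.  Exactly-constant features are always
    dropped; if every feature falls below the threshold the single
    highest-variance one is retained with a warning.
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X, y=None):
        df = _as_frame(X)
        rng_ = df.max() - df.min()
        scaled = (df - df.min()) / rng_.replace(0.0, 1.0)
        var = scaled.var(ddof=0)
        thr = (float(np.percentile(var, 25.0)) if self.threshold is None
               else self.threshold)
        keep = (var >= thr) & (var > 0.0)
        if not keep.any():
            warnings.warn("all features below variance threshold; "
                          "keeping the single highest-variance feature")
            keep[var.idxmax()] = True
        self.feature_names_in_ = np.asarray(df.columns)
        self.variances_ = var
        self.threshold_ = thr
        self.selected_features_ = list(df.columns[keep.values])
        self.dropped_ = list(df.columns[~keep.values])
        self.support_ = keep.values.copy()
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        return _as_frame(X)[self.selected_features_]


def default_elimination_estimator(seed: int = 0):
    """Small seeded random forest used to score candidate feature sets."""
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


class BackwardElimination(TransformerMixin, BaseEstimator):
    """Wrapper selection minimizing 1 - macro-F1 on a fixed held-out split.

    ``estimator`` is cloned and refitted for every candidate set; the
    validation split is stratified and controlled by ``random_state`` so
    the whole elimination is deterministic.
    """

    def __init__(self, estimator=None, val_fraction: float = 0.2,
                 random_state: int = 0):
        self.estimator = estimator
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _error(self, Xtr, Xval, ytr, yval, cols) -> float:
        est = clone(self._est)
        est.fit(Xtr[cols], ytr)
        return 1.0 - f1_score(yval, est.predict(Xval[cols]), average="macro")

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y)
        if df.shape[1] < 2:
            raise ValueError("need at least 2 features")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        self._est = (self.estimator if self.estimator is not None
                     else default_elimination_estimator(self.random_state))
        Xtr, Xval, ytr, yval = train_test_split(
            df, y, test_size=self.val_fraction, stratify=y,
            random_state=self.random_state)
        cols = list(df.columns)
        current = self._error(Xtr, Xval, ytr, yval, cols)
        order: list[str] = []
        errors: list[float] = [current]
        while len(cols) > 1:
            candidates = [(self._error(Xtr, Xval, ytr, yval,
                                       [c for c in cols if c != drop]), drop)
                          for drop in cols]
            best_err, best_drop = min(candidates, key=lambda t: (t[0], t[1]))
            if best_err > current:
                break
            cols.remove(best_drop)
            order.append(best_drop)
            errors.append(best_err)
            current = best_err
        self.feature_names_in_ = np.asarray(df.columns)
        self.selected_features_ = cols
        self.elimination_order_ = order
        self.validation_errors_ = errors
        self.support_ = np.asarray([c in cols for c in df.columns])
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        return _as_frame(X)[self.selected_features_]


def run_selection_cascade(
    table: pd.DataFrame,
    labels,
    corr_threshold: float = 0.9,
    var_threshold: float | None = None,
    estimator=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Run the full cascade on a feature table; returns the reduced table
    and a :class:`SelectionReport`."""
    report = SelectionReport()
    cf = CorrelationFilter(corr_threshold).fit(table)
    report.corr_dropped = cf.dropped_pairs_
    reduced = cf.transform(table)

    vf = ScaledVarianceFilter(var_threshold).fit(reduced)
    report.var_dropped = vf.dropped_
    report.var_threshold = vf.threshold_
    reduced = vf.transform(reduced)

    if reduced.shape[1] >= 2:
        be = BackwardElimination(estimator=estimator, random_state=seed)
        be.fit(reduced, labels)
        report.elimination_order = be.elimination_order_
        report.elimination_errors = be.validation_errors_
        reduced = be.transform(reduced)
    report.final_features = list(reduced.columns)
    report.validate()
    return reduced, report
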