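"""Supervised approved-vs-discontinued stage.

Univariate F ranking of features against the binary label, top-k selection,
linear classifiers (linear-margin SVC default; ridge and logistic also
wired) with Platt-style probability calibration and a tunable decision
threshold, stratified 10-fold cross-validation scored by MCC/sensitivity/
specificity, and mapping of selected feature indices back to grid positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .errors import (
    DimensionMismatch,
    SingleClassLabels,
    TooFewSamples,
    UnknownIndex,
)

CLASSIFIER_KINDS = ("linear_svc", "ridge", "logistic")

# Registry hooks for the remaining published classifier sweep; deliberately
# unimplemented here.
CLASSIFIER_STUBS = (
    "decision_tree", "sgd", "ridge_cv", "adaboost", "gradient_boost",
    "bagging", "random_forest", "calibrated", "gaussian_nb", "svc",
    "logistic_cv", "qda",
)


# ---------------------------------------------------------------------------
# feature ranking / selection


def f_regression_rank(X: np.ndarray, y: np.ndarray):
    """Per-feature univariate F statistic and p-value against the labels.

    F = r^2 (n-2) / (1 - r^2) from the feature-label Pearson correlation;
    p from F(1, n-2).  Constant features score F = 0; a perfectly
    correlated feature scores F = inf and ranks above everything finite.
    Returns (order, F, p) with order sorted by descending F, ties by
    ascending index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(y)) < 2:
        raise SingleClassLabels("labels contain a single class")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.nan_to_num(r, nan=0.0)  # constant features
    r = np.clip(r, -1.0, 1.0)
    r2 = r ** 2
    with np.errstate(divide="ignore"):
        F = np.where(r2 >= 1.0 - 1e-12, np.inf, r2 * (n - 2) / (1.0 - r2))
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isinf(F), 0.0, F), 1, n - 2))
    order = np.lexsort((np.arange(X.shape[1]), -F))
    return order, F, p


@dataclass(frozen=True)
class FeatureSelection:
    """Top-k feature indices with their F scores and p-values."""

    k: int
    indices: tuple[int, ...]
    f_scores: tuple[float, ...]
    p_values: tuple[float, ...]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def select_k(X: np.ndarray, y: np.ndarray, k: int) -> FeatureSelection:
    """Top-k features by F score (ties broken by ascending index)."""
    order, F, p = f_regression_rank(X, y)
    kept = order[: min(k, len(order))]
    return FeatureSelection(
        k=k,
        indices=tuple(int(i) for i in kept),
        f_scores=tuple(float(F[i]) for i in kept),
        p_values=tuple(float(p[i]) for i in kept),
    )


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class Layer2Model:
    """Linear decision rule on selected features with calibrated probability."""

    kind: str
    selection: FeatureSelection
    weights: np.ndarray
    intercept: float
    calibration: tuple[float, float]  # (slope, intercept) of Platt logistic
    threshold: float = 0.5
    encoder_name: str = ""

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def decision_scores(self, X_selected: np.ndarray) -> np.ndarray:
        X_selected = np.asarray(X_selected, dtype=float)
        if X_selected.size == 0:
            return np.empty(0)
        if X_selected.shape[1] != len(self.weights):
            raise DimensionMismatch(
                f"expected {len(self.weights)} features, got {X_selected.shape[1]}"
            )
        return X_selected @ self.weights + self.intercept

    def probabilities(self, X_selected: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X_selected)
        a, c = self.calibration
        return 1.0 / (1.0 + np.exp(-(a * s + c)))

    def to_json(self) -> str:
        return json.dumps({
            "format": "abtriage-layer2-v1",
            "kind": self.kind,
            "threshold": self.threshold,
            "encoder": self.encoder_name,
            "selection": {"k": self.selection.k,
                          "indices": list(self.selection.indices),
                          "f_scores": list(self.selection.f_scores),
                          "p_values": list(self.selection.p_values)},
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "calibration": list(self.calibration),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Layer2Model":
        d = json.loads(text)
        if d.get("format") != "abtriage-layer2-v1":
            raise ValueError("unrecognised model serialisation format")
        sel = FeatureSelection(k=d["selection"]["k"],
                               indices=tuple(d["selection"]["indices"]),
                               f_scores=tuple(d["selection"]["f_scores"]),
                               p_values=tuple(d["selection"]["p_values"]))
        return cls(kind=d["kind"], selection=sel,
                   weights=np.asarray(d["weights"], dtype=float),
                   intercept=float(d["intercept"]),
                   calibration=(d["calibration"][0], d["calibration"][1]),
                   threshold=float(d["threshold"]), encoder_name=d.get("encoder", ""))


def _fit_linear(X: np.ndarray, y: np.ndarray, kind: str, seed: int):
    if kind == "linear_svc":
        clf = LinearSVC(random_state=seed, max_iter=20000)
    elif kind == "ridge":
        clf = RidgeClassifier(random_state=seed)
    elif kind == "logistic":
        clf = LogisticRegression(random_state=seed, max_iter=5000)
    elif kind in CLASSIFIER_STUBS:
        raise NotImplementedError(f"classifier {kind!r} is a registry stub")
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y)
    return clf


def train_classifier(X_selected: np.ndarray, y: np.ndarray,
                     kind: str = "linear_svc", seed: int = 0,
                     threshold: float = 0.5,
                     selection: FeatureSelection | None = None,
                     encoder_name: str = "") -> Layer2Model:
    """Fit a linear decision rule and Platt-calibrate its scores on the
    training split so probability thresholds (0.5 / 0.8) are meaningful."""
    X_selected = np.asarray(X_selected, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassLabels("training labels contain a single class")
    clf = _fit_linear(X_selected, y, kind, seed)
    w = np.ravel(clf.coef_)
    b = float(np.ravel(clf.intercept_)[0])
    scores = X_selected @ w + b
    # Platt scaling: logistic regression of the label on the decision score.
    platt = LogisticRegression(max_iter=5000)
    platt.fit(scores.reshape(-1, 1), y)
    a = float(platt.coef_[0, 0])
    c = float(platt.intercept_[0])
    if selection is None:
        selection = FeatureSelection(
            k=X_selected.shape[1],
            indices=tuple(range(X_selected.shape[1])),
            f_scores=(float("nan"),) * X_selected.shape[1],
            p_values=(float("nan"),) * X_selected.shape[1],
        )
    return Layer2Model(kind=kind, selection=selection, weights=w, intercept=b,
                       calibration=(a, c), threshold=threshold,
                       encoder_name=encoder_name)


def predict(model: Layer2Model, X_selected: np.ndarray,
            threshold: float | None = None):
    """(labels, probabilities); positive ("approved-like") iff p >= threshold."""
    t = model.threshold if threshold is None else threshold
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    probs = model.probabilities(X_selected)
    return (probs >= t).astype(int), probs


# ---------------------------------------------------------------------------
# metrics


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


@dataclass(frozen=True)
class EvalMetrics:
    """Per-fold and aggregate MCC / sensitivity / specificity."""

    per_fold: tuple[dict, ...]
    mean_mcc: float
    sd_mcc: float
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float


def _fold_metrics(y_true, y_pred) -> dict:
    tp, fp, tn, fn = confusion(y_true, y_pred)
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "mcc": mcc(tp, fp, tn, fn), "sensitivity": sn, "specificity": sp}


def cross_validate(X: np.ndarray, y: np.ndarray, k: int,
                   kind: str = "linear_svc", folds: int = 10, seed: int = 0,
                   threshold: float = 0.5,
                   select_outside_folds: bool = False) -> EvalMetrics:
    """Stratified k-fold CV with feature selection refit inside each training
    fold.  ``select_outside_folds`` reproduces the leakage-prone variant
    (selection on the full matrix before splitting) for comparison only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < folds:
        raise TooFewSamples(f"{len(y)} samples < {folds} folds")
    if len(np.unique(y)) < 2:
        raise SingleClassLabels("labels contain a single class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    global_sel = select_k(X, y, k) if select_outside_folds else None
    rows = []
    for train_idx, test_idx in skf.split(X, y):
        sel = global_sel or select_k(X[train_idx], y[train_idx], k)
        cols = list(sel.indices)
        model = train_classifier(X[train_idx][:, cols], y[train_idx], kind=kind,
                                 seed=seed, threshold=threshold, selection=sel)
        y_pred, _ = predict(model, X[test_idx][:, cols])
        rows.append(_fold_metrics(y[test_idx], y_pred))
    def agg(key):
        vals = np.array([r[key] for r in rows])
        return float(vals.mean()), float(vals.std(ddof=1))
    m, ms = agg("mcc")
    sn, sns = agg("sensitivity")
    sp, sps_ = agg("specificity")
    return EvalMetrics(per_fold=tuple(rows), mean_mcc=m, sd_mcc=ms,
                       mean_sensitivity=sn, sd_sensitivity=sns,
                       mean_specificity=sp, sd_specificity=sps_)


# ---------------------------------------------------------------------------
# feature -> position attribution


@dataclass(frozen=True)
class PositionAttribution:
    """Count of selected features per (chain, grid slot)."""

    counts: dict

    def total(self) -> int:
        return sum(self.counts.values())


def feature_positions(selection: FeatureSelection, layout) -> PositionAttribution:
    """Histogram of selected feature indices over (chain, grid slot)."""
    counts: dict = {}
    for idx in selection.indices:
        if idx < 0 or idx >= len(layout):
            raise UnknownIndex(f"feature index {idx} outside layout of {len(layout)}")
        chain, slot, _ = layout.entry(idx)
        counts[(chain, slot)] = counts.get((chain, slot), 0) + 1
    return PositionAttribution(counts=counts)
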