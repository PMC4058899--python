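"""SVM-AdaBoost classification with recursive feature elimination under LOOCV.

Per leave-one-out fold: standardize features on the training subjects only,
apply the same transform to the held-out subject, run recursive feature
elimination (RFE) on the training fold, train an AdaBoost ensemble of linear
soft-margin SVMs (C = 1) on the retained features, and predict the held-out
subject.  Accuracy and precision are pooled over all folds.

The two core estimators are sklearn-compatible:

* :class:`SVMRFE` — a feature selector that iteratively refits a linear SVM
  and drops 10% of the *surviving* features with the smallest absolute
  weights (ties broken by dropping the lower canonical index first) until
  ``ceil(n_features * (1 - elim_frac))`` remain.
* :class:`SVMAdaBoost` — discrete AdaBoost over weighted linear SVMs: vote
  weight alpha = 0.5 * ln((1 - eps) / eps) per round, multiplicative sample
  re-weighting, early stop on eps = 0 (member kept with capped alpha) or
  eps >= 0.5 (member discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "ScalingParams",
    "LinearModel",
    "BoostedEnsemble",
    "FoldResult",
    "CVReport",
    "SVMRFE",
    "SVMAdaBoost",
    "fit_scaler",
    "apply_scaler",
    "train_linear_svm",
    "rfe",
    "vote_weight",
    "adaboost_train",
    "loocv_pipeline",
    "performance",
]

_EPS_FLOOR = 1e-10


def vote_weight(eps: float) -> float:
    """AdaBoost vote weight alpha = 0.5 ln((1 - eps) / eps), with eps floored
    at 1e-10 so separable rounds (eps = 0) get a large finite vote."""
    eps = min(max(eps, _EPS_FLOOR), 1.0 - _EPS_FLOOR)
    return 0.5 * math.log((1.0 - eps) / eps)


# -- scaling ----------------------------------------------------------------

@dataclass
class ScalingParams:
    """Per-feature location/dispersion fitted on the training fold only."""

    center: np.ndarray
    scale: np.ndarray
    method: str = "standard"


def fit_scaler(X_train: np.ndarray, method: str = "standard",
               feature_names: list[str] | None = None) -> ScalingParams:
    """Fit a per-feature scaling on training rows.

    ``method="standard"``: subtract mean, divide by population SD.
    ``method="minmax"``: map the training range to [0, 1].
    A zero-dispersion feature raises, naming the offending column.
    """
    X = np.asarray(X_train, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples to fit a scaler")
    if method == "standard":
        center = X.mean(axis=0)
        scale = X.std(axis=0)
    elif method == "minmax":
        center = X.min(axis=0)
        scale = X.max(axis=0) - center
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        label = feature_names[bad[0]] if feature_names else f"column {bad[0]}"
        raise ValueError(f"zero-variance training feature: {label}")
    return ScalingParams(center=center, scale=scale, method=method)


def apply_scaler(params: ScalingParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.center) / params.scale


# -- linear SVM -------------------------------------------------------------

@dataclass
class LinearModel:
    """Linear soft-margin classifier: decision value = weights . x + bias."""

    weights: np.ndarray
    bias: float
    C: float
    classes: np.ndarray  # classes[1] is the positive (decision > 0) class

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        # boundary (decision exactly 0) resolves to the positive class, the
        # same convention the boosted vote uses
        return np.where(self.decision(X) >= 0, self.classes[1], self.classes[0])


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0,
    sample_weight: np.ndarray | None = None,
) -> LinearModel:
    """Fit a weighted linear soft-margin SVM (libsvm via scikit-learn)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y, sample_weight=sample_weight)
    return LinearModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        classes=svc.classes_,
    )


# -- recursive feature elimination ------------------------------------------

class SVMRFE(SelectorMixin, BaseEstimator):
    """Recursive feature elimination driven by linear-SVM weight magnitudes.

    Parameters
    ----------
    elim_frac : fraction of features to eliminate (0, 0.5 or 0.9 in the
        standard protocol; any value in [0, 1) is accepted).  The retained
        count is ``ceil(n_features * (1 - elim_frac))``.
    step : fraction of *surviving* features dropped per iteration (>= 1
        feature per iteration; never overshoots the target).
    """

    def __init__(self, elim_frac: float = 0.0, C: float = 1.0, step: float = 0.1):
        self.elim_frac = elim_frac
        self.C = C
        self.step = step

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n_features = X.shape[1]
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[rfe(X, y, self.elim_frac, C=self.C, step=self.step)] = True
        self.n_features_in_ = n_features
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def rfe(
    X: np.ndarray, y: np.ndarray, elim_frac: float,
    C: float = 1.0, step: float = 0.1,
) -> np.ndarray:
    """Indices (ascending canonical order) of the retained features.

    ``elim_frac = 0`` returns all features without fitting anything.
    Ties in |weight| are broken by dropping the lower canonical index first.
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    if n_features < 1:
        raise ValueError("need at least one feature")
    if not 0.0 <= elim_frac < 1.0:
        raise ValueError("elim_frac must be in [0, 1)")
    target = math.ceil(n_features * (1.0 - elim_frac))
    if target < 1:
        raise ValueError("target retained count < 1")
    surviving = np.arange(n_features)
    while surviving.size > target:
        model = train_linear_svm(X[:, surviving], y, C=C)
        w = np.abs(model.weights)
        n_drop = min(max(1, int(step * surviving.size)), surviving.size - target)
        # stable sort on (|w|, canonical index): lowest weight first, lower
        # canonical index first among ties
        order = np.lexsort((surviving, w))
        drop = np.zeros(surviving.size, dtype=bool)
        drop[order[:n_drop]] = True
        surviving = surviving[~drop]
    return surviving


# -- AdaBoost ---------------------------------------------------------------

@dataclass
class BoostedEnsemble:
    """Weighted vote over linear members: sign(sum alpha * sign(decision))."""

    members: list[LinearModel]
    alphas: list[float]
    history: list[float]  # weighted training error per round
    classes: np.ndarray

    def votes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        total = np.zeros(X.shape[0])
        for model, alpha in zip(self.members, self.alphas):
            s = np.sign(model.decision(X))
            s[s == 0] = 1.0
            total += alpha * s
        return total

    def predict(self, X: np.ndarray) -> np.ndarray:
        # tie (vote sum exactly 0) resolves to the positive class
        return np.where(self.votes(X) >= 0, self.classes[1], self.classes[0])


def adaboost_train(
    X: np.ndarray, y: np.ndarray, n_rounds: int = 10, C: float = 1.0
) -> BoostedEnsemble:
    """Discrete AdaBoost over weighted linear SVMs.

    Per round: fit on current sample weights, compute weighted error eps,
    vote weight alpha = 0.5 ln((1 - eps)/eps), multiplicative re-weighting.
    eps = 0 stops early with the member kept at a capped alpha (eps floored
    at 1e-10); eps >= 0.5 discards the member and stops.  If the very first
    round is discarded, that one member is kept with alpha = 1 so the
    ensemble always predicts (it then equals the plain SVM).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    members: list[LinearModel] = []
    alphas: list[float] = []
    history: list[float] = []
    ysign = np.where(y == classes[1], 1.0, -1.0)
    for _ in range(n_rounds):
        model = train_linear_svm(X, y, C=C, sample_weight=w * n)
        pred_sign = np.sign(model.decision(X))
        pred_sign[pred_sign == 0] = 1.0
        miss = pred_sign != ysign
        eps = float(w[miss].sum())
        history.append(eps)
        if eps >= 0.5:
            if not members:
                members.append(model)
                alphas.append(1.0)
            break
        alpha = vote_weight(eps)
        members.append(model)
        alphas.append(alpha)
        if eps == 0.0:
            break
        w = w * np.exp(-alpha * ysign * pred_sign)
        w /= w.sum()
    return BoostedEnsemble(members=members, alphas=alphas, history=history, classes=classes)


class SVMAdaBoost(ClassifierMixin, BaseEstimator):
    """sklearn-compatible wrapper around :func:`adaboost_train`."""

    def __init__(self, C: float = 1.0, n_rounds: int = 10):
        self.C = C
        self.n_rounds = n_rounds

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.ensemble_ = adaboost_train(X, y, n_rounds=self.n_rounds, C=self.C)
        self.classes_ = self.ensemble_.classes
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.votes(X)

    def predict(self, X):
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.predict(X)


# -- LOOCV pipeline ---------------------------------------------------------

@dataclass
class FoldResult:
    held_out: str
    predicted: int
    truth: int
    selected_features: frozenset[str]


@dataclass
class CVReport:
    folds: list[FoldResult]
    accuracy: float
    precision: float
    elim_frac: float
    kind: str = ""
    n_rounds: int = 10
    n_features: int = 0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "elim_frac": self.elim_frac,
            "n_rounds": self.n_rounds,
            "n_features": self.n_features,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "folds": [
                {
                    "held_out": f.held_out,
                    "predicted": int(f.predicted),
                    "truth": int(f.truth),
                    "selected_features": sorted(f.selected_features),
                }
                for f in self.folds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVReport":
        return cls(
            folds=[
                FoldResult(
                    held_out=f["held_out"],
                    predicted=int(f["predicted"]),
                    truth=int(f["truth"]),
                    selected_features=frozenset(f["selected_features"]),
                )
                for f in d["folds"]
            ],
            accuracy=float(d["accuracy"]),
            precision=float(d["precision"]),
            elim_frac=float(d["elim_frac"]),
            kind=d.get("kind", ""),
            n_rounds=int(d.get("n_rounds", 10)),
            n_features=int(d.get("n_features", 0)),
        )


def performance(
    folds: list[FoldResult],
    precision_mode: str = "standard",
    positive: int = 1,
) -> tuple[float, float]:
    """Pooled accuracy and precision over LOOCV folds.

    Accuracy = (TP + TN) / all.  Precision defaults to TP / (TP + FP);
    ``precision_mode="as-printed"`` uses the TP / (TP + TN) variant instead.
    With no positive predictions the standard precision is reported as 0.
    """
    if not folds:
        raise ValueError("need at least one fold")
    tp = sum(1 for f in folds if f.predicted == positive and f.truth == positive)
    tn = sum(1 for f in folds if f.predicted != positive and f.truth != positive)
    fp = sum(1 for f in folds if f.predicted == positive and f.truth != positive)
    accuracy = (tp + tn) / len(folds)
    if precision_mode == "standard":
        precision = tp / (tp + fp) if (tp + fp) else 0.0
    elif precision_mode == "as-printed":
        precision = tp / (tp + tn) if (tp + tn) else 0.0
    else:
        raise ValueError(f"unknown precision_mode {precision_mode!r}")
    return accuracy, precision


def loocv_pipeline(
    table,
    elim_frac: float = 0.0,
    n_rounds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    scaling: str = "standard",
    precision_mode: str = "standard",
) -> CVReport:
    """Leave-one-out cross-validation of the full per-fold chain.

    For each subject: fit the scaler on the remaining subjects, run RFE on
    the (scaled) training fold, train AdaBoost on the retained features, and
    predict the held-out subject.  The per-fold retained feature names are
    recorded for the recurrence analysis.

    The chain is deterministic; ``seed`` is accepted for interface symmetry
    with stochastic stages and recorded nowhere else.
    """
    X = np.asarray(table.values, dtype=float)
    y = np.asarray(table.labels, dtype=int)
    names = np.asarray(table.names, dtype=object)
    ids = list(table.subject_ids)
    n = X.shape[0]
    for cls_label in np.unique(y):
        if (y == cls_label).sum() < 2:
            raise ValueError("need at least 2 subjects per class")
    folds: list[FoldResult] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        try:
            params = fit_scaler(X[train], method=scaling, feature_names=list(names))
            Xtr = apply_scaler(params, X[train])
            xte = apply_scaler(params, X[i][None, :])
            keep = rfe(Xtr, y[train], elim_frac, C=C)
            ens = adaboost_train(Xtr[:, keep], y[train], n_rounds=n_rounds, C=C)
            pred = int(ens.predict(xte[:, keep])[0])
        except Exception as exc:  # annotate with fold context
            raise RuntimeError(f"fold {i} (held out {ids[i]}): {exc}") from exc
        folds.append(
            FoldResult(
                held_out=ids[i],
                predicted=pred,
                truth=int(y[i]),
                selected_features=frozenset(names[keep]),
            )
        )
    accuracy, precision = performance(folds, precision_mode=precision_mode)
    return CVReport(
        folds=folds,
        accuracy=accuracy,
        precision=precision,
        elim_frac=elim_frac,
        kind=getattr(table, "kind", ""),
        n_rounds=n_rounds,
        n_features=X.shape[1],
    )
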