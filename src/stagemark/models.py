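"""Nested model selection over six classifier families, the evaluation
metric suite, and the agreement/abstain voting ensemble.

Hyperparameters are tuned by stratified k-fold cross-validation on the
training set only (grid search on balanced accuracy); the tuned families
are then compared on the untouched holdout set, so model-class selection
never leaks holdout information into tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (balanced_accuracy_score, confusion_matrix,
                             f1_score, matthews_corrcoef, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

FAMILIES = ("random_forest", "svm", "knn", "nn_1layer", "nn_2layer", "xgboost")


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter grid."""
    family: str
    estimator: BaseEstimator
    grid: dict
    seed: int = 0

    def __post_init__(self):
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def default_model_specs(seed: int = 0, n_features: int | None = None,
                        fast: bool = False) -> list[ModelSpec]:
    """The six default families and grids.

    ``fast=True`` shrinks grids and ensemble sizes for desk-scale runs
    (small synthetic cohorts); the family list is unchanged.
    """
    mtry = ["sqrt"]
    if n_features is not None and not fast:
        mtry = sorted({max(1, int(np.sqrt(n_features))),
                       max(1, n_features // 3)})
    trees = [250] if fast else [250, 500]
    hidden1 = [(16,)] if fast else [(8,), (16,), (32,)]
    hidden2 = [(16, 16)] if fast else [(8, 8), (16, 16), (32, 32)]
    svm_c = [1.0] if fast else [0.1, 1.0, 10.0]
    knn_k = [5] if fast else [3, 5, 7, 11]
    xgb_depth = [4] if fast else [2, 4, 6]
    xgb_eta = [0.3] if fast else [0.05, 0.3]
    xgb_trees = 100 if fast else 200
    specs = [
        ModelSpec("random_forest",
                  RandomForestClassifier(random_state=seed),
                  {"n_estimators": trees,
                   "max_features": mtry if n_features else ["sqrt"]},
                  seed),
        ModelSpec("svm",
                  Pipeline([("scale", StandardScaler()),
                            ("clf", SVC(kernel="rbf", gamma="scale",
                                        probability=True,
                                        random_state=seed))]),
                  {"clf__C": svm_c}, seed),
        ModelSpec("knn",
                  Pipeline([("scale", StandardScaler()),
                            ("clf", KNeighborsClassifier())]),
                  {"clf__n_neighbors": knn_k}, seed),
        ModelSpec("nn_1layer",
                  Pipeline([("scale", StandardScaler()),
                            ("clf", MLPClassifier(max_iter=400,
                                                  random_state=seed))]),
                  {"clf__hidden_layer_sizes": hidden1}, seed),
        ModelSpec("nn_2layer",
                  Pipeline([("scale", StandardScaler()),
                            ("clf", MLPClassifier(max_iter=400,
                                                  random_state=seed))]),
                  {"clf__hidden_layer_sizes": hidden2}, seed),
        ModelSpec("xgboost",
                  XGBClassifier(n_estimators=xgb_trees, random_state=seed,
                                eval_metric="logloss"),
                  {"max_depth": xgb_depth, "learning_rate": xgb_eta}, seed),
    ]
    return specs


class _LabelledClassifier(BaseEstimator, ClassifierMixin):
    """Wraps an estimator so arbitrary (string) labels survive XGBoost's
    integer-class requirement."""

    def __init__(self, base):
        self.base = base

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.model_ = clone(self.base)
        self.model_.fit(X, y_enc)
        return self

    def predict(self, X):
        return self.classes_[self.model_.predict(np.asarray(X))]

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X))


def tune_model(spec: ModelSpec, X_train, y_train, folds: int = 10):
    """Grid-search the spec's hyperparameters by stratified k-fold CV on
    balanced accuracy, then refit on the full training data.

    Returns (fitted_model, cv_balanced_accuracy, best_params). Raises if a
    class has fewer members than the number of folds (stratification error).
    """
    y_train = np.asarray(y_train)
    _, counts = np.unique(y_train, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()}) cannot stratify {folds} folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    est = _LabelledClassifier(clone(spec.estimator))
    search = GridSearchCV(est, {f"base__{k}": v for k, v in spec.grid.items()},
                          cv=cv, scoring="balanced_accuracy", refit=True)
    search.fit(np.asarray(X_train, dtype=float), y_train)
    return search.best_estimator_, search.best_score_, search.best_params_


@dataclass
class EvalReport:
    """Holdout evaluation metrics, each on [0, 1].

    Binary metrics use textbook definitions; multiclass metrics are
    macro-averaged one-vs-rest (sensitivity / specificity / PPV / AUROC),
    with the multiclass MCC being Gorodkin's R_K. AUROC is None when
    y_true has a single class.
    """
    balanced_accuracy: float
    f1: float
    auroc: float | None
    mcc: float
    ppv: float
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame
    probabilities: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("balanced_accuracy", "f1", "auroc", "mcc", "ppv",
                 "sensitivity", "specificity")}


def compute_metrics(y_true, y_pred, probabilities=None,
                    labels=None) -> EvalReport:
    """Evaluation metric suite: balanced accuracy, F1, AUROC, MCC, PPV,
    sensitivity and specificity, plus the confusion matrix."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)
    binary = len(labels) == 2
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    cm_df = pd.DataFrame(cm, index=labels, columns=labels)
    avg = "binary" if binary else "macro"
    pos = labels[-1] if binary else None
    if binary:
        tn, fp, fn, tp = cm.ravel()
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        ppv = tp / (tp + fp) if tp + fp else 0.0
        f1 = f1_score(y_true, y_pred, labels=labels, pos_label=pos,
                      zero_division=0)
    else:
        sens = recall_score(y_true, y_pred, labels=labels, average="macro",
                            zero_division=0)
        specs = []
        for i in range(len(labels)):
            tn = cm.sum() - cm[i, :].sum() - cm[:, i].sum() + cm[i, i]
            fp = cm[:, i].sum() - cm[i, i]
            specs.append(tn / (tn + fp) if tn + fp else 0.0)
        spec = float(np.mean(specs))
        ppv = precision_score(y_true, y_pred, labels=labels, average="macro",
                              zero_division=0)
        f1 = f1_score(y_true, y_pred, labels=labels, average="macro",
                      zero_division=0)
    auroc = None
    if probabilities is not None and len(np.unique(y_true)) > 1:
        probabilities = np.asarray(probabilities, dtype=float)
        if binary:
            p = probabilities if probabilities.ndim == 1 else probabilities[:, -1]
            auroc = roc_auc_score((y_true == pos).astype(int), p)
        else:
            auroc = roc_auc_score(y_true, probabilities, multi_class="ovr",
                                  average="macro", labels=labels)
    return EvalReport(
        balanced_accuracy=balanced_accuracy_score(y_true, y_pred),
        f1=float(f1), auroc=auroc,
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        ppv=float(ppv), sensitivity=float(sens), specificity=float(spec),
        confusion=cm_df, probabilities=probabilities)


def nested_select(specs: list[ModelSpec], X_train, y_train, X_test, y_test,
                  folds: int = 10, refit_on_all: bool = False):
    """Tune every family on the training set, rank by holdout balanced
    accuracy (ties broken by MCC, then family order), and return
    (winner_family, fitted_models, reports DataFrame-able dict).

    The holdout set is touched only after every family's tuning is
    complete. With ``refit_on_all`` the winning configuration is refitted
    on train+test for deployment.
    """
    if len(np.asarray(y_test)) == 0:
        raise ValueError("empty test set")
    fitted, cv_scores = {}, {}
    for spec in specs:
        model, cv_score, _ = tune_model(spec, X_train, y_train, folds=folds)
        fitted[spec.family] = model
        cv_scores[spec.family] = cv_score
    reports = {}
    X_test_arr = np.asarray(X_test, dtype=float)
    for i, spec in enumerate(specs):
        model = fitted[spec.family]
        y_pred = model.predict(X_test_arr)
        proba = model.predict_proba(X_test_arr)
        rep = compute_metrics(y_test, y_pred, probabilities=proba,
                              labels=model.classes_)
        rep.extra["cv_balanced_accuracy"] = cv_scores[spec.family]
        rep.extra["family_order"] = i
        reports[spec.family] = rep
    winner = min(reports,
                 key=lambda f: (-reports[f].balanced_accuracy,
                                -reports[f].mcc,
                                reports[f].extra["family_order"]))
    if refit_on_all:
        X_all = np.vstack([np.asarray(X_train, dtype=float), X_test_arr])
        y_all = np.concatenate([np.asarray(y_train), np.asarray(y_test)])
        fitted[winner] = fitted[winner].fit(X_all, y_all)
    return winner, fitted, reports


# ---------------------------------------------------------------------------
# agreement / abstain ensemble

ABSTAIN = "ABSTAIN"


class AgreementEnsemble(BaseEstimator, ClassifierMixin):
    """Voting ensemble that accepts a prediction only on unanimity.

    Members must share a label set. ``decide`` returns, per sample, the
    unanimous prediction with the mean member probability, or ABSTAIN when
    members disagree. ``coverage`` is accepted/n and accuracy is reported
    over the accepted samples only.
    """

    def __init__(self, members: list):
        self.members = members

    def fit(self, X, y):
        self.members_ = [m.fit(X, y) for m in self.members]
        self.classes_ = self.members_[0].classes_
        for m in self.members_[1:]:
            if not np.array_equal(m.classes_, self.classes_):
                raise ValueError("ensemble members have mismatched label sets")
        return self

    def _fitted_members(self):
        members = getattr(self, "members_", None)
        if members is None:
            members = self.members
            if len(members) < 2:
                raise ValueError("need at least two members")
            classes = members[0].classes_
            for m in members[1:]:
                if not np.array_equal(m.classes_, classes):
                    raise ValueError(
                        "ensemble members have mismatched label sets")
        return members

    def decide(self, X) -> pd.DataFrame:
        members = self._fitted_members()
        X = np.asarray(X, dtype=float)
        preds = np.column_stack([m.predict(X) for m in members])
        probas = np.stack([m.predict_proba(X) for m in members])
        mean_proba = probas.mean(axis=0)
        classes = members[0].classes_
        rows = []
        for i in range(len(X)):
            unanimous = all(p == preds[i, 0] for p in preds[i])
            if unanimous:
                cls = preds[i, 0]
                prob = float(mean_proba[i, list(classes).index(cls)])
                rows.append({"prediction": cls, "accepted": True,
                             "probability": prob,
                             "member_predictions": tuple(preds[i])})
            else:
                rows.append({"prediction": ABSTAIN, "accepted": False,
                             "probability": float("nan"),
                             "member_predictions": tuple(preds[i])})
        return pd.DataFrame(rows)

    def predict(self, X):
        return self.decide(X)["prediction"].to_numpy()


def ensemble_vote(models: list, X, y_true=None):
    """Run the agreement ensemble over fitted models.

    Returns (decisions, coverage, accuracy_over_accepted); the accuracy is
    None when y_true is not given or nothing was accepted.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    ens = AgreementEnsemble(models)
    decisions = ens.decide(X)
    coverage = float(decisions["accepted"].mean()) if len(decisions) else 0.0
    accuracy = None
    if y_true is not None:
        y_true = np.asarray(y_true)
        acc_mask = decisions["accepted"].to_numpy()
        if acc_mask.any():
            accuracy = float(
                (decisions.loc[acc_mask, "prediction"].to_numpy()
                 == y_true[acc_mask]).mean())
    return decisions, coverage, accuracy


class TrackedArray(np.ndarray):
    """ndarray that counts element reads; used to audit that model tuning
    never touches holdout samples."""

    def __new__(cls, arr):
        obj = np.asarray(arr, dtype=float).view(cls)
        obj.reads = 0
        return obj

    def __array_finalize__(self, obj):
        if obj is not None and not hasattr(self, "reads"):
            self.reads = getattr(obj, "reads", 0)

    def __getitem__(self, item):
        self.reads += 1
        return super().__getitem__(item)

    def __array__(self, dtype=None, copy=None):
        self.reads += 1
        base = self.view(np.ndarray)
        return base.astype(dtype) if dtype is not None else base
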