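"""Problem-specific feature pooling and consensus feature selection.

The base feature pool for each learning problem combines the top-ranked
genes of the stagewise linear model, the stage-salient genes, and genes
from the problem-specific contrast. The pool is then reduced by the
consensus of a Boruta-style shadow-feature wrapper and cross-validated
recursive feature elimination (RFE), both driven by random-forest
importance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

PROBLEMS = ("screen", "metastasis", "molsubtype", "histology")


# ---------------------------------------------------------------------------
# base feature pooling

def rank_consensus(list_by_lfc, list_by_p, k: int = 50,
                   backfill: int = 6) -> list[str]:
    """Consensus of the top-k of two rankings, plus a significance backfill.

    Returns the genes present in the top-k of both lists, ordered by the
    significance ranking, followed by the top ``backfill`` genes of the
    significance list not already included. When k exceeds a list's length
    the whole list is used.
    """
    list_by_lfc = list(list_by_lfc)
    list_by_p = list(list_by_p)
    top_lfc = set(list_by_lfc[:k])
    top_p = list_by_p[:k]
    consensus = [g for g in top_p if g in top_lfc]
    chosen = set(consensus)
    extras = [g for g in list_by_p if g not in chosen][:backfill]
    return consensus + extras


def pool_base_features(problem: str,
                       salient: pd.DataFrame | None = None,
                       linear_top: list[str] | None = None,
                       contrast: pd.DataFrame | None = None,
                       n_linear_top: int = 10,
                       n_top_per_subtype: int = 10,
                       lfc_min: float = 2.0,
                       consensus_k: int = 50,
                       consensus_backfill: int = 6) -> pd.DataFrame:
    """Assemble the base feature pool for a learning problem.

    * screen: stage-salient genes + top-n linear-model genes;
    * metastasis: rank-consensus of the metastasis contrast (by |lfc| and
      by significance) + stage-salient genes;
    * molsubtype: top-n genes per pairwise subtype contrast;
    * histology: every gene passing |lfc| > lfc_min in the histology
      contrast.

    Returns a deduplicated DataFrame with columns ``gene`` and
    ``provenance`` (linear_top / stage_salient / problem_contrast).
    """
    if problem not in PROBLEMS:
        raise ValueError(f"unknown problem {problem!r}")
    entries: list[tuple[str, str]] = []
    if problem == "screen":
        _require(salient is not None and linear_top is not None, problem)
        entries += [(g, "stage_salient") for g in salient["gene"]]
        entries += [(g, "linear_top") for g in list(linear_top)[:n_linear_top]]
    elif problem == "metastasis":
        _require(salient is not None and contrast is not None, problem)
        lfc_col = _single_pair_col(contrast, "lfc")
        p_col = _single_pair_col(contrast, "adj_p")
        by_lfc = contrast[lfc_col].abs().sort_values(ascending=False).index
        by_p = contrast[p_col].sort_values(kind="mergesort").index
        pooled = rank_consensus(by_lfc, by_p, k=consensus_k,
                                backfill=consensus_backfill)
        entries += [(g, "problem_contrast") for g in pooled]
        entries += [(g, "stage_salient") for g in salient["gene"]]
    elif problem == "molsubtype":
        _require(contrast is not None, problem)
        pair_cols = [c for c in contrast.columns if c.startswith("adj_p_")]
        for col in pair_cols:
            top = contrast[col].sort_values(kind="mergesort").index[:n_top_per_subtype]
            entries += [(g, "problem_contrast") for g in top]
    else:  # histology
        _require(contrast is not None, problem)
        lfc_col = _single_pair_col(contrast, "lfc")
        passing = contrast.index[contrast[lfc_col].abs() > lfc_min]
        entries += [(g, "problem_contrast") for g in passing]
    seen: dict[str, str] = {}
    for gene, prov in entries:
        seen.setdefault(gene, prov)
    if not seen:
        raise ValueError(f"empty base feature pool for problem {problem!r}")
    panel = pd.DataFrame({"gene": list(seen), "provenance": list(seen.values())})
    panel.insert(0, "problem", problem)
    return panel


def _require(cond: bool, problem: str):
    if not cond:
        raise ValueError(f"missing upstream inputs for problem {problem!r}")


def _single_pair_col(contrast: pd.DataFrame, prefix: str) -> str:
    cols = [c for c in contrast.columns
            if c.startswith(prefix + "_") and "_vs_" in c]
    if len(cols) != 1:
        raise ValueError(f"expected one pairwise {prefix} column, "
                         f"found {cols}")
    return cols[0]


# ---------------------------------------------------------------------------
# Boruta-style shadow-feature selection

class BorutaSelector(BaseEstimator):
    """All-relevant feature selection with shadow features.

    Each iteration appends a permuted (shadow) copy of every feature,
    fits a random forest, and scores a real feature a "hit" when its
    importance exceeds the maximum shadow importance. After ``max_iter``
    iterations each feature's hit count is tested against Binomial(n, 1/2)
    two-sided at ``alpha``: significantly more hits than chance confirms
    the feature, significantly fewer rejects it, anything else is
    tentative. Constant features are auto-rejected.

    Attributes
    ----------
    support_ : bool array, confirmed features.
    support_weak_ : bool array, tentative features.
    hits_ : int array of hit counts.
    n_iter_ : iterations performed.
    """

    def __init__(self, n_estimators: int = 500, alpha: float = 0.01,
                 max_iter: int = 100, include_tentative: bool = False,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.alpha = alpha
        self.max_iter = max_iter
        self.include_tentative = include_tentative
        self.random_state = random_state

    def fit(self, X, y):
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes")
        rng = check_random_state(self.random_state)
        n, p = X.shape
        constant = X.std(axis=0) == 0
        hits = np.zeros(p, dtype=int)
        for _ in range(self.max_iter):
            shadow = X.copy()
            for j in range(p):
                shadow[:, j] = shadow[rng.permutation(n), j]
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=rng.randint(np.iinfo(np.int32).max))
            forest.fit(np.hstack([X, shadow]), y)
            imp = forest.feature_importances_
            thresh = imp[p:].max()
            hits += imp[:p] > thresh
        self.hits_ = hits
        self.n_iter_ = self.max_iter
        confirmed = np.zeros(p, dtype=bool)
        tentative = np.zeros(p, dtype=bool)
        for j in range(p):
            if constant[j]:
                continue
            pval = binomtest(int(hits[j]), self.max_iter, 0.5,
                             alternative="two-sided").pvalue
            if pval < self.alpha:
                confirmed[j] = hits[j] > self.max_iter / 2
            else:
                tentative[j] = True
        self.support_ = confirmed
        self.support_weak_ = tentative
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        mask = self.support_ | (self.support_weak_
                                if self.include_tentative else False)
        return np.flatnonzero(mask) if indices else mask


def boruta_select(X: pd.DataFrame, y, alpha: float = 0.01,
                  max_iter: int = 100, n_estimators: int = 500,
                  seed: int | None = None,
                  include_tentative: bool = False) -> list[str]:
    """Run :class:`BorutaSelector` on a samples x features DataFrame and
    return the selected feature names."""
    sel = BorutaSelector(n_estimators=n_estimators, alpha=alpha,
                         max_iter=max_iter,
                         include_tentative=include_tentative,
                         random_state=seed).fit(X.to_numpy(), y)
    return [X.columns[j] for j in sel.get_support(indices=True)]


# ---------------------------------------------------------------------------
# cross-validated RFE with a one-standard-error size rule

class RfeSelector(BaseEstimator):
    """Backward feature elimination with cross-validated size choice.

    Features are eliminated one at a time by random-forest importance
    (sklearn RFE ranking); each candidate subset size is scored by
    stratified k-fold balanced accuracy, and the smallest subset whose
    mean score is within one standard error of the best is selected.
    Ties in importance fall back to column order (earlier column kept).
    """

    def __init__(self, estimator=None, subset_sizes=None, cv: int = 5,
                 scoring: str = "balanced_accuracy",
                 random_state: int | None = None):
        self.estimator = estimator
        self.subset_sizes = subset_sizes
        self.cv = cv
        self.scoring = scoring
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        est = self.estimator
        if est is None:
            est = RandomForestClassifier(n_estimators=250,
                                         random_state=self.random_state)
        rfe = RFE(clone(est), n_features_to_select=1, step=1).fit(X, y)
        self.ranking_ = rfe.ranking_
        sizes = self.subset_sizes
        if sizes is None:
            sizes = list(range(1, p + 1))
        sizes = sorted({min(s, p) for s in sizes if s >= 1})
        cv = StratifiedKFold(n_splits=self.cv, shuffle=True,
                             random_state=self.random_state)
        means, ses = {}, {}
        for s in sizes:
            cols = self.ranking_ <= s
            scores = cross_val_score(clone(est), X[:, cols], y, cv=cv,
                                     scoring=self.scoring)
            means[s] = scores.mean()
            ses[s] = scores.std(ddof=1) / np.sqrt(len(scores))
        best = max(sizes, key=lambda s: means[s])
        floor = means[best] - ses[best]
        chosen = min(s for s in sizes if means[s] >= floor)
        self.cv_scores_ = pd.DataFrame(
            {"size": sizes, "mean_score": [means[s] for s in sizes],
             "se": [ses[s] for s in sizes]})
        self.n_features_ = chosen
        self.support_ = self.ranking_ <= chosen
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_


def rfe_select(X: pd.DataFrame, y, subset_sizes=None, folds: int = 5,
               seed: int | None = None, estimator=None) -> list[str]:
    """Run :class:`RfeSelector` on a samples x features DataFrame and
    return the selected feature names (elimination order preserved)."""
    sel = RfeSelector(estimator=estimator, subset_sizes=subset_sizes,
                      cv=folds, random_state=seed).fit(X.to_numpy(), y)
    idx = sel.get_support(indices=True)
    order = np.argsort(sel.ranking_[idx], kind="stable")
    return [X.columns[j] for j in idx[order]]


def consensus_features(boruta_genes, rfe_genes) -> list[str]:
    """Intersection of the two selector outputs (RFE order preserved).

    An empty intersection with non-empty inputs falls back to the RFE set
    with a warning; two empty inputs are an error.
    """
    boruta_genes, rfe_genes = list(boruta_genes), list(rfe_genes)
    if not boruta_genes and not rfe_genes:
        raise ValueError("both selector outputs are empty")
    consensus = [g for g in rfe_genes if g in set(boruta_genes)]
    if not consensus:
        warnings.warn("selector consensus empty; falling back to the RFE set",
                      stacklevel=2)
        return rfe_genes
    return consensus


def gini_importance_report(fitted_rf, feature_names) -> pd.Series:
    """Mean-decrease-in-impurity importances normalized to the top feature.

    Returns a descending Series whose maximum is exactly 1.0.
    """
    check_is_fitted(fitted_rf, "feature_importances_")
    imp = pd.Series(fitted_rf.feature_importances_, index=list(feature_names))
    top = imp.max()
    if top <= 0:
        raise ValueError("all importances are zero")
    return (imp / top).sort_values(ascending=False)
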