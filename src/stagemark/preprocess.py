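"""Cohort conditioning: filtering, label derivation, variance stabilization,
stratified splitting, SMOTE class balancing, and cross-platform harmonization.

Expression matrices are pandas DataFrames with genes as rows and samples as
columns. Annotation tables are DataFrames indexed by sample id.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils import check_random_state
from statsmodels.nonparametric.smoothers_lowess import lowess

STAGES = ("I", "II", "III", "IV")

# AJCC sub-stage -> macro stage. Both arabic ("2B") and roman ("IIB")
# spellings occur in clinical files; "X"/missing map to NA (None).
_SUBSTAGE_MAP = {
    "1": "I", "1A": "I", "1B": "I", "I": "I", "IA": "I", "IB": "I",
    "2": "II", "2A": "II", "2B": "II", "II": "II", "IIA": "II", "IIB": "II",
    "3": "III", "3A": "III", "3B": "III", "3C": "III",
    "III": "III", "IIIA": "III", "IIIB": "III", "IIIC": "III",
    "4": "IV", "IV": "IV",
}


def merge_substages(stage_raw) -> str | None:
    """Collapse an AJCC sub-stage string to its macro stage (I-IV) or None.

    Total and idempotent: any unrecognized value (including "X", NA, or an
    already-merged macro stage) maps to itself-or-None without error.
    """
    if stage_raw is None or (isinstance(stage_raw, float) and np.isnan(stage_raw)):
        return None
    s = str(stage_raw).strip().upper()
    if s.startswith("STAGE"):
        s = s[len("STAGE"):].strip()
    return _SUBSTAGE_MAP.get(s)


def derive_molecular_subtype(er, pgr, her2, ki67=None) -> str | None:
    """IHC-based molecular subtype: TNBC, HER2, or Luminal.

    Receptor states are "+", "-", or None. Triple-negative -> TNBC;
    HER2+ with both hormone receptors negative -> HER2; any hormone-receptor
    positivity -> Luminal. Without a Ki-67 labelling index the Luminal A/B
    distinction cannot be made and the two are lumped into "Luminal"
    (with Ki-67, "Luminal A"/"Luminal B" are emitted for HER2- tumours).
    All three receptors missing -> None.
    """
    states = {"+", "-"}
    if er not in states and pgr not in states and her2 not in states:
        return None
    hr_pos = er == "+" or pgr == "+"
    if hr_pos:
        if ki67 is None or her2 == "+":
            return "Luminal"
        return "Luminal B" if ki67 >= 0.14 else "Luminal A"
    if her2 == "+":
        return "HER2"
    if er == "-" and pgr == "-" and her2 == "-":
        return "TNBC"
    return None


def filter_low_variance(X: pd.DataFrame, sigma_min: float = 1.0) -> pd.DataFrame:
    """Drop genes whose across-sample standard deviation is below sigma_min.

    The boundary is kept: genes with sd exactly equal to ``sigma_min``
    are retained (removal criterion is strictly sd < sigma_min).
    """
    sd = X.std(axis=1, ddof=1).to_numpy()
    keep = sd >= sigma_min
    if not keep.any():
        warnings.warn("variance filter removed every gene", stacklevel=2)
    return X.loc[keep]


class VoomTransformer(BaseEstimator, TransformerMixin):
    """log2(x + pseudo_count) variance stabilization with optional
    precision weights from a smoothed mean vs sqrt-sd trend.

    The weights emulate the variance-stabilizing weighting used with
    RNA-seq linear modelling: a lowess trend of sqrt(residual sd) against
    mean log2 expression is fitted across genes and each gene receives
    weight 1 / trend(mean)^4, suitable for weighted least squares.

    Attributes
    ----------
    trend_x_, trend_y_ : ndarray
        Fitted lowess trend (mean log2 expression vs sqrt sd).
    weights_ : DataFrame
        Per-observation weights aligned with the transformed matrix
        (constant within a gene).
    """

    def __init__(self, pseudo_count: float = 0.5, lowess_frac: float = 0.5):
        self.pseudo_count = pseudo_count
        self.lowess_frac = lowess_frac

    def fit(self, X: pd.DataFrame, y=None):
        logx = self._log(X)
        mean = logx.mean(axis=1).to_numpy()
        sqrt_sd = np.sqrt(logx.std(axis=1, ddof=1).to_numpy())
        if np.ptp(mean) < 1e-9:  # degenerate: no mean spread, flat trend
            self.trend_x_ = np.array([mean.min() - 1, mean.max() + 1])
            self.trend_y_ = np.full(2, sqrt_sd.mean())
            return self
        order = np.argsort(mean)
        fit = lowess(sqrt_sd[order], mean[order], frac=self.lowess_frac,
                     return_sorted=True)
        keep = np.isfinite(fit[:, 1])
        self.trend_x_, self.trend_y_ = fit[keep, 0], fit[keep, 1]
        return self

    def _log(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = X.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("variance stabilization requires non-negative input")
        return pd.DataFrame(np.log2(arr + self.pseudo_count),
                            index=X.index, columns=X.columns)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        logx = self._log(X)
        mean = logx.mean(axis=1).to_numpy()
        trend = np.interp(mean, self.trend_x_, self.trend_y_)
        trend = np.clip(trend, 1e-6, None)
        w = 1.0 / trend ** 4
        self.weights_ = pd.DataFrame(
            np.repeat(w[:, None], logx.shape[1], axis=1),
            index=logx.index, columns=logx.columns)
        return logx


def variance_stabilize(X: pd.DataFrame, pseudo_count: float = 0.5,
                       return_weights: bool = False):
    """Functional wrapper over :class:`VoomTransformer`."""
    vt = VoomTransformer(pseudo_count=pseudo_count)
    logx = vt.fit(X).transform(X)
    if return_weights:
        return logx, vt.weights_
    return logx


def stratified_split(annotation: pd.DataFrame, stratify_on: str,
                     train_fraction: float = 0.8, seed: int = 0):
    """Stratified train/test partition of sample ids.

    Per-stratum train counts follow largest-remainder rounding so that the
    overall train total equals round(n * train_fraction) while each stratum
    stays within one sample of the target fraction. Strata of size < 2 go
    entirely to the training set with a warning.

    Returns (train_ids, test_ids) as lists.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = annotation[stratify_on]
    if labels.isna().any():
        raise ValueError(f"stratify label '{stratify_on}' has missing values")
    rng = check_random_state(seed)
    strata = {}
    singletons = []
    for value, idx in labels.groupby(labels).groups.items():
        ids = list(idx)
        if len(ids) < 2:
            warnings.warn(f"stratum {value!r} has <2 samples; assigned to train",
                          stacklevel=2)
            singletons.extend(ids)
        else:
            strata[value] = ids
    sizes = {v: len(ids) for v, ids in strata.items()}
    total = sum(sizes.values())
    target_total = int(round(total * train_fraction))
    ideal = {v: n * train_fraction for v, n in sizes.items()}
    counts = {v: int(np.floor(x)) for v, x in ideal.items()}
    remainder = target_total - sum(counts.values())
    by_frac = sorted(ideal, key=lambda v: (ideal[v] - counts[v]), reverse=True)
    for v in by_frac[:remainder]:
        counts[v] += 1
    train_ids, test_ids = list(singletons), []
    for v, ids in strata.items():
        ids = list(ids)
        rng.shuffle(ids)
        n_tr = min(counts[v], len(ids))
        train_ids.extend(ids[:n_tr])
        test_ids.extend(ids[n_tr:])
    return train_ids, test_ids


class SmoteBalancer(BaseEstimator):
    """SMOTE with percentage-based over/under-sampling counting semantics.

    For a binary problem with ``n_min`` minority samples:

    * ``perc_over`` percent oversampling creates ``n_min * perc_over / 100``
      synthetic minority points, each a convex combination of a minority
      point and one of its ``k`` minority-class nearest neighbours, giving
      ``n_min * (1 + perc_over/100)`` minority samples in total.
    * ``perc_under`` percent undersampling retains
      ``(perc_under/100) * (n_min * perc_over/100)`` majority samples,
      drawn without replacement when possible.

    With 16 minority / 837 majority and the 1000% / 300% defaults this
    yields 176 minority and 480 majority samples.
    """

    def __init__(self, perc_over: float = 1000.0, perc_under: float = 300.0,
                 k: int = 5, random_state: int | None = None):
        self.perc_over = perc_over
        self.perc_under = perc_under
        self.k = k
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE balancing requires a binary outcome")
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
        X_min, X_maj = X[y == minority], X[y == majority]
        n_min = len(X_min)
        rng = check_random_state(self.random_state)

        k = self.k
        if n_min <= k:
            k = max(1, n_min - 1)
            warnings.warn(
                f"minority count {n_min} <= k={self.k}; reducing k to {k}",
                stacklevel=2)
        n_syn = int(round(n_min * self.perc_over / 100.0))
        if n_syn > 0:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
            _, neigh = nn.kneighbors(X_min)
            neigh = neigh[:, 1:]  # drop self
            base = np.arange(n_syn) % n_min  # DMwR: each point spawns over/100
            chosen = neigh[base, rng.randint(0, k, size=n_syn)]
            gamma = rng.uniform(size=(n_syn, 1))
            X_syn = X_min[base] + gamma * (X_min[chosen] - X_min[base])
        else:
            X_syn = np.empty((0, X.shape[1]))

        n_keep = int(round(self.perc_under / 100.0 * n_syn))
        if n_keep == 0:
            X_keep = X_maj
        elif n_keep <= len(X_maj):
            X_keep = X_maj[rng.choice(len(X_maj), size=n_keep, replace=False)]
        else:
            X_keep = X_maj[rng.choice(len(X_maj), size=n_keep, replace=True)]

        X_out = np.vstack([X_min, X_syn, X_keep])
        y_out = np.concatenate([
            np.full(n_min + n_syn, minority, dtype=y.dtype),
            np.full(len(X_keep), majority, dtype=y.dtype),
        ])
        return X_out, y_out


def smote_balance(X, y, perc_over: float = 1000.0, perc_under: float = 300.0,
                  k: int = 5, seed: int | None = None):
    """Functional wrapper over :class:`SmoteBalancer`."""
    return SmoteBalancer(perc_over=perc_over, perc_under=perc_under, k=k,
                         random_state=seed).fit_resample(X, y)


class FsqnNormalizer(BaseEstimator, TransformerMixin):
    """Feature-specific quantile normalization.

    Each gene of the target matrix is rank-mapped onto the empirical
    quantiles of the same gene in a reference matrix, removing per-gene
    platform shifts while preserving within-gene sample ranks. Genes
    absent from the reference pass through unchanged with a warning.
    """

    def fit(self, reference: pd.DataFrame, y=None):
        self.reference_ = reference
        return self

    def transform(self, target: pd.DataFrame) -> pd.DataFrame:
        out = target.copy().astype(float)
        missing = [g for g in target.index if g not in self.reference_.index]
        if missing:
            warnings.warn(
                f"{len(missing)} gene(s) missing from reference; passed through",
                stacklevel=2)
        n = target.shape[1]
        if n == 1:
            positions = np.array([0.5])
        for gene in target.index:
            if gene in missing:
                continue
            vals = target.loc[gene].to_numpy(dtype=float)
            ref = np.sort(self.reference_.loc[gene].to_numpy(dtype=float))
            ranks = rankdata(vals, method="average")
            p = (ranks - 1) / (n - 1) if n > 1 else np.array([0.5])
            out.loc[gene] = np.quantile(ref, p)
        return out


def fsqn_harmonize(target: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper over :class:`FsqnNormalizer`."""
    return FsqnNormalizer().fit(reference).transform(target)
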