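"""Stage-encoded differential expression.

Two stage-aware linear models are fitted gene-wise to log2 expression:

* reference coding: intercept = control baseline, coefficients = stagewise
  log fold-changes (lfc) relative to controls;
* cell-means coding: one coefficient per group (control, stages I-IV), so
  the stage-k deviation is beta_k - beta_0.

Because both designs are group-indicator models, the least-squares
coefficients are exactly the group means (or their differences from the
control mean), computed here in closed form. Gene-wise residual variances
are moderated by empirical-Bayes shrinkage toward a pooled prior before
t-statistics, and p-values are Benjamini-Hochberg adjusted within each
contrast family.

A two-level contrast protocol then produces the feature classes:
level-I (stage vs control) stage-specific sets, level-II (inter-stage)
stage-salient calls, monotonic trend genes, and contra-regulated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

STAGES = ("I", "II", "III", "IV")


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (squeeze toward a pooled prior)

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float):
    """Shrink gene-wise residual variances toward a common prior.

    Fits a scaled inverse-chi-square prior (df0, s0^2) to the observed
    variances by matching the moments of log s^2, then returns the
    posterior variances (df0*s0^2 + df*s^2) / (df0 + df) and df0.
    A non-finite or huge fitted df0 degenerates to the common-variance
    limit, which is handled by returning df0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_var = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if e_var <= 0:
        # observed spread no larger than sampling noise: common variance
        s0_2 = np.exp(np.mean(e))
        return np.full_like(s2, s0_2), np.inf
    df0 = 2 * _trigamma_inverse(e_var)
    s0_2 = np.exp(np.mean(e) + special.digamma(df0 / 2) - np.log(df0 / 2))
    post = (df0 * s0_2 + df * s2) / (df0 + df)
    return post, df0


# ---------------------------------------------------------------------------
# gene-wise group-indicator fits

@dataclass
class StageDesign:
    """Design for the stage-encoded linear model.

    encoding="reference": intercept is the control baseline and the
    reported coefficients are stagewise lfc relative to control.
    encoding="cell_means": one coefficient (group mean) per group with
    the control as one of the indicator variables.
    """
    encoding: str = "cell_means"
    groups: tuple = ("control",) + STAGES

    def __post_init__(self):
        if self.encoding not in ("reference", "cell_means"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if not self.groups:
            raise ValueError("groups must be non-empty")


def _group_stats(X: pd.DataFrame, labels: pd.Series, groups, weights=None):
    """Per-gene group means, pooled residual variance, residual df, counts."""
    n_genes = X.shape[0]
    means = {}
    counts = {}
    rss = np.zeros(n_genes)
    df_resid = 0
    arr = X.to_numpy(dtype=float)
    w = None if weights is None else weights.to_numpy(dtype=float)
    for g in groups:
        cols = np.asarray(labels == g)
        n = int(cols.sum())
        counts[g] = n
        if n == 0:
            means[g] = np.full(n_genes, np.nan)
            continue
        sub = arr[:, cols]
        if w is not None:
            wsub = w[:, cols]
            mu = (sub * wsub).sum(axis=1) / wsub.sum(axis=1)
            rss += (wsub * (sub - mu[:, None]) ** 2).sum(axis=1)
        else:
            mu = sub.mean(axis=1)
            rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        means[g] = mu
        df_resid += max(n - 1, 0)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = rss / df_resid
    return means, counts, s2, df_resid


def fit_linear_model(X: pd.DataFrame, labels: pd.Series,
                     design: StageDesign | None = None,
                     weights: pd.DataFrame | None = None,
                     moderate: bool = True,
                     control_label: str = "control") -> pd.DataFrame:
    """Gene-wise stage-encoded least squares with moderated t-statistics.

    Parameters
    ----------
    X : DataFrame, genes x samples, log2 scale.
    labels : Series over samples with values in design.groups.
    weights : optional per-observation precision weights (genes x samples).
    moderate : apply empirical-Bayes variance shrinkage before t-tests.

    Returns a DataFrame indexed by gene with per-group coefficients
    (``coef_<group>`` under cell-means; ``intercept``/``lfc_<stage>`` under
    reference coding), and per stage-vs-control contrast columns
    ``lfc_<stage>``, ``p_<stage>``, ``adj_p_<stage>``.
    Groups with fewer than 2 samples have their contrasts skipped with
    a warning.
    """
    design = design or StageDesign()
    labels = labels.loc[X.columns]
    present = [g for g in design.groups if (labels == g).sum() > 0]
    if control_label not in present:
        raise ValueError("control group absent")
    means, counts, s2, df_resid = _group_stats(X, labels, present, weights)
    if moderate:
        s2_used, df0 = squeeze_variances(s2, df_resid)
        df_t = np.inf if not np.isfinite(df0) else df_resid + df0
    else:
        s2_used, df_t = s2, df_resid

    out = pd.DataFrame(index=X.index)
    mu0 = means[control_label]
    if design.encoding == "cell_means":
        for g in present:
            out[f"coef_{g}"] = means[g]
    else:
        out["intercept"] = mu0
    contrast_groups = [g for g in present if g != control_label]
    for g in contrast_groups:
        if counts[g] < 2 or counts[control_label] < 2:
            warnings.warn(f"group {g!r} has <2 samples; contrast skipped",
                          stacklevel=2)
            continue
        diff = means[g] - mu0
        se = np.sqrt(s2_used * (1.0 / counts[g] + 1.0 / counts[control_label]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        if np.isinf(df_t):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), df_t)
        p = np.where(np.isnan(p), 1.0, p)
        out[f"lfc_{g}"] = diff
        out[f"p_{g}"] = p
        out[f"adj_p_{g}"] = bh_adjust(p)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def regulation_status(lfcs) -> str:
    """Up/Down label from the sign of the mean stagewise lfc."""
    return "Up" if float(np.mean(np.asarray(lfcs, dtype=float))) > 0 else "Down"


# ---------------------------------------------------------------------------
# level-I: stage-specific sets

def level1_stage_specific(result: pd.DataFrame, lfc_min: float = 2.0,
                          p_max: float = 0.001) -> dict[str, set]:
    """Per-stage gene sets passing |lfc| > lfc_min and adjusted p < p_max.

    Both thresholds are strict, so a gene at exactly |lfc| = lfc_min is
    excluded. Sets may overlap across stages.
    """
    sets: dict[str, set] = {}
    for stage in STAGES:
        lfc_col, p_col = f"lfc_{stage}", f"adj_p_{stage}"
        if lfc_col not in result.columns:
            sets[stage] = set()
            continue
        mask = (result[lfc_col].abs() > lfc_min) & (result[p_col] < p_max)
        sets[stage] = set(result.index[mask])
    return sets


# ---------------------------------------------------------------------------
# level-II: stage salience

def salient_stage_rule(control_mean: float, deviations) -> tuple[str, str] | None:
    """Assign the salient stage from stage-vs-control deviations.

    The salient stage is the argmax of |deviation|; the direction is the
    sign of the salient deviation. Ties in |deviation| are ambiguous and
    return None. ``control_mean`` is carried for record-keeping only; the
    deviations are already relative to control.
    """
    dev = np.asarray(deviations, dtype=float)
    absdev = np.abs(dev)
    best = absdev.max()
    winners = np.flatnonzero(absdev == best)
    if len(winners) != 1:
        return None
    k = winners[0]
    return STAGES[k], ("Up" if dev[k] > 0 else "Down")


def call_stage_salient(X: pd.DataFrame, labels: pd.Series,
                       result: pd.DataFrame | None = None,
                       level1_sets: dict[str, set] | None = None,
                       contrast_p_max: float = 0.05,
                       n_top_per_stage: int = 10,
                       lfc_min: float = 2.0, p_max: float = 0.001,
                       moderate: bool = True,
                       control_label: str = "control") -> pd.DataFrame:
    """Two-level contrast protocol for stage-salient genes.

    A gene must pass level-I in at least one stage. Its candidate salient
    stage k is the argmax of |mean_k - mean_control|; the call is made iff
    every level-II pairwise contrast (k vs j, j != k) is significant at
    ``contrast_p_max`` (BH-adjusted across genes per pair) with the
    deviation mean_k - mean_j of consistent sign. The reported contrast p
    is the worst (max) pairwise adjusted p; per-stage lists are truncated
    to the top ``n_top_per_stage`` by that p.

    Returns a DataFrame with columns gene, stage, direction, the group-mean
    coefficients, adj_p_contrast and adj_p_control.
    """
    labels = labels.loc[X.columns]
    if result is None:
        result = fit_linear_model(X, labels, StageDesign("cell_means"),
                                  moderate=moderate, control_label=control_label)
    if level1_sets is None:
        level1_sets = level1_stage_specific(result, lfc_min=lfc_min, p_max=p_max)
    candidates = sorted(set().union(*level1_sets.values()))
    if not candidates:
        return _empty_salient_frame()

    present_stages = [s for s in STAGES if (labels == s).sum() >= 2]
    means = {s: result[f"coef_{s}"] for s in present_stages}
    mu0 = result[f"coef_{control_label}"]
    counts = {g: int((labels == g).sum())
              for g in present_stages + [control_label]}

    # moderated pairwise inter-stage contrasts, BH within each pair family
    _, _, s2, df_resid = _group_stats(
        X, labels, [control_label] + present_stages)
    if moderate:
        s2_used, df0 = squeeze_variances(s2, df_resid)
        df_t = np.inf if not np.isfinite(df0) else df_resid + df0
    else:
        s2_used, df_t = s2, df_resid
    pair_adj = {}
    for i, a in enumerate(present_stages):
        for b in present_stages[i + 1:]:
            diff = (means[a] - means[b]).to_numpy()
            se = np.sqrt(s2_used * (1 / counts[a] + 1 / counts[b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / se
            if np.isinf(df_t):
                p = 2 * stats.norm.sf(np.abs(t))
            else:
                p = 2 * stats.t.sf(np.abs(t), df_t)
            p = np.where(np.isnan(p), 1.0, p)
            adj = pd.Series(bh_adjust(p), index=result.index)
            pair_adj[(a, b)] = adj
            pair_adj[(b, a)] = adj

    rows = []
    for gene in candidates:
        dev = np.array([means[s].loc[gene] - mu0.loc[gene]
                        for s in present_stages])
        call = salient_stage_rule(mu0.loc[gene],
                                  _pad_deviations(dev, present_stages))
        if call is None:
            warnings.warn(f"ambiguous salience tie for {gene}; no call",
                          stacklevel=2)
            continue
        stage, direction = call
        if stage not in present_stages:
            continue
        k_dev = means[stage].loc[gene] - mu0.loc[gene]
        worst_p, consistent = 0.0, True
        for j in present_stages:
            if j == stage:
                continue
            d_kj = means[stage].loc[gene] - means[j].loc[gene]
            if np.sign(d_kj) != np.sign(k_dev) or d_kj == 0:
                consistent = False
                break
            worst_p = max(worst_p, float(pair_adj[(stage, j)].loc[gene]))
        if not consistent or worst_p >= contrast_p_max:
            continue
        row = {"gene": gene, "stage": stage, "direction": direction,
               f"coef_{control_label}": mu0.loc[gene],
               "adj_p_contrast": worst_p,
               "adj_p_control": float(result[f"adj_p_{stage}"].loc[gene])}
        for s in present_stages:
            row[f"coef_{s}"] = means[s].loc[gene]
        rows.append(row)
    if not rows:
        return _empty_salient_frame()
    calls = pd.DataFrame(rows)
    calls = (calls.sort_values(["stage", "adj_p_contrast"])
                  .groupby("stage", group_keys=False)
                  .head(n_top_per_stage)
                  .reset_index(drop=True))
    return calls


def _pad_deviations(dev, present_stages):
    """Expand deviations over present stages to the full I-IV vector,
    padding absent stages with 0 so they can never win the argmax."""
    full = np.zeros(len(STAGES))
    for d, s in zip(dev, present_stages):
        full[STAGES.index(s)] = d
    return full


def _empty_salient_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "stage", "direction",
                                 "adj_p_contrast", "adj_p_control"])


# ---------------------------------------------------------------------------
# monotonic trend genes

def detect_monotonic(X: pd.DataFrame, labels: pd.Series,
                     include_control: bool = False) -> pd.DataFrame:
    """Genes with strictly monotone stage-group means, with an ordinal fit.

    Stage means (I -> IV) must be strictly increasing or strictly
    decreasing. For flagged genes, per-sample expression is regressed on
    the ordinal stage (coded 1..4; controls excluded by default), and the
    slope p-values are BH-adjusted across flagged genes.

    Returns a DataFrame with gene, intercept, slope, p, adj_p, adj_r2,
    status (Up/Down by slope sign).
    """
    labels = labels.loc[X.columns]
    cancer = labels.isin(STAGES)
    if include_control:
        cancer = cancer | (labels == "control")
    stage_means = {s: X.loc[:, (labels == s).to_numpy()].mean(axis=1)
                   for s in STAGES}
    M = np.column_stack([stage_means[s].to_numpy() for s in STAGES])
    diffs = np.diff(M, axis=1)
    inc = (diffs > 0).all(axis=1)
    dec = (diffs < 0).all(axis=1)
    flagged = X.index[inc | dec]
    if len(flagged) == 0:
        return pd.DataFrame(columns=["gene", "intercept", "slope", "p",
                                     "adj_p", "adj_r2", "status"])

    cols = cancer.to_numpy()
    x = labels[cols].map({s: i + 1 for i, s in enumerate(STAGES)})
    if include_control:
        x = x.fillna(0)
    x = x.to_numpy(dtype=float)
    Y = X.loc[flagged].to_numpy(dtype=float)[:, cols]
    n = len(x)
    xm = x - x.mean()
    sxx = (xm ** 2).sum()
    ym = Y - Y.mean(axis=1, keepdims=True)
    slope = ym @ xm / sxx
    intercept = Y.mean(axis=1) - slope * x.mean()
    resid = ym - np.outer(slope, xm)
    rss = (resid ** 2).sum(axis=1)
    tss = (ym ** 2).sum(axis=1)
    df = n - 2
    s2 = rss / df
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
        r2 = 1 - rss / tss
    adj_r2 = 1 - (1 - r2) * (n - 1) / df
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame({
        "gene": flagged, "intercept": intercept, "slope": slope,
        "p": p, "adj_p": bh_adjust(p),
        "adj_r2": adj_r2,
        "status": np.where(slope > 0, "Up", "Down"),
    }).reset_index(drop=True)
    return out.sort_values("adj_p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# contra-regulation

def classify_contra_regulation(stage_means, control_mean: float,
                               anchor_stage: str | None = None):
    """Classify a stage-specific gene's trajectory as contra-regulated.

    The deviation trajectory d_k = stage_mean_k - control_mean is
    "paradoxical" when it reverses sign across stages: a gene anchored up
    at one stage later drops below the control baseline (or mirror-image
    for down-anchored genes). Six patterns are distinguished by the anchor
    (interior extremum) position: patterns 1-3 are up-anchored at stage
    I/II/III, patterns 4-6 the down-anchored mirrors. A trajectory whose
    deviations keep a consistent sign, or whose extremum sits at stage IV,
    is not contra-regulated and returns None.

    Returns (anchor_stage, pattern_id) or None.
    """
    d = np.asarray(stage_means, dtype=float) - control_mean
    pos, neg = (d > 0).any(), (d < 0).any()
    if not (pos and neg):
        return None
    if anchor_stage is None:
        k = int(np.argmax(np.abs(d)))
    else:
        k = STAGES.index(anchor_stage)
    if k == 3:  # extremum at stage IV: terminal, not paradoxical
        return None
    up = d[k] > 0
    pattern = (k + 1) if up else (k + 4)
    return STAGES[k], pattern


# ---------------------------------------------------------------------------
# problem-specific group contrasts

def group_contrast(X: pd.DataFrame, labels: pd.Series,
                   moderate: bool = True) -> pd.DataFrame:
    """Cell-means fit over arbitrary group labels with all pairwise contrasts.

    Used for the problem-specific contrasts: non-metastatic vs metastatic,
    the three-way molecular-subtype comparisons, and ductal vs lobular
    histology. Returns a DataFrame with ``coef_<level>`` columns and, per
    pair (a, b), ``lfc_<a>_vs_<b>``, ``p_<a>_vs_<b>``, ``adj_p_<a>_vs_<b>``.
    """
    labels = labels.loc[X.columns]
    levels = [lv for lv in pd.unique(labels.dropna())]
    if len(levels) < 2:
        raise ValueError("group contrast requires at least two levels")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ValueError(f"level {lv!r} has fewer than 2 samples")
    means, counts, s2, df_resid = _group_stats(X, labels, levels)
    if moderate:
        s2_used, df0 = squeeze_variances(s2, df_resid)
        df_t = np.inf if not np.isfinite(df0) else df_resid + df0
    else:
        s2_used, df_t = s2, df_resid
    out = pd.DataFrame(index=X.index)
    for lv in levels:
        out[f"coef_{lv}"] = means[lv]
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            diff = means[a] - means[b]
            se = np.sqrt(s2_used * (1 / counts[a] + 1 / counts[b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / se
            if np.isinf(df_t):
                p = 2 * stats.norm.sf(np.abs(t))
            else:
                p = 2 * stats.t.sf(np.abs(t), df_t)
            p = np.where(np.isnan(p), 1.0, p)
            out[f"lfc_{a}_vs_{b}"] = diff
            out[f"p_{a}_vs_{b}"] = p
            out[f"adj_p_{a}_vs_{b}"] = bh_adjust(p)
    return out
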