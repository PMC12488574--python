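"""Late integration of miRNA and methylation layers with the mRNA results.

miRNA layer: the same two-level contrast protocol is applied to the miRNA
matrix; a (regulator, target) pair is concordant in expression when the
directions are opposite (an over-expressed miRNA suppressing its target or
vice versa), and temporally concordant when the miRNA's salience stage is
at least as early as the target gene's. Temporal concordance is only
evaluated when expression concordance holds.

Methylation layer: per-gene CpG probes are clustered by correlation, beta
distributions are decomposed into Gaussian mixtures (on the logit/M-value
scale, component count by BIC), differential methylation is called by
rank-sum test with an effect-size filter, and methylation-driven genes
require a negative methylation-expression correlation. Stage-salient
methylation is called by the consensus of three stage-informed routes:
probe-averaged betas ("averep"), logit M-values, and mixture-component
posterior means (a MethylMix-style summarization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import expit, logit
from sklearn.mixture import GaussianMixture

from .dge import STAGES, bh_adjust, call_stage_salient

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


# ---------------------------------------------------------------------------
# miRNA concordance

def mirna_stage_salience(X_mir: pd.DataFrame, labels: pd.Series,
                         **kwargs) -> pd.DataFrame:
    """Stage-salient miRNAs via the identical two-level contrast protocol
    used for genes."""
    return call_stage_salient(X_mir, labels, **kwargs)


def expression_concordance(gene_direction: str, mirna_direction: str) -> bool:
    """True iff the gene and its regulator move in opposite directions."""
    for d in (gene_direction, mirna_direction):
        if d not in ("Up", "Down"):
            raise ValueError(f"direction must be Up/Down, got {d!r}")
    return gene_direction != mirna_direction


def temporal_concordance(mirna_stage: str, gene_stage: str) -> bool:
    """True iff the miRNA's salience is at least as early as the gene's."""
    return _STAGE_INDEX[mirna_stage] <= _STAGE_INDEX[gene_stage]


def join_targets(mirna_salience: pd.DataFrame, target_map: pd.DataFrame,
                 gene_salience: pd.DataFrame):
    """Join salient miRNAs to salient target genes through a map table.

    ``target_map`` must have columns (mirna, gene). Returns
    (records, orphan_genes, orphan_mirnas): one record per mapped pair of
    salient regulator and salient target with both concordance flags
    (temporal is NA when expression concordance fails), plus the salient
    genes with no salient regulator and the salient miRNAs with no salient
    target.
    """
    for col in ("mirna", "gene"):
        if col not in target_map.columns:
            raise ValueError("target map needs columns 'mirna' and 'gene'")
    mir_info = {row["gene"]: (row["direction"], row["stage"])
                for _, row in mirna_salience.iterrows()}
    gene_info = {row["gene"]: (row["direction"], row["stage"])
                 for _, row in gene_salience.iterrows()}
    rows = []
    matched_genes, matched_mirnas = set(), set()
    for _, pair in target_map.iterrows():
        m, g = pair["mirna"], pair["gene"]
        if m not in mir_info or g not in gene_info:
            continue
        g_dir, g_stage = gene_info[g]
        m_dir, m_stage = mir_info[m]
        expr_conc = expression_concordance(g_dir, m_dir)
        temp_conc = temporal_concordance(m_stage, g_stage) if expr_conc else None
        rows.append({"gene": g, "gene_direction": g_dir,
                     "gene_salient_stage": g_stage, "mirna": m,
                     "mirna_direction": m_dir, "mirna_salient_stage": m_stage,
                     "expression_concordant": expr_conc,
                     "temporal_concordant": temp_conc})
        matched_genes.add(g)
        matched_mirnas.add(m)
    records = pd.DataFrame(rows, columns=[
        "gene", "gene_direction", "gene_salient_stage", "mirna",
        "mirna_direction", "mirna_salient_stage", "expression_concordant",
        "temporal_concordant"])
    orphan_genes = sorted(set(gene_info) - matched_genes)
    orphan_mirnas = sorted(set(mir_info) - matched_mirnas)
    return records, orphan_genes, orphan_mirnas


# ---------------------------------------------------------------------------
# methylation analysis

def cluster_probes(beta: pd.DataFrame, r_min: float = 0.7) -> pd.Series:
    """Cluster one gene's probes on (1 - Pearson r) distance.

    Average-linkage hierarchical clustering; the tree is cut at the
    coarsest level at which every cluster's within-cluster pairwise
    correlations all exceed ``r_min``. Returns a Series probe -> cluster id
    (1-based). A single probe forms one cluster.
    """
    probes = list(beta.index)
    if len(probes) == 1:
        return pd.Series([1], index=probes)
    corr = np.corrcoef(beta.to_numpy(dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    heights = sorted({0.0} | set(link[:, 2]))
    best = None
    for h in heights:  # coarsest valid cut wins (fewest clusters)
        labels = hierarchy.fcluster(link, t=h, criterion="distance")
        ok = True
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) < 2:
                continue
            sub = corr[np.ix_(members, members)]
            if sub[np.triu_indices(len(members), 1)].min() <= r_min:
                ok = False
                break
        if ok:
            best = labels
    if best is None:
        best = np.arange(1, len(probes) + 1)
    return pd.Series(best, index=probes)


@dataclass
class MixtureFit:
    """Gaussian mixture decomposition of one beta distribution (fitted on
    the logit scale; means reported back on the beta scale)."""
    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: dict
    model: GaussianMixture


def fit_beta_mixture(beta_values, max_components: int = 3,
                     random_state: int = 0, n_init: int = 3) -> MixtureFit:
    """Fit 1..max_components Gaussian mixtures to logit-transformed beta
    values and keep the component count minimizing BIC."""
    b = np.asarray(beta_values, dtype=float)
    b = b[np.isfinite(b)]
    if len(b) < 20:
        raise ValueError("need at least 20 observations for a mixture fit")
    m = logit(np.clip(b, 1e-4, 1 - 1e-4)).reshape(-1, 1)
    bics, models = {}, {}
    for k in range(1, max_components + 1):
        try:
            gm = GaussianMixture(n_components=k, n_init=n_init,
                                 random_state=random_state).fit(m)
        except ValueError:
            warnings.warn(f"mixture with {k} components failed to fit; "
                          "using fewer", stacklevel=2)
            break
        bics[k] = gm.bic(m)
        models[k] = gm
    best = min(bics, key=bics.get)
    gm = models[best]
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        n_components=best,
        means=expit(gm.means_.ravel()[order]),
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
        bic=bics, model=gm)


def differential_methylation(beta: pd.DataFrame, groups: pd.Series,
                             p_max: float = 0.05,
                             effect_min: float = 0.1) -> pd.DataFrame:
    """Two-group differential methylation per row.

    Wilcoxon rank-sum test with BH adjustment across rows; effect size is
    the difference of group mean betas (second group minus first, i.e.
    cancer minus normal when groups are ordered that way); called iff
    adj p < p_max and |effect| > effect_min; positive effect => Hyper.
    """
    groups = groups.loc[beta.columns]
    levels = list(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError("differential methylation requires two groups")
    a_mask = (groups == levels[0]).to_numpy()
    b_mask = (groups == levels[1]).to_numpy()
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("need at least 3 samples per group")
    effects, pvals = [], []
    arr = beta.to_numpy(dtype=float)
    for row in arr:
        a, b = row[a_mask], row[b_mask]
        effects.append(b.mean() - a.mean())
        if np.ptp(row) == 0:  # all tied
            pvals.append(1.0)
        else:
            pvals.append(stats.ranksums(b, a).pvalue)
    adj = bh_adjust(np.asarray(pvals))
    effects = np.asarray(effects)
    out = pd.DataFrame({
        "effect_size": effects, "p": pvals, "adj_p": adj,
        "dm_type": np.where(effects > 0, "Hyper", "Hypo"),
        "called": (adj < p_max) & (np.abs(effects) > effect_min),
    }, index=beta.index)
    return out


def methylation_expression_correlation(beta: pd.Series, expression: pd.Series,
                                       r_max: float = -0.3,
                                       p_max: float = 0.001):
    """Pearson correlation of a gene-cluster's methylation against the
    gene's expression; driver iff r <= r_max and p < p_max.

    Returns (r, p, is_driver); zero-variance input yields (nan, nan, False).
    """
    common = beta.index.intersection(expression.index)
    b = beta.loc[common].to_numpy(dtype=float)
    e = expression.loc[common].to_numpy(dtype=float)
    if b.std() == 0 or e.std() == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(b, e)
    return float(r), float(p), bool(r <= r_max and p < p_max)


def methylation_salience_consensus(averep_calls: pd.DataFrame,
                                   mvalue_calls: pd.DataFrame,
                                   methylmix_calls: pd.DataFrame,
                                   *extra_calls: pd.DataFrame) -> pd.DataFrame:
    """Genes whose salient stage agrees across all three (or more)
    stage-informed routes.

    Each input is a salience table with columns (gene, stage, direction).
    Adding further agreeing call sets never removes a consensus gene.
    """
    tables = [averep_calls, mvalue_calls, methylmix_calls, *extra_calls]
    maps = [dict(zip(t["gene"], t["stage"])) for t in tables]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    rows = []
    base = tables[0].set_index("gene")
    for gene in sorted(common):
        stages = {m[gene] for m in maps}
        if len(stages) == 1:
            rows.append({"gene": gene, "stage": stages.pop(),
                         "direction": base.loc[gene, "direction"]})
    return pd.DataFrame(rows, columns=["gene", "stage", "direction"])


def methylation_stage_salience(beta: pd.DataFrame, probe_map: pd.DataFrame,
                               labels: pd.Series, lfc_min: float = 0.5,
                               p_max: float = 0.001,
                               contrast_p_max: float = 0.05,
                               n_top_per_stage: int = 50,
                               max_components: int = 3,
                               random_state: int = 0) -> dict:
    """Run the three stage-informed salience routes on a methylation layer.

    Routes: (a) "averep" — probe-averaged beta per gene; (b) "mvalue" —
    logit-transformed probe-averaged values; (c) "methylmix" — per-sample
    mixture-component posterior means fitted on the M-values. Each route
    feeds the same two-level contrast protocol (with methylation-scale
    thresholds), and the consensus keeps genes on whose salient stage all
    three routes agree.

    Returns {"averep": ..., "mvalue": ..., "methylmix": ..., "consensus": ...}.
    """
    genes = probe_map["gene"].unique()
    averep = pd.DataFrame(
        {g: beta.loc[probe_map.index[probe_map["gene"] == g]].mean(axis=0)
         for g in genes}).T
    averep.columns = beta.columns
    mvals = pd.DataFrame(
        logit(np.clip(averep.to_numpy(dtype=float), 1e-4, 1 - 1e-4)),
        index=averep.index, columns=averep.columns)
    mix_rows = {}
    for g in genes:
        fit = fit_beta_mixture(averep.loc[g].to_numpy(),
                               max_components=max_components,
                               random_state=random_state)
        m = logit(np.clip(averep.loc[g].to_numpy(dtype=float),
                          1e-4, 1 - 1e-4)).reshape(-1, 1)
        post = fit.model.predict_proba(m)
        mix_rows[g] = post @ fit.model.means_.ravel()
    methylmix = pd.DataFrame(mix_rows).T
    methylmix.columns = beta.columns

    kwargs = dict(lfc_min=lfc_min, p_max=p_max,
                  contrast_p_max=contrast_p_max,
                  n_top_per_stage=n_top_per_stage)
    calls = {
        "averep": call_stage_salient(averep, labels, **kwargs),
        "mvalue": call_stage_salient(mvals, labels, **kwargs),
        "methylmix": call_stage_salient(methylmix, labels, **kwargs),
    }
    calls["consensus"] = methylation_salience_consensus(
        calls["averep"], calls["mvalue"], calls["methylmix"])
    return calls


def methylation_temporal_concordance(meth_salient_stage: str,
                                     expr_extremum_stage: str,
                                     dm_type: str,
                                     expr_direction: str) -> bool:
    """Methylation-before-expression concordance.

    Concordant iff the methylation change can explain the expression
    change (Hyper with expression Down, or Hypo with expression Up) and
    the methylation salience is no later than the expression extremum
    (ties count as concordant).
    """
    direction_ok = ((dm_type == "Hyper" and expr_direction == "Down")
                    or (dm_type == "Hypo" and expr_direction == "Up"))
    if not direction_ok:
        return False
    return _STAGE_INDEX[meth_salient_stage] <= _STAGE_INDEX[expr_extremum_stage]
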