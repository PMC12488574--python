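"""End-to-end workflow: cohort -> contrasts -> panels -> models -> cascade.

Mirrors the full study design on a (synthetic or user-supplied) cohort:
variance filtering, per-problem stratified splitting, SMOTE balancing for
the metastasis problem, the stage-encoded and problem-specific contrasts,
Boruta/RFE consensus feature selection, nested model selection over the
six classifier families, and assembly of the cascade bundle (with the
histology agreement ensemble) evaluated on held-out samples.

Desk-scale defaults (``fast=True``) shrink selector iterations and model
grids so a full run on the default synthetic cohort stays in the minutes
range on one CPU; the workflow structure is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dge, selection
from .cascade import CascadeBundle, batch_predict
from .cohort import CohortConfig, generate_cohort
from .models import (AgreementEnsemble, ModelSpec, default_model_specs,
                     nested_select, tune_model)
from .preprocess import filter_low_variance, smote_balance, stratified_split

PROBLEM_LABELS = {"screen": "tissue", "metastasis": "metastasis",
                  "molsubtype": "molecular_subtype", "histology": "histology"}


@dataclass
class PipelineResult:
    panels: dict
    winners: dict
    reports: dict
    bundle: CascadeBundle
    readouts: pd.DataFrame
    summary: pd.Series
    salient: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _labels_for(ann: pd.DataFrame, problem: str) -> pd.Series:
    col = PROBLEM_LABELS[problem]
    if problem == "screen":
        return ann[col]
    labels = ann.loc[ann["tissue"] == "cancer", col]
    return labels.dropna()


def _matrix(expr: pd.DataFrame, genes, samples) -> np.ndarray:
    return expr.loc[list(genes), list(samples)].to_numpy(dtype=float).T


def run_pipeline(expr: pd.DataFrame | None = None,
                 ann: pd.DataFrame | None = None,
                 config: CohortConfig | None = None,
                 seed: int = 0, fast: bool = True,
                 sigma_min: float = 1.0,
                 boruta_iter: int = 20, boruta_trees: int = 50,
                 rfe_trees: int = 100, folds: int = 3) -> PipelineResult:
    """Run the full workflow and return panels, model reports and the
    cascade readouts on the held-out samples."""
    if expr is None or ann is None:
        config = config or CohortConfig(seed=seed)
        expr, ann, _ = generate_cohort(config)
    expr = filter_low_variance(expr, sigma_min=sigma_min)

    splits = {}
    for problem in PROBLEM_LABELS:
        labels = _labels_for(ann, problem)
        sub = ann.loc[labels.index].assign(_y=labels)
        splits[problem] = stratified_split(sub, "_y", 0.8, seed=seed)

    # stage contrasts on the screen training samples only
    train_ids, test_ids = splits["screen"]
    stage_labels = ann["stage_macro"].copy()
    stage_labels[ann["tissue"] == "normal"] = "control"
    stage_train = stage_labels.loc[train_ids].dropna()
    X_stage = expr[stage_train.index]
    fit = dge.fit_linear_model(X_stage, stage_train)
    adj_cols = [c for c in fit.columns if c.startswith("adj_p_")]
    linear_top = fit[adj_cols].min(axis=1).sort_values().index.tolist()
    salient = dge.call_stage_salient(X_stage, stage_train, result=fit)

    rng = np.random.RandomState(seed)
    panels, winners, reports, models, extras = {}, {}, {}, {}, {}
    for problem in PROBLEM_LABELS:
        tr_ids, te_ids = splits[problem]
        labels = _labels_for(ann, problem)
        y_tr = labels.loc[tr_ids].to_numpy()
        y_te = labels.loc[te_ids].to_numpy()

        contrast = None
        if problem != "screen":
            contrast = dge.group_contrast(expr[tr_ids], labels.loc[tr_ids])
        pool = selection.pool_base_features(
            problem, salient=salient, linear_top=linear_top,
            contrast=contrast)
        genes = [g for g in pool["gene"] if g in expr.index]
        X_tr = _matrix(expr, genes, tr_ids)

        if problem == "metastasis":
            X_bal, y_bal = smote_balance(X_tr, y_tr, seed=seed)
        else:
            X_bal, y_bal = X_tr, y_tr

        X_df = pd.DataFrame(X_bal, columns=genes)
        boruta = selection.boruta_select(
            X_df, y_bal, max_iter=boruta_iter, n_estimators=boruta_trees,
            seed=rng.randint(2 ** 31 - 1))
        from sklearn.ensemble import RandomForestClassifier
        sizes = sorted({2, 5, 10, min(20, len(genes)), len(genes)})
        rfe = selection.rfe_select(
            X_df, y_bal, subset_sizes=sizes, folds=folds,
            seed=rng.randint(2 ** 31 - 1),
            estimator=RandomForestClassifier(n_estimators=rfe_trees,
                                             random_state=seed))
        final_genes = selection.consensus_features(boruta, rfe)
        panels[problem] = final_genes

        X_fit = pd.DataFrame(X_bal, columns=genes)[final_genes].to_numpy()
        X_te = _matrix(expr, final_genes, te_ids)
        specs = default_model_specs(seed=seed, n_features=len(final_genes),
                                    fast=fast)
        winner, fitted, reps = nested_select(specs, X_fit, y_bal, X_te, y_te,
                                             folds=folds)
        winners[problem] = winner
        reports[problem] = reps
        models[problem] = fitted[winner]

        if problem == "histology":
            # agreement/abstain ensemble of the boosted trees + 1-layer net
            members = [fitted["xgboost"], fitted["nn_1layer"]]
            models["histology_ensemble"] = AgreementEnsemble(members)

    bundle = CascadeBundle(
        models={"screen": models["screen"],
                "metastasis": models["metastasis"],
                "subtype": models["molsubtype"],
                "histology": models["histology_ensemble"]},
        panels={"screen": panels["screen"],
                "metastasis": panels["metastasis"],
                "subtype": panels["molsubtype"],
                "histology": panels["histology"]})

    readout_ids = splits["screen"][1]
    readouts, summary = batch_predict(bundle, expr[readout_ids])
    return PipelineResult(panels=panels, winners=winners, reports=reports,
                          bundle=bundle, readouts=readouts, summary=summary,
                          salient=salient,
                          extras={"splits": splits, "linear_top": linear_top})
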