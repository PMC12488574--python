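"""Stage-encoded differential expression: closed-form coefficients, the
two-level contrast protocol, monotonic trends, contra-regulation, and
multiple-testing adjustment."""

import numpy as np
import pandas as pd
import pytest

import stagemark as sm
from stagemark.dge import STAGES, bh_adjust


def _labels(ann):
    labels = ann["stage_macro"].copy()
    labels[ann["tissue"] == "normal"] = "control"
    return labels.dropna()


# ---------------------------------------------------------------------------
# linear model coefficients

def test_unmoderated_coefficients_equal_group_mean_oracle(small_cohort):
    _, expr, ann, _ = small_cohort
    labels = _labels(ann)
    X = expr.iloc[:200][labels.index]
    fit = sm.fit_linear_model(X, labels, moderate=False)
    for stage in STAGES:
        direct = (X.loc[:, (labels == stage).to_numpy()].mean(axis=1)
                  - X.loc[:, (labels == "control").to_numpy()].mean(axis=1))
        assert np.allclose(fit[f"lfc_{stage}"], direct, atol=1e-10)


def test_reference_and_cell_means_codings_agree(small_cohort):
    _, expr, ann, _ = small_cohort
    labels = _labels(ann)
    X = expr.iloc[:50][labels.index]
    ref = sm.fit_linear_model(X, labels, sm.StageDesign("reference"))
    cm = sm.fit_linear_model(X, labels, sm.StageDesign("cell_means"))
    for stage in STAGES:
        assert np.allclose(ref[f"lfc_{stage}"],
                           cm[f"coef_{stage}"] - cm["coef_control"],
                           atol=1e-10)
    assert np.allclose(ref["intercept"], cm["coef_control"], atol=1e-10)


def test_identical_groups_give_null_coefficients():
    rng = np.random.default_rng(0)
    n = 40
    labels = pd.Series(["control"] * n + sum([[s] * n for s in STAGES], []),
                       index=[f"s{i}" for i in range(5 * n)])
    X = pd.DataFrame(rng.normal(5, 1, size=(30, 5 * n)),
                     columns=labels.index)
    fit = sm.fit_linear_model(X, labels)
    for stage in STAGES:
        assert np.abs(fit[f"lfc_{stage}"]).max() < 1.0
        assert fit[f"adj_p_{stage}"].median() > 0.2


def test_planted_gene_recovers_printed_scale_coefficient():
    # a NEK2-like cancer-wide gene with stage-I lfc 4.34
    planted = [sm.PlantedGene("NEK2like", "cancer_wide", 4.34, "up")]
    cfg = sm.CohortConfig(n_control=100, n_per_stage=(100, 50, 50, 30),
                          n_genes=1, planted_profiles=planted, seed=8)
    expr, ann, _ = sm.generate_cohort(cfg)
    labels = _labels(ann)
    fit = sm.fit_linear_model(expr[labels.index], labels)
    se = cfg.noise_sd * np.sqrt(1 / 100 + 1 / 100)
    assert fit["lfc_I"].iloc[0] == pytest.approx(4.34, abs=3 * se)


def test_small_group_contrast_skipped_with_warning():
    rng = np.random.default_rng(1)
    labels = pd.Series(["control"] * 10 + ["I"] * 10 + ["II"],
                       index=[f"s{i}" for i in range(21)])
    X = pd.DataFrame(rng.normal(size=(5, 21)), columns=labels.index)
    with pytest.warns(UserWarning, match="contrast skipped"):
        fit = sm.fit_linear_model(X, labels)
    assert "lfc_I" in fit.columns and "lfc_II" not in fit.columns


# ---------------------------------------------------------------------------
# BH adjustment

def test_bh_matches_direct_step_up_oracle():
    rng = np.random.default_rng(2)
    for _ in range(5):
        p = rng.uniform(size=200)
        # direct step-up: sort, scale by m/rank, enforce monotonicity
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# level-I stage-specific sets

def test_level1_thresholds_are_strict():
    result = pd.DataFrame({
        "lfc_I": [2.0, 2.01, -2.5, 3.0],
        "adj_p_I": [1e-6, 1e-6, 1e-6, 0.001],
    }, index=["boundary_lfc", "pass", "pass_down", "boundary_p"])
    sets = sm.level1_stage_specific(result)
    assert sets["I"] == {"pass", "pass_down"}
    assert sets["II"] == set()


def test_level1_recovers_planted_membership_and_addition():
    # disjointly planted per-stage exceedances: sizes must sum to the total
    rng = np.random.default_rng(3)
    sizes = {"I": 74, "II": 238, "III": 90, "IV": 525}
    rows = {}
    genes = []
    for stage, n in sizes.items():
        for j in range(n):
            genes.append(f"{stage}_{j}")
    for stage in STAGES:
        lfc = np.zeros(len(genes))
        p = np.ones(len(genes))
        for i, g in enumerate(genes):
            if g.startswith(stage + "_"):
                lfc[i] = rng.choice([-1, 1]) * rng.uniform(2.5, 6)
                p[i] = 1e-8
        rows[f"lfc_{stage}"] = lfc
        rows[f"adj_p_{stage}"] = p
    result = pd.DataFrame(rows, index=genes)
    sets = sm.level1_stage_specific(result)
    assert {s: len(v) for s, v in sets.items()} == sizes
    assert sum(len(v) for v in sets.values()) == 927
    for stage in STAGES:
        assert sets[stage] == {g for g in genes if g.startswith(stage + "_")}


def test_level1_empty_input_gives_empty_sets():
    sets = sm.level1_stage_specific(pd.DataFrame())
    assert all(v == set() for v in sets.values())


# ---------------------------------------------------------------------------
# stage salience

def test_salient_rule_reproduces_reference_calls():
    ref = sm.load_stage_salient_reference()
    for gene, row in ref.iterrows():
        call = sm.salient_stage_rule(
            row["control_mean"],
            [row["lfc_I"], row["lfc_II"], row["lfc_III"], row["lfc_IV"]])
        assert call == (row["stage"], row["status"]), gene


def test_salient_rule_tie_gives_no_call():
    assert sm.salient_stage_rule(0.0, [2.0, 2.0, 2.0, 2.0]) is None
    assert sm.salient_stage_rule(1.0, [3.0, -3.0, 1.0, 0.5]) is None


def test_regulation_status_reproduces_reference_labels():
    ref = sm.load_top_linear_reference()
    for gene, row in ref.iterrows():
        lfcs = [row["lfc_I"], row["lfc_II"], row["lfc_III"], row["lfc_IV"]]
        assert sm.regulation_status(lfcs) == row["status"], gene


def test_stage_salient_recovery_on_default_cohort(default_cohort):
    _, expr, ann, truth = default_cohort
    labels = _labels(ann)
    calls = sm.call_stage_salient(expr[labels.index], labels)
    planted = {t.gene_id: (t.stage, t.direction.capitalize())
               for t in truth if t.klass == "stage_salient"}
    called = {r.gene: (r.stage, r.direction) for r in calls.itertuples()}
    recall = np.mean([called.get(g) == sd for g, sd in planted.items()])
    assert recall >= 0.9
    nulls = {t.gene_id for t in truth if t.klass == "null"}
    false_calls = len(set(called) & nulls) / len(nulls)
    assert false_calls <= 0.05


# ---------------------------------------------------------------------------
# monotonic genes

def test_monotonic_strictness_on_constructed_means():
    rng = np.random.default_rng(4)
    n = 30
    labels = pd.Series(sum([[s] * n for s in STAGES], []),
                       index=[f"s{i}" for i in range(4 * n)])
    down = np.concatenate([np.full(n, m) for m in (5, 4, 3, 2)])
    flat = np.concatenate([np.full(n, m) for m in (5, 4, 4, 2)])
    X = pd.DataFrame([down + rng.normal(0, 1e-3, 4 * n), flat],
                     index=["down", "flat"], columns=labels.index)
    fits = sm.detect_monotonic(X, labels)
    assert list(fits["gene"]) == ["down"]
    assert fits.iloc[0]["status"] == "Down"
    assert fits.iloc[0]["slope"] < 0


def test_monotonic_recovery_and_slope_estimate():
    # planted |slope| 0.6/stage at noise sd 1, 100 samples per stage
    planted = [sm.PlantedGene(f"M{i}", "monotonic", 2.4,
                              "up" if i % 2 else "down") for i in range(10)]
    cfg = sm.CohortConfig(n_control=100, n_per_stage=(100,) * 4, n_genes=60,
                          planted_profiles=planted, seed=9)
    expr, ann, truth = sm.generate_cohort(cfg)
    labels = _labels(ann)
    fits = sm.detect_monotonic(expr[labels.index], labels)
    sig = fits[fits["adj_p"] < 0.05]
    recovered = set(sig["gene"]) & {t.gene_id for t in planted}
    assert len(recovered) >= 9  # >= 90% recall
    se = cfg.noise_sd / np.sqrt(100 * 5)  # ~SE of the ordinal slope
    for row in sig.itertuples():
        if row.gene.startswith("M"):
            true_slope = 0.6 if row.status == "Up" else -0.6
            assert row.slope == pytest.approx(true_slope, abs=3 * 3 * se)


# ---------------------------------------------------------------------------
# contra-regulation

def test_contra_monotone_profile_is_not_contra():
    assert sm.classify_contra_regulation([3, 4, 5, 6], 0.0) is None
    assert sm.classify_contra_regulation([-1, -2, -3, -4], 0.0) is None


@pytest.mark.parametrize("means,control,expected", [
    ([4.0, 2.0, 1.0, -1.5], 0.0, ("I", 1)),   # up at I, below control at IV
    ([1.5, 4.0, 1.0, -1.5], 0.0, ("II", 2)),
    ([1.0, 2.0, 4.0, -1.5], 0.0, ("III", 3)),
    ([-4.0, -2.0, -1.0, 1.5], 0.0, ("I", 4)),
    ([-1.5, -4.0, -1.0, 1.5], 0.0, ("II", 5)),
    ([-1.0, -2.0, -4.0, 1.5], 0.0, ("III", 6)),
])
def test_contra_pattern_templates(means, control, expected):
    assert sm.classify_contra_regulation(means, control) == expected


def test_contra_early_salient_decay_profile_flagged():
    # stage-I salient upregulation decaying below the baseline late
    call = sm.classify_contra_regulation([3.35, 2.85, 1.0, -0.4], 0.0)
    assert call == ("I", 1)


def test_contra_planted_patterns_recovered(default_cohort):
    _, expr, ann, truth = default_cohort
    labels = _labels(ann)
    stage_means = {s: expr.loc[:, (labels == s).reindex(expr.columns,
                                                        fill_value=False
                                                        ).to_numpy()].mean(axis=1)
                   for s in STAGES}
    control = expr.loc[:, (labels == "control").reindex(
        expr.columns, fill_value=False).to_numpy()].mean(axis=1)
    for t in truth:
        if t.klass != "contra":
            continue
        means = [stage_means[s].loc[t.gene_id] for s in STAGES]
        call = sm.classify_contra_regulation(means, control.loc[t.gene_id])
        assert call is not None and call[1] == t.pattern_id


# ---------------------------------------------------------------------------
# problem-specific contrasts

def test_ternary_contrast_produces_three_pairs():
    rng = np.random.default_rng(5)
    labels = pd.Series(["Luminal"] * 30 + ["HER2"] * 20 + ["TNBC"] * 25,
                       index=[f"s{i}" for i in range(75)])
    X = pd.DataFrame(rng.normal(size=(20, 75)), columns=labels.index)
    res = sm.group_contrast(X, labels)
    pairs = [c for c in res.columns if c.startswith("lfc_")]
    assert len(pairs) == 3
    assert res[pairs].abs().to_numpy().max() < 2  # identical distributions


def test_group_contrast_single_level_errors():
    labels = pd.Series(["a"] * 10, index=[f"s{i}" for i in range(10)])
    X = pd.DataFrame(np.zeros((3, 10)), columns=labels.index)
    with pytest.raises(ValueError):
        sm.group_contrast(X, labels)


def test_planted_histology_marker_passes_lfc_threshold(default_cohort):
    _, expr, ann, truth = default_cohort
    labels = ann.loc[ann["tissue"] == "cancer", "histology"]
    res = sm.group_contrast(expr[labels.index], labels)
    lfc_col = [c for c in res.columns if c.startswith("lfc_")][0]
    markers = [t.gene_id for t in truth if t.klass == "histology_marker"]
    assert (res.loc[markers, lfc_col].abs() > 2).all()
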