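"""Multi-omics late integration: miRNA direction/temporal concordance,
probe clustering, beta-mixture decomposition, differential methylation,
and the methylation-before-expression rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stagemark as sm
from stagemark.dge import STAGES


# ---------------------------------------------------------------------------
# direction and temporal rules

def test_expression_concordance_truth_table():
    # concordant iff directions are opposite
    for g, m in itertools.product(["Up", "Down"], repeat=2):
        assert sm.expression_concordance(g, m) == (g != m)


def test_expression_concordance_rejects_bad_direction():
    with pytest.raises(ValueError):
        sm.expression_concordance("Up", "sideways")


def test_temporal_concordance_all_stage_pairs():
    for i, mir_stage in enumerate(STAGES):
        for j, gene_stage in enumerate(STAGES):
            assert sm.temporal_concordance(mir_stage, gene_stage) == (i <= j)


def test_worked_pairs_from_the_reference_table():
    # DEPDC1 (Up, II) with a down-regulated stage-II regulator: doubly
    # concordant; CDH19 (Down, III) with a down-regulated regulator: not
    # expression-concordant, so temporal is never evaluated
    assert sm.expression_concordance("Up", "Down")
    assert sm.temporal_concordance("II", "II")
    assert not sm.expression_concordance("Down", "Down")


# ---------------------------------------------------------------------------
# target join

def _salience(rows):
    return pd.DataFrame(rows, columns=["gene", "stage", "direction"]) \
        .rename(columns={})[["gene", "stage", "direction"]]


def test_join_targets_empty_map_yields_orphans():
    genes = _salience([("FOXA1", "III", "Up")])
    mirs = _salience([("mir-1", "II", "Down")])
    records, orphan_genes, orphan_mirs = sm.join_targets(
        mirs, pd.DataFrame(columns=["mirna", "gene"]), genes)
    assert records.empty
    assert orphan_genes == ["FOXA1"] and orphan_mirs == ["mir-1"]


def test_join_targets_flags_and_na_propagation():
    genes = _salience([("gUp2", "II", "Up"), ("gDown4", "IV", "Down"),
                       ("lonely", "I", "Up")])
    mirs = _salience([("mir-early-down", "I", "Down"),
                      ("mir-late-up", "IV", "Up"),
                      ("mir-up", "II", "Up")])
    target_map = pd.DataFrame({
        "mirna": ["mir-early-down", "mir-late-up", "mir-up"],
        "gene": ["gUp2", "gDown4", "gUp2"]})
    records, orphan_genes, orphan_mirs = sm.join_targets(mirs, target_map,
                                                         genes)
    rec = records.set_index(["gene", "mirna"])
    # opposite directions, regulator at stage I <= gene stage II
    assert rec.loc[("gUp2", "mir-early-down"), "expression_concordant"]
    assert rec.loc[("gUp2", "mir-early-down"), "temporal_concordant"]
    # opposite directions but regulator later is still temporal-evaluable
    assert rec.loc[("gDown4", "mir-late-up"), "expression_concordant"]
    # same direction: temporal must be NA, not False
    assert not rec.loc[("gUp2", "mir-up"), "expression_concordant"]
    assert rec.loc[("gUp2", "mir-up"), "temporal_concordant"] is None
    assert orphan_genes == ["lonely"]
    assert orphan_mirs == []


def test_join_targets_planted_couplings_doubly_concordant(small_cohort):
    config, expr, ann, _ = small_cohort
    couplings = [sm.MiRnaCoupling("mir-a", "G0001", direction="down",
                                  salient_stage="I", coupling=1.0),
                 sm.MiRnaCoupling("mir-b", "G0002", direction="down",
                                  salient_stage="II", coupling=1.0)]
    genes = _salience([("G0001", "II", "Up"), ("G0002", "III", "Up")])
    mirs = _salience([("mir-a", "I", "Down"), ("mir-b", "II", "Down")])
    target_map = pd.DataFrame({"mirna": ["mir-a", "mir-b"],
                               "gene": ["G0001", "G0002"]})
    records, _, _ = sm.join_targets(mirs, target_map, genes)
    assert records["expression_concordant"].all()
    assert records["temporal_concordant"].all()


def test_join_targets_malformed_map_errors():
    with pytest.raises(ValueError, match="mirna"):
        sm.join_targets(_salience([]), pd.DataFrame({"x": []}), _salience([]))


# ---------------------------------------------------------------------------
# miRNA salience via the shared protocol

def test_planted_salient_mirna_recovered_and_null_layer_quiet(small_cohort):
    config, expr, ann, _ = small_cohort
    truth = sm.MultiOmicTruth(mirna_couplings=[
        sm.MiRnaCoupling("mir-sal", "G0001", direction="up",
                         salient_stage="II", effect_lfc=4.0, coupling=0.0)])
    mir = sm.generate_mirna_layer(truth, ann, config, expr)
    labels = ann["stage_macro"].copy()
    labels[ann["tissue"] == "normal"] = "control"
    calls = sm.mirna_stage_salience(mir[labels.dropna().index],
                                    labels.dropna())
    called = {r.gene: (r.stage, r.direction) for r in calls.itertuples()}
    assert called.get("mir-sal") == ("II", "Up")
    null_calls = [g for g in called if g.startswith("mir-null")]
    assert len(null_calls) / (config.n_mirna - 1) <= 0.05


# ---------------------------------------------------------------------------
# probe clustering

def test_single_probe_single_cluster():
    beta = pd.DataFrame([[0.1, 0.2, 0.3]], index=["cg1"])
    clusters = sm.cluster_probes(beta)
    assert clusters.tolist() == [1]


def test_two_correlated_one_anticorrelated_probe():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.2, 0.8, size=200)
    beta = pd.DataFrame({
        "cg1": base + rng.normal(0, 0.01, 200),
        "cg2": base + rng.normal(0, 0.01, 200),
        "cg3": 1 - base + rng.normal(0, 0.01, 200)}).T
    clusters = sm.cluster_probes(beta, r_min=0.7)
    assert clusters["cg1"] == clusters["cg2"]
    assert clusters["cg3"] != clusters["cg1"]
    assert clusters.nunique() == 2
    # exhaustive check at n=3: every within-cluster pair correlates > 0.7
    corr = np.corrcoef(beta.to_numpy())
    for a, b in itertools.combinations(range(3), 2):
        if clusters.iloc[a] == clusters.iloc[b]:
            assert corr[a, b] > 0.7


def test_planted_two_block_probe_structure():
    rng = np.random.default_rng(1)
    block1 = rng.uniform(0.1, 0.9, size=300)
    block2 = rng.uniform(0.1, 0.9, size=300)
    rows = {}
    for i in range(10):
        rows[f"cgA{i}"] = block1 + rng.normal(0, 0.02, 300)
    for i in range(8):
        rows[f"cgB{i}"] = block2 + rng.normal(0, 0.02, 300)
    clusters = sm.cluster_probes(pd.DataFrame(rows).T, r_min=0.7)
    assert clusters.nunique() == 2
    assert clusters[[f"cgA{i}" for i in range(10)]].nunique() == 1
    assert clusters[[f"cgB{i}" for i in range(8)]].nunique() == 1


# ---------------------------------------------------------------------------
# beta mixtures

def test_two_component_mixture_recovery():
    from scipy.special import expit, logit
    rng = np.random.default_rng(2)
    beta = expit(np.concatenate([rng.normal(logit(0.2), 0.4, 150),
                                 rng.normal(logit(0.7), 0.4, 150)]))
    fit = sm.fit_beta_mixture(beta)
    assert fit.n_components == 2
    assert np.allclose(fit.means, (0.2, 0.7), atol=0.05)
    assert fit.weights.sum() == pytest.approx(1.0)
    assert min(fit.bic, key=fit.bic.get) == 2


def test_single_tight_component():
    rng = np.random.default_rng(3)
    beta = np.clip(rng.normal(0.5, 0.03, 200), 0.01, 0.99)
    assert sm.fit_beta_mixture(beta).n_components == 1


def test_mixture_needs_enough_observations():
    with pytest.raises(ValueError):
        sm.fit_beta_mixture(np.linspace(0.1, 0.9, 10))


# ---------------------------------------------------------------------------
# differential methylation

def test_differential_methylation_worked_case_and_null():
    rng = np.random.default_rng(4)
    n = 120
    groups = pd.Series(["normal"] * 60 + ["cancer"] * 60,
                       index=[f"s{i}" for i in range(n)])
    hyper = np.concatenate([rng.normal(0.3, 0.05, 60),
                            rng.normal(0.673, 0.05, 60)])  # effect +0.373
    flat = rng.normal(0.5, 0.05, n)
    tied = np.full(n, 0.4)
    beta = pd.DataFrame([hyper, flat, tied],
                        index=["hyper", "flat", "tied"], columns=groups.index)
    res = sm.differential_methylation(beta, groups)
    assert res.loc["hyper", "called"]
    assert res.loc["hyper", "dm_type"] == "Hyper"
    assert res.loc["hyper", "effect_size"] == pytest.approx(0.373, abs=0.03)
    assert not res.loc["flat", "called"]
    assert res.loc["tied", "p"] == 1.0


def test_differential_methylation_null_type_one_rate():
    rng = np.random.default_rng(5)
    n = 60
    groups = pd.Series(["a"] * 30 + ["b"] * 30,
                       index=[f"s{i}" for i in range(n)])
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(200, n)),
                        columns=groups.index)
    res = sm.differential_methylation(beta, groups)
    assert (res["adj_p"] < 0.05).mean() <= 0.05


# ---------------------------------------------------------------------------
# methylation-expression coupling

def test_methylation_expression_driver_thresholds():
    rng = np.random.default_rng(6)
    n = 500
    expr = pd.Series(rng.normal(8, 2, n), index=[f"s{i}" for i in range(n)])
    noise = rng.normal(0, 1.0, n)
    beta = pd.Series(1 / (1 + np.exp(0.35 * (expr - 8) + noise)),
                     index=expr.index)
    r, p, driver = sm.methylation_expression_correlation(beta, expr)
    assert r < -0.3 and driver
    flat = pd.Series(rng.uniform(size=n), index=expr.index)
    r0, _, driver0 = sm.methylation_expression_correlation(flat, expr)
    assert not driver0
    const = pd.Series(np.full(n, 0.4), index=expr.index)
    r_na, p_na, drv = sm.methylation_expression_correlation(const, expr)
    assert np.isnan(r_na) and not drv


def test_planted_coupling_correlation_recovered(small_cohort):
    config, expr, ann, _ = small_cohort
    truth = sm.MultiOmicTruth(methylation_couplings=[
        sm.MethylationCoupling("G0005", n_probes=1, component_means=(0.5,),
                               component_sds=(0.2,), correlation_sign=-1,
                               coupling_strength=2.0, probe_sd=0.0)])
    beta, _ = sm.generate_methylation_layer(truth, ann, config, expr)
    r, p, driver = sm.methylation_expression_correlation(
        beta.iloc[0], expr.loc["G0005"])
    assert driver and r < -0.5


# ---------------------------------------------------------------------------
# three-route salience consensus

def _calls(rows):
    return pd.DataFrame(rows, columns=["gene", "stage", "direction"])


def test_consensus_identity_and_dissent():
    calls = _calls([("g1", "II", "Up"), ("g2", "IV", "Down")])
    out = sm.methylation_salience_consensus(calls, calls.copy(), calls.copy())
    assert set(out["gene"]) == {"g1", "g2"}
    dissent = _calls([("g1", "III", "Up"), ("g2", "IV", "Down")])
    out = sm.methylation_salience_consensus(calls, calls.copy(), dissent)
    assert set(out["gene"]) == {"g2"}


def test_consensus_monotone_in_agreeing_call_sets():
    calls = _calls([("g1", "II", "Up")])
    base = sm.methylation_salience_consensus(calls, calls.copy(), calls.copy())
    more = sm.methylation_salience_consensus(calls, calls.copy(), calls.copy(),
                                             calls.copy())
    assert set(base["gene"]) <= set(more["gene"])


def test_three_route_salience_recovers_planted_gene(small_cohort):
    config, expr, ann, _ = small_cohort
    truth = sm.MultiOmicTruth(methylation_couplings=[
        sm.MethylationCoupling("G0007", n_probes=3, component_means=(0.35,),
                               component_sds=(0.3,), salient_stage="III",
                               salient_effect=2.5),
        sm.MethylationCoupling("G0008", n_probes=3, component_means=(0.5,),
                               component_sds=(0.3,))])
    beta, probe_map = sm.generate_methylation_layer(truth, ann, config, expr)
    labels = ann["stage_macro"].copy()
    labels[ann["tissue"] == "normal"] = "control"
    labels = labels.dropna()
    calls = sm.methylation_stage_salience(beta[labels.index], probe_map,
                                          labels, lfc_min=0.1, p_max=0.01)
    for route in ("averep", "mvalue", "methylmix", "consensus"):
        called = dict(zip(calls[route]["gene"], calls[route]["stage"]))
        assert called.get("G0007") == "III", route
        assert "G0008" not in called, route


# ---------------------------------------------------------------------------
# methylation-before-expression concordance

@pytest.mark.parametrize("meth_stage,expr_stage,dm,direction,expected", [
    ("II", "IV", "Hyper", "Down", True),    # early hypermethylation, late
    ("IV", "IV", "Hyper", "Up", False),     # hyper with overexpression
    ("III", "III", "Hyper", "Up", False),   # hyper cannot explain Up
    ("I", "III", "Hypo", "Up", True),
    ("IV", "I", "Hyper", "Down", False),    # methylation too late
    ("III", "III", "Hypo", "Up", True),     # ties count as concordant
])
def test_methylation_temporal_concordance_rule(meth_stage, expr_stage, dm,
                                               direction, expected):
    assert sm.methylation_temporal_concordance(
        meth_stage, expr_stage, dm, direction) == expected
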