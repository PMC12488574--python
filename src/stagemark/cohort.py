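"""Synthetic multi-layer breast-cancer cohorts with known ground truth.

The generator emulates the structure of a stage-annotated bulk expression
cohort: healthy controls plus four AJCC macro stages, molecular-subtype and
histology label structure, severe metastasis class imbalance, planted
per-stage log-fold-change profiles, a miRNA layer whose planted regulators
are anti-correlated with their targets, and a methylation layer of per-gene
beta-value mixtures that may be negatively coupled to expression.

Expression noise is Gaussian on the log2 scale: every downstream consumer
works on variance-stabilized data, so the generator produces it directly.
All randomness fans out from a single seed into independent per-layer
substreams, so the three layers are individually and jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

STAGES = ("I", "II", "III", "IV")
SUBTYPES = ("Luminal", "HER2", "TNBC")
HISTOLOGIES = ("IDC", "ILC")

# raw AJCC sub-stage spellings per macro stage, sampled for stage_raw
_RAW_SUBSTAGES = {
    "I": ("1", "1A", "1B"),
    "II": ("2", "2A", "2B"),
    "III": ("3", "3A", "3B", "3C"),
    "IV": ("4",),
}

# stage profile (fraction of the planted effect per stage I..IV) for the six
# contra-regulation patterns: 1-3 up-anchored at stage I/II/III with a
# terminal drop below control, 4-6 the down-anchored mirrors.
CONTRA_TEMPLATES = {
    1: (1.0, 0.5, 0.1, -0.6),
    2: (0.5, 1.0, 0.2, -0.6),
    3: (0.3, 0.6, 1.0, -0.6),
    4: (-1.0, -0.5, -0.1, 0.6),
    5: (-0.5, -1.0, -0.2, 0.6),
    6: (-0.3, -0.6, -1.0, 0.6),
}

PLANT_CLASSES = ("null", "cancer_wide", "stage_salient", "monotonic",
                 "contra", "subtype_marker", "histology_marker",
                 "metastasis_marker")


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class PlantedGene:
    """Ground-truth annotation of one simulated gene.

    effect_lfc is the magnitude (log2 units, >= 0) of the planted effect;
    direction ("up"/"down") carries its sign. ``stage`` applies to
    stage_salient genes, ``pattern_id`` (1-6) to contra genes, ``subtype``
    to subtype markers.
    """
    gene_id: str
    klass: str = "null"
    effect_lfc: float = 0.0
    direction: str = "up"
    stage: str | None = None
    pattern_id: int | None = None
    subtype: str | None = None

    def __post_init__(self):
        if self.klass not in PLANT_CLASSES:
            raise ConfigurationError(f"unknown planted class {self.klass!r}")
        if self.effect_lfc < 0:
            raise ConfigurationError("effect_lfc must be >= 0")
        if self.klass == "contra" and self.pattern_id not in CONTRA_TEMPLATES:
            raise ConfigurationError("contra pattern_id must be in 1..6")
        if self.klass == "stage_salient" and self.stage not in STAGES:
            raise ConfigurationError("stage_salient requires stage in I..IV")

    @property
    def signed_effect(self) -> float:
        return self.effect_lfc if self.direction == "up" else -self.effect_lfc


@dataclass
class MiRnaCoupling:
    """A planted miRNA regulator and its mRNA target."""
    mirna_id: str
    target_gene: str
    direction: str = "up"          # regulator's own regulation status
    salient_stage: str = "II"
    effect_lfc: float = 3.0
    coupling: float = 1.0          # >0: anti-correlated with the target
    temporal_concordant: bool = True


@dataclass
class MethylationCoupling:
    """A planted per-gene methylation mixture, optionally coupled to
    expression (correlation_sign -1 => hypermethylation suppresses
    expression) and optionally stage-salient on the logit (M-value) scale."""
    gene: str
    n_probes: int = 3
    component_means: tuple = (0.2, 0.7)
    component_sds: tuple = (0.5, 0.5)          # logit-scale spread
    weights_normal: tuple | None = None
    weights_cancer: tuple | None = None
    correlation_sign: int = 0
    coupling_strength: float = 1.0
    salient_stage: str | None = None
    salient_effect: float = 0.0
    probe_sd: float = 0.15             # logit-scale probe-level noise

    def __post_init__(self):
        for m in self.component_means:
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError("beta component means must be in [0,1]")
        k = len(self.component_means)
        if self.weights_normal is None:
            self.weights_normal = tuple([1.0 / k] * k)
        if self.weights_cancer is None:
            self.weights_cancer = tuple(self.weights_normal)


@dataclass
class MultiOmicTruth:
    """Planted couplings for the miRNA and methylation layers."""
    mirna_couplings: list = field(default_factory=list)
    methylation_couplings: list = field(default_factory=list)


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the stage distribution of the reference cohort
    (112 controls; 181/616/249/20 samples in stages I-IV, so that an 80:20
    split leaves roughly 16 metastatic vs 837 non-metastatic training
    samples) and its subtype and histology fractions. ``metastatic_fraction``
    is derived (stage IV <=> metastatic); when supplied it is validated
    against the stage counts rather than used as an independent dial.
    """
    n_control: int = 112
    n_per_stage: tuple = (181, 616, 249, 20)
    n_genes: int = 1000
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 1.0
    planted_profiles: list | None = None
    subtype_fractions: tuple = (0.7886, 0.0515, 0.1599)   # Luminal, HER2, TNBC
    histology_fractions: tuple = (0.794, 0.206)           # IDC, ILC
    metastatic_fraction: float | None = None
    salient_background: float = 0.55   # off-stage fraction of a salient effect
    n_mirna: int = 150
    mirna_baseline_mean: float = 6.0
    n_probes_null: int = 0
    seed: int = 0

    def validate(self):
        if self.n_control < 0 or any(n < 0 for n in self.n_per_stage):
            raise ConfigurationError("sample counts must be >= 0")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        for name, frac in (("subtype_fractions", self.subtype_fractions),
                           ("histology_fractions", self.histology_fractions)):
            if abs(sum(frac) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        if self.metastatic_fraction is not None:
            n_cancer = sum(self.n_per_stage)
            if n_cancer and abs(self.metastatic_fraction
                                - self.n_per_stage[3] / n_cancer) > 1e-6:
                raise ConfigurationError(
                    "metastatic_fraction inconsistent with the stage-IV count "
                    "(metastatic <=> stage IV)")

    def rngs(self):
        """Independent substreams for the expression/miRNA/methylation
        layers and label assignment, all derived from the single seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return {name: np.random.default_rng(ss)
                for name, ss in zip(("labels", "expression", "mirna",
                                     "methylation"), children)}


def default_planted_profiles(effect_salient: float = 4.0,
                             effect_monotonic: float = 2.4,
                             effect_cancer_wide: float = 4.5,
                             effect_contra: float = 3.0,
                             effect_marker: float = 3.0) -> list[PlantedGene]:
    """Planted truth used by the default study conditions: stage-salient
    genes at the coefficient scale of the reference cohort (|lfc| ~ 2-5.7),
    monotonic genes with |slope| ~ 0.6 per stage, cancer-wide genes at the
    top-linear-model scale, one contra gene per pattern, and subtype /
    histology / metastasis markers."""
    planted: list[PlantedGene] = []
    i = 0

    def gid():
        nonlocal i
        i += 1
        return f"G{i:04d}"

    for stage in STAGES:
        for direction in ("up", "up", "down", "down"):
            planted.append(PlantedGene(gid(), "stage_salient",
                                       effect_salient, direction, stage=stage))
    for direction in ("up",) * 5 + ("down",) * 5:
        planted.append(PlantedGene(gid(), "monotonic", effect_monotonic,
                                   direction))
    for direction in ("up",) * 5 + ("down",) * 5:
        planted.append(PlantedGene(gid(), "cancer_wide", effect_cancer_wide,
                                   direction))
    for pattern in range(1, 7):
        planted.append(PlantedGene(gid(), "contra", effect_contra,
                                   "up" if pattern <= 3 else "down",
                                   pattern_id=pattern))
    for subtype in SUBTYPES:
        for _ in range(3):
            planted.append(PlantedGene(gid(), "subtype_marker", effect_marker,
                                       "up", subtype=subtype))
    for _ in range(5):
        planted.append(PlantedGene(gid(), "histology_marker", 2.5, "up"))
    for _ in range(5):
        planted.append(PlantedGene(gid(), "metastasis_marker", effect_marker,
                                   "up"))
    return planted


def _annotation(config: CohortConfig, rng) -> pd.DataFrame:
    rows = []
    for j in range(config.n_control):
        rows.append({"sample_id": f"N{j + 1:04d}", "tissue": "normal",
                     "stage_raw": None, "stage_macro": None,
                     "metastasis": None, "er": None, "pgr": None,
                     "her2": None, "ki67": None, "molecular_subtype": None,
                     "histology": None})
    n_cancer = sum(config.n_per_stage)
    subtypes = rng.choice(SUBTYPES, size=n_cancer, p=config.subtype_fractions)
    histologies = rng.choice(HISTOLOGIES, size=n_cancer,
                             p=config.histology_fractions)
    c = 0
    for stage, n in zip(STAGES, config.n_per_stage):
        for _ in range(n):
            subtype, hist = subtypes[c], histologies[c]
            if subtype == "TNBC":
                er = pgr = her2 = "-"
            elif subtype == "HER2":
                er = pgr = "-"
                her2 = "+"
            else:
                er = "+"
                pgr = rng.choice(["+", "-"])
                her2 = "-"
            rows.append({
                "sample_id": f"T{c + 1:04d}", "tissue": "cancer",
                "stage_raw": rng.choice(_RAW_SUBSTAGES[stage]),
                "stage_macro": stage,
                "metastasis": "metastatic" if stage == "IV" else "non_metastatic",
                "er": er, "pgr": pgr, "her2": her2, "ki67": None,
                "molecular_subtype": subtype, "histology": hist})
            c += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _stage_offsets(gene: PlantedGene, config: CohortConfig) -> np.ndarray:
    """Planted mean shift per group (control, I..IV), log2 units."""
    s = gene.signed_effect
    off = np.zeros(5)
    if gene.klass == "cancer_wide":
        off[1:] = s
    elif gene.klass == "stage_salient":
        k = STAGES.index(gene.stage)
        off[1:] = s * config.salient_background
        off[1 + k] = s
    elif gene.klass == "monotonic":
        off[1:] = s * np.arange(1, 5) / 4.0
    elif gene.klass == "contra":
        off[1:] = gene.effect_lfc * np.asarray(CONTRA_TEMPLATES[gene.pattern_id])
    return off


def generate_cohort(config: CohortConfig):
    """Generate the mRNA layer.

    Returns (expression, annotation, truth): a genes x samples log2
    expression DataFrame, the per-sample annotation table, and the list of
    PlantedGene records (one per gene, including nulls). Deterministic
    under a fixed config seed.
    """
    config.validate()
    rngs = config.rngs()
    ann = _annotation(config, rngs["labels"])
    planted = list(config.planted_profiles
                   if config.planted_profiles is not None
                   else default_planted_profiles())
    if len(planted) > config.n_genes:
        raise ConfigurationError("more planted profiles than genes")
    truth = planted + [PlantedGene(f"G{j + 1:04d}", "null")
                       for j in range(len(planted), config.n_genes)]

    rng = rngs["expression"]
    group_idx = np.zeros(len(ann), dtype=int)  # 0 control, 1..4 stages
    for k, stage in enumerate(STAGES):
        group_idx[(ann["stage_macro"] == stage).to_numpy()] = k + 1
    is_subtype = {s: (ann["molecular_subtype"] == s).to_numpy()
                  for s in SUBTYPES}
    is_ilc = (ann["histology"] == "ILC").to_numpy()
    is_met = (ann["metastasis"] == "metastatic").to_numpy()

    baselines = rng.normal(config.baseline_mean, config.baseline_sd,
                           size=config.n_genes)
    means = np.tile(baselines[:, None], (1, len(ann)))
    for g, gene in enumerate(truth):
        if gene.klass in ("cancer_wide", "stage_salient", "monotonic", "contra"):
            means[g] += _stage_offsets(gene, config)[group_idx]
        elif gene.klass == "subtype_marker":
            means[g, is_subtype[gene.subtype]] += gene.signed_effect
        elif gene.klass == "histology_marker":
            means[g, is_ilc] += gene.signed_effect
        elif gene.klass == "metastasis_marker":
            means[g, is_met] += gene.signed_effect
    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    expr = pd.DataFrame(values, index=[t.gene_id for t in truth],
                        columns=ann.index)
    return expr, ann, truth


class MappingError(KeyError):
    """A planted regulator references a gene absent from the mRNA layer."""


def generate_mirna_layer(truth: MultiOmicTruth, annotation: pd.DataFrame,
                         config: CohortConfig,
                         expression: pd.DataFrame) -> pd.DataFrame:
    """Generate the miRNA layer (log2 scale, miRNA x samples).

    Planted regulators carry their own stage-salient profile and an
    anti-correlation term against their target's expression residual, so a
    regulator coupled to a target shows negative sample-wise correlation at
    planted effect sizes. Couplings flagged temporally concordant are
    planted with a salience stage no later than the target's.
    """
    config.validate()
    rng = config.rngs()["mirna"]
    ann = annotation
    group_idx = np.zeros(len(ann), dtype=int)
    for k, stage in enumerate(STAGES):
        group_idx[(ann["stage_macro"] == stage).to_numpy()] = k + 1

    ids = []
    rows = []
    for coupling in truth.mirna_couplings:
        if coupling.target_gene not in expression.index:
            raise MappingError(
                f"regulator {coupling.mirna_id} targets unknown gene "
                f"{coupling.target_gene}")
        s = (coupling.effect_lfc if coupling.direction == "up"
             else -coupling.effect_lfc)
        k = STAGES.index(coupling.salient_stage)
        off = np.zeros(5)
        off[1:] = s * config.salient_background
        off[1 + k] = s
        base = config.mirna_baseline_mean + off[group_idx]
        target = expression.loc[coupling.target_gene].to_numpy(dtype=float)
        z = (target - target.mean()) / max(target.std(), 1e-12)
        vals = (base - coupling.coupling * z
                + rng.normal(0.0, config.noise_sd, size=len(ann)))
        ids.append(coupling.mirna_id)
        rows.append(vals)
    n_null = max(config.n_mirna - len(ids), 0)
    for j in range(n_null):
        ids.append(f"mir-null-{j + 1:03d}")
        rows.append(config.mirna_baseline_mean
                    + rng.normal(0.0, config.noise_sd, size=len(ann)))
    return pd.DataFrame(np.asarray(rows), index=ids, columns=ann.index)


def generate_methylation_layer(truth: MultiOmicTruth, annotation: pd.DataFrame,
                               config: CohortConfig,
                               expression: pd.DataFrame):
    """Generate the methylation layer.

    Returns (beta, probe_map): a probes x samples beta-value DataFrame in
    [0, 1] and a probe -> gene map. Per coupled gene, a per-sample latent
    M-value is drawn from the declared mixture (component weights may
    differ between normal and cancer samples, planting differential
    methylation), shifted by the optional stage-salient effect and by the
    expression-coupling term, then shared across that gene's probes with
    small independent probe noise before the logistic map back to beta.
    """
    config.validate()
    rng = config.rngs()["methylation"]
    ann = annotation
    is_cancer = (ann["tissue"] == "cancer").to_numpy()
    group_idx = np.zeros(len(ann), dtype=int)
    for k, stage in enumerate(STAGES):
        group_idx[(ann["stage_macro"] == stage).to_numpy()] = k + 1

    probe_ids, genes, rows = [], [], []
    p = 0
    for coupling in truth.methylation_couplings:
        k = len(coupling.component_means)
        comp = np.empty(len(ann), dtype=int)
        comp[~is_cancer] = rng.choice(k, size=(~is_cancer).sum(),
                                      p=coupling.weights_normal)
        comp[is_cancer] = rng.choice(k, size=is_cancer.sum(),
                                     p=coupling.weights_cancer)
        mu = logit(np.clip(np.asarray(coupling.component_means), 1e-4, 1 - 1e-4))
        sd = np.asarray(coupling.component_sds, dtype=float)
        m = mu[comp] + rng.normal(0.0, 1.0, size=len(ann)) * sd[comp]
        if coupling.salient_stage is not None:
            m[group_idx == STAGES.index(coupling.salient_stage) + 1] += \
                coupling.salient_effect
        if coupling.correlation_sign != 0:
            if coupling.gene not in expression.index:
                raise MappingError(f"methylation coupling references unknown "
                                   f"gene {coupling.gene}")
            e = expression.loc[coupling.gene].to_numpy(dtype=float)
            z = (e - e.mean()) / max(e.std(), 1e-12)
            m = m + coupling.correlation_sign * coupling.coupling_strength * z
        for _ in range(max(coupling.n_probes, 1)):
            p += 1
            probe_ids.append(f"cg{p:05d}")
            genes.append(coupling.gene)
            rows.append(expit(m + rng.normal(0.0, 1.0, size=len(ann))
                              * coupling.probe_sd))
    for j in range(config.n_probes_null):
        p += 1
        probe_ids.append(f"cg{p:05d}")
        genes.append(f"NULLGENE{j + 1:03d}")
        rows.append(expit(rng.normal(0.0, 1.0, size=len(ann))))
    beta = pd.DataFrame(np.asarray(rows) if rows else
                        np.empty((0, len(ann))),
                        index=probe_ids, columns=ann.index)
    probe_map = pd.DataFrame({"probe": probe_ids, "gene": genes}
                             ).set_index("probe")
    return beta, probe_map
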