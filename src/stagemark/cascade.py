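"""Cascade inference: screen first, then characterize predicted cancers.

A sample's expression vector is routed through a first-level cancer/normal
screen; only samples called "cancer" are passed to the three second-level
models (metastasis, molecular subtype, histology). Each prediction carries
its probability and a strong/weak confidence flag against a per-model
threshold, and the readout is composed into a clinical-style phrase such
as "Metastatic triple-negative ductal cancer". A histology-ensemble
abstention propagates as "ambiguous".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ABSTAIN, AgreementEnsemble

SUBTYPE_ADJECTIVE = {"TNBC": "triple-negative", "HER2": "HER2-positive",
                     "Luminal": "luminal"}
HISTOLOGY_NOUN = {"IDC": "ductal", "ILC": "lobular"}

DEFAULT_THRESHOLDS = {"screen": 0.90, "metastasis": 0.75,
                      "subtype": 0.70, "histology": 0.70}

LEVEL2 = ("metastasis", "subtype", "histology")


@dataclass
class CascadeBundle:
    """Fitted models, per-model feature panels, and confidence thresholds.

    ``models`` maps 'screen' / 'metastasis' / 'subtype' to fitted
    classifiers with predict_proba; 'histology' may be an
    :class:`AgreementEnsemble` (abstention-capable) or a plain classifier.
    ``panels`` maps the same keys to ordered gene lists; ``cancer_label``
    is the screen model's positive class.
    """
    models: dict
    panels: dict
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    cancer_label: str = "cancer"

    def __post_init__(self):
        for name, t in self.thresholds.items():
            if not 0.5 < t <= 1.0:
                raise ValueError(f"threshold for {name!r} must be in (0.5, 1]")


@dataclass
class CascadeReadout:
    """Per-sample cascade result. Second-level fields are None when the
    screen calls the sample normal."""
    sample_id: str
    screen_label: str
    screen_probability: float
    screen_confidence: str
    metastasis_label: str | None = None
    metastasis_probability: float | None = None
    metastasis_confidence: str | None = None
    subtype_label: str | None = None
    subtype_probability: float | None = None
    subtype_confidence: str | None = None
    histology_label: str | None = None
    histology_probability: float | None = None
    histology_confidence: str | None = None
    phrase: str = ""

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _predict_one(model, x: np.ndarray):
    """(label, probability) for a single feature vector."""
    if isinstance(model, AgreementEnsemble):
        decision = model.decide(x[None, :]).iloc[0]
        return decision["prediction"], decision["probability"]
    proba = model.predict_proba(x[None, :])[0]
    j = int(np.argmax(proba))
    return model.classes_[j], float(proba[j])


def _flag(prob: float, threshold: float) -> str:
    return "strong" if prob >= threshold else "weak"


def compose_phrase(metastasis, subtype, histology) -> str:
    met = {"metastatic": "Metastatic",
           "non_metastatic": "Non-metastatic"}.get(metastasis, "ambiguous")
    sub = SUBTYPE_ADJECTIVE.get(subtype, "ambiguous")
    hist = HISTOLOGY_NOUN.get(histology, "ambiguous")
    return f"{met} {sub} {hist} cancer"


def _extract(vector: pd.Series, panel) -> np.ndarray:
    missing = [g for g in panel if g not in vector.index]
    if missing:
        raise KeyError(f"expression vector is missing panel gene(s): "
                       f"{', '.join(missing)}")
    return vector.loc[list(panel)].to_numpy(dtype=float)


def predict_sample(bundle: CascadeBundle, vector: pd.Series,
                   sample_id: str = "sample") -> CascadeReadout:
    """Route one expression vector (log2 scale, indexed by gene) through
    the cascade."""
    if float(np.nanmax(vector.to_numpy(dtype=float))) > 30:
        warnings.warn("expression vector looks unlogged (max > 30); the "
                      "cascade expects log2-scale input", stacklevel=2)
    label, prob = _predict_one(bundle.models["screen"],
                               _extract(vector, bundle.panels["screen"]))
    readout = CascadeReadout(
        sample_id=sample_id, screen_label=str(label),
        screen_probability=prob,
        screen_confidence=_flag(prob, bundle.thresholds["screen"]))
    if str(label) != bundle.cancer_label:
        readout.phrase = "Normal breast tissue"
        return readout
    results = {}
    for name in LEVEL2:
        lab, p = _predict_one(bundle.models[name],
                              _extract(vector, bundle.panels[name]))
        conf = "abstain" if lab == ABSTAIN else _flag(p, bundle.thresholds[name])
        results[name] = (str(lab), p, conf)
    (readout.metastasis_label, readout.metastasis_probability,
     readout.metastasis_confidence) = results["metastasis"]
    (readout.subtype_label, readout.subtype_probability,
     readout.subtype_confidence) = results["subtype"]
    (readout.histology_label, readout.histology_probability,
     readout.histology_confidence) = results["histology"]
    readout.phrase = compose_phrase(readout.metastasis_label,
                                    readout.subtype_label,
                                    readout.histology_label)
    return readout


def batch_predict(bundle: CascadeBundle, X: pd.DataFrame):
    """Row-wise cascade over a genes x samples matrix.

    Returns (table, summary): one readout row per sample and the class
    counts over composed phrases. Per-sample failures (e.g. missing genes)
    are recorded as 'error' rows rather than aborting the batch.
    """
    rows = []
    for sample in X.columns:
        try:
            rows.append(predict_sample(bundle, X[sample], sample_id=sample)
                        .as_dict())
        except KeyError as exc:  # per-sample, non-fatal
            rows.append({"sample_id": sample, "screen_label": "error",
                         "phrase": str(exc)})
    if not rows:
        return (pd.DataFrame(columns=list(CascadeReadout.__dataclass_fields__)),
                pd.Series(dtype=int))
    table = pd.DataFrame(rows)
    return table, table["phrase"].value_counts()
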