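"""Tab-delimited readers/writers for matrices, annotation and truth tables."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .cohort import PlantedGene


def read_matrix(path) -> pd.DataFrame:
    """Gene (or probe) x sample matrix; first column is the feature id,
    header row carries sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(X: pd.DataFrame, path):
    X.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(ann: pd.DataFrame, path):
    ann.to_csv(path, sep="\t")


def write_truth(truth: list[PlantedGene], path):
    pd.DataFrame([asdict(t) for t in truth]).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[PlantedGene]:
    # keep_default_na: the class name "null" must survive as a string
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        d = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        if d.get("pattern_id") is not None:
            d["pattern_id"] = int(d["pattern_id"])
        out.append(PlantedGene(**d))
    return out


def write_cohort(out_dir, expression: pd.DataFrame, annotation: pd.DataFrame,
                 truth: list[PlantedGene]):
    """Write the mRNA layer of a simulated cohort to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(expression, out / "expression.tsv")
    write_annotation(annotation, out / "annotation.tsv")
    write_truth(truth, out / "truth.tsv")
    return out
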