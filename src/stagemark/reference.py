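"""Bundled reference tables from the TCGA BRCA stage-stratified analysis.

These are published coefficient estimates for breast invasive carcinoma,
bundled so that the stage-salience and regulation-status rules can be
exercised on real printed values (worked examples and regression tests)
without downloading any cohort data.

Coefficient convention: ``control_mean`` is the baseline (control) log2
expression; ``lfc_I`` .. ``lfc_IV`` are the stage-vs-control log2
fold-change deviations estimated from the stage-encoded linear model.
"""

from __future__ import annotations

import pandas as pd

# 24 stage-salient genes: control baseline, stagewise lfc, assigned salient
# stage, adjusted p from the inter-stage contrast / vs control, direction.
_STAGE_SALIENT_ROWS = [
    # gene, stage, b0, lfc_I, lfc_II, lfc_III, lfc_IV, p_contrast, p_control, status
    ("CHRNA6", "I", -1.67, 3.35, 2.85, 2.93, 2.21, 2.25e-52, 7.59e-51, "Up"),
    ("MMP10", "I", 0.04, 3.19, 2.76, 2.61, 1.68, 5.07e-23, 1.66e-24, "Up"),
    ("DEPDC1", "II", 2.01, 2.83, 3.32, 3.03, 2.43, 3.26e-92, 1.39e-89, "Up"),
    ("COX7A1", "II", 2.36, -2.31, -2.62, -2.30, -2.03, 3.15e-72, 4.39e-69, "Down"),
    ("KCNK15", "III", 1.99, 2.40, 1.85, 2.59, 1.72, 8.24e-21, 5.27e-20, "Up"),
    ("MFSD4", "III", 1.56, -2.06, -1.96, -2.32, -1.79, 4.51e-41, 2.88e-41, "Down"),
    ("CDH19", "III", -3.13, -2.60, -2.58, -3.19, -2.61, 3.31e-26, 1.53e-24, "Down"),
    ("CXCL5", "III", -2.03, -2.47, -2.17, -2.87, -2.83, 5.12e-24, 1.30e-22, "Down"),
    ("AKR7A3", "III", 3.26, 2.05, 1.52, 2.33, 2.12, 1.83e-13, 2.55e-12, "Up"),
    ("DEGS2", "III", 4.82, 2.60, 2.02, 2.69, 2.27, 9.30e-22, 1.68e-21, "Up"),
    ("CST2", "III", -0.60, 4.18, 3.57, 4.22, 3.52, 2.19e-48, 8.75e-52, "Up"),
    ("LOC100124692", "III", -2.52, -3.64, -3.60, -4.13, -3.83, 2.98e-46, 8.24e-48, "Down"),
    ("GDF5", "III", -1.26, -2.08, -2.31, -2.63, -2.24, 1.67e-26, 3.64e-26, "Down"),
    ("FOXA1", "III", 7.19, 2.09, 1.64, 2.32, 1.94, 4.81e-13, 1.30e-11, "Up"),
    ("EGR3", "IV", 4.14, -2.33, -2.71, -2.57, -4.04, 3.53e-18, 1.46e-44, "Down"),
    ("FOS", "IV", 7.27, -2.44, -3.07, -3.09, -4.19, 3.40e-21, 3.50e-62, "Down"),
    ("FOSB", "IV", 4.71, -3.80, -4.33, -4.30, -5.66, 9.16e-25, 4.51e-76, "Down"),
    ("DUSP1", "IV", 7.00, -2.13, -2.40, -2.23, -3.13, 2.51e-19, 1.81e-58, "Down"),
    ("FREM1", "IV", 0.85, -3.67, -4.13, -3.70, -5.09, 1.29e-23, 2.43e-77, "Down"),
    ("EGR1", "IV", 7.45, -2.72, -3.18, -3.11, -4.00, 3.63e-23, 2.23e-75, "Down"),
    ("HFM1", "IV", -3.44, -2.02, -2.24, -2.23, -3.02, 6.13e-18, 1.43e-52, "Down"),
    ("ABCA10", "IV", -0.28, -4.38, -4.80, -4.48, -5.67, 5.63e-33, 3.89e-115, "Down"),
    ("KLK5", "IV", 1.26, -3.21, -3.44, -3.44, -5.45, 6.93e-20, 2.41e-09, "Down"),
    ("KCNA1", "IV", -1.69, -2.58, -2.99, -2.81, -3.93, 3.08e-15, 1.99e-45, "Down"),
]

# Top ten genes of the stagewise linear model: stage lfc vs control,
# FDR-adjusted significance and regulation status.
_TOP_LINEAR_ROWS = [
    ("NEK2", 4.34, 4.83, 4.65, 4.82, 1.37e-188, "Up"),
    ("MMP11", 5.94, 5.75, 5.96, 6.43, 3.80e-173, "Up"),
    ("PKMYT1", 4.42, 4.83, 4.73, 4.90, 1.60e-172, "Up"),
    ("GPAM", -3.57, -3.68, -3.65, -3.85, 9.39e-171, "Down"),
    ("CPA1", -4.34, -4.56, -4.28, -4.21, 6.39e-170, "Down"),
    ("COL10A1", 7.04, 6.74, 6.95, 7.22, 3.43e-169, "Up"),
    ("MYOC", -6.06, -6.55, -6.34, -7.17, 1.06e-166, "Down"),
    ("KIF4A", 4.05, 4.54, 4.33, 4.55, 1.61e-164, "Up"),
    ("CA4", -6.63, -7.35, -6.91, -7.11, 2.01e-162, "Down"),
    ("LYVE1", -4.76, -5.19, -4.90, -4.91, 5.79e-159, "Down"),
]

STAGES = ("I", "II", "III", "IV")


def load_stage_salient_reference() -> pd.DataFrame:
    """Reference table of the 24 stage-salient genes (indexed by gene)."""
    df = pd.DataFrame(
        _STAGE_SALIENT_ROWS,
        columns=[
            "gene", "stage", "control_mean",
            "lfc_I", "lfc_II", "lfc_III", "lfc_IV",
            "adj_p_contrast", "adj_p_control", "status",
        ],
    )
    return df.set_index("gene")


def load_top_linear_reference() -> pd.DataFrame:
    """Reference table of the top 10 stagewise linear-model genes."""
    df = pd.DataFrame(
        _TOP_LINEAR_ROWS,
        columns=["gene", "lfc_I", "lfc_II", "lfc_III", "lfc_IV", "adj_p", "status"],
    )
    return df.set_index("gene")


def stage_salient_gene_list() -> list[str]:
    return [row[0] for row in _STAGE_SALIENT_ROWS]


def top_linear_gene_list() -> list[str]:
    return [row[0] for row in _TOP_LINEAR_ROWS]
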