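import numpy as np
import pandas as pd
import pytest

import stagemark as sm


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (same structure, smaller sizes) reused across
    modules where only structure, not power, matters."""
    config = sm.CohortConfig(
        n_control=40, n_per_stage=(40, 60, 40, 20), n_genes=200, seed=11)
    expr, ann, truth = sm.generate_cohort(config)
    return config, expr, ann, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions (full sample sizes); session-scoped
    because several recovery tests share it."""
    config = sm.CohortConfig(seed=3)
    expr, ann, truth = sm.generate_cohort(config)
    return config, expr, ann, truth


@pytest.fixture()
def stage_labels():
    def _make(ann):
        labels = ann["stage_macro"].copy()
        labels[ann["tissue"] == "normal"] = "control"
        return labels.dropna()
    return _make
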