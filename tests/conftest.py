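import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from depsel import (
    FeatureKind,
    FeatureMatrix,
    Measure,
    PanelMetadata,
    ScoreMatrix,
    SyntheticPanelConfig,
    simulate_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """The study-condition panel: 500 reference + 4 group lines, 1000 genes."""
    return simulate_panel(SyntheticPanelConfig(seed=11))


@pytest.fixture(scope="session")
def small_panel():
    """A scaled-down panel for fast structural tests."""
    return simulate_panel(
        SyntheticPanelConfig(
            n_reference=60,
            n_group=4,
            n_genes=300,
            n_common_essential=15,
            n_group_selective=8,
            n_reference_selective=3,
            n_chrom=3,
            n_lineages=10,
            n_background_mutation_features=20,
            seed=5,
        )
    )


@pytest.fixture()
def tiny_scores():
    """5 group + 6 reference lines over 4 hand-set genes."""
    rng = np.random.default_rng(3)
    lines = [f"g{i}" for i in range(5)] + [f"r{i}" for i in range(6)]
    vals = pd.DataFrame(
        rng.normal(size=(11, 4)),
        index=lines,
        columns=["A", "B", "C", "D"],
    )
    meta = PanelMetadata(
        pd.DataFrame(
            {
                "group_flag": [True] * 5 + [False] * 6,
                "lineage": ["grp"] * 5 + ["lin1"] * 3 + ["lin2"] * 3,
            },
            index=pd.Index(lines),
        )
    )
    return ScoreMatrix(vals, Measure.gene_effect), meta
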