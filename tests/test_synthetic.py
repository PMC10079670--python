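"""The synthetic panel generator: bookkeeping, determinism and planted structure."""

import numpy as np
import pandas as pd
import pytest

from depsel import (
    SyntheticPanelConfig,
    evaluate_recovery,
    simulate_panel,
)
from depsel.iodata import write_score_matrix


def test_dimensions_and_truth_bookkeeping(small_panel):
    cfg = small_panel.config
    n_lines = cfg.n_reference + cfg.n_group
    assert small_panel.gene_effect.values.shape == (n_lines, cfg.n_genes)
    assert small_panel.dependency_probability.values.shape == (n_lines, cfg.n_genes)
    assert len(small_panel.truth.group_selective) == cfg.n_group_selective
    assert len(small_panel.truth.reference_selective) == cfg.n_reference_selective
    assert len(small_panel.truth.common_essential) == cfg.n_common_essential
    assert len(small_panel.truth.isg_genes) == 38
    # truth tables reference existing genes only
    universe = set(small_panel.gene_effect.values.columns)
    for genes in (
        small_panel.truth.group_selective,
        small_panel.truth.isg_genes,
        small_panel.truth.window_anchor["block_genes"],
    ):
        assert set(genes) <= universe


def test_probability_is_monotone_transform_in_range(small_panel):
    prob = small_panel.dependency_probability.values.to_numpy()
    assert prob.min() >= 0 and prob.max() <= 1
    eff = small_panel.gene_effect.values.to_numpy().ravel()
    p = prob.ravel()
    # strong negative association between effect and probability overall
    assert np.corrcoef(eff, p)[0, 1] < -0.9


def test_group_selective_effect_mean_within_sampling_bound(default_panel):
    cfg = default_panel.config
    eff = default_panel.gene_effect.values
    group = eff.loc[default_panel.metadata.group_lines]
    bound = 3 * cfg.noise_sd / np.sqrt(cfg.n_group)
    for g in default_panel.truth.group_selective:
        if g == default_panel.truth.window_anchor["dependency_gene"]:
            continue  # carries the planted copy-number coupling on top
        assert abs(group[g].mean() - cfg.group_effect) < bound


def test_same_seed_is_byte_identical(tmp_path):
    cfg = dict(n_reference=30, n_genes=120, n_common_essential=6,
               n_group_selective=4, n_reference_selective=2, seed=3)
    p1 = simulate_panel(SyntheticPanelConfig(**cfg))
    p2 = simulate_panel(SyntheticPanelConfig(**cfg))
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_score_matrix(p1.gene_effect, a)
    write_score_matrix(p2.gene_effect, b)
    assert a.read_bytes() == b.read_bytes()
    pd.testing.assert_frame_equal(
        p1.dependency_probability.values, p2.dependency_probability.values
    )


def test_different_seed_changes_draws():
    base = dict(n_reference=30, n_genes=120, n_common_essential=6,
                n_group_selective=4, n_reference_selective=2)
    p1 = simulate_panel(SyntheticPanelConfig(seed=3, **base))
    p2 = simulate_panel(SyntheticPanelConfig(seed=4, **base))
    assert not np.allclose(
        p1.gene_effect.values.to_numpy(), p2.gene_effect.values.to_numpy()
    )


def test_neutral_mean_difference_vanishes_with_noise():
    base = dict(n_reference=40, n_genes=150, n_common_essential=5,
                n_group_selective=4, n_reference_selective=2, seed=6)
    diffs = []
    for sd in (0.5, 0.05):
        p = simulate_panel(SyntheticPanelConfig(noise_sd=sd, **base))
        eff = p.gene_effect.values
        grp = eff.loc[p.metadata.group_lines]
        ref = eff.loc[p.metadata.reference_lines]
        neutral = [
            g for g in p.truth.neutral
            if g != p.truth.window_anchor["dependency_gene"]
            and g not in set(p.truth.biomarkers["dependency_gene"])
        ]
        diffs.append(np.abs(grp[neutral].mean() - ref[neutral].mean()).mean())
    assert diffs[1] < diffs[0] / 3


def test_copy_number_spatial_autocorrelation(default_panel):
    cn = default_panel.copy_number.values
    coords = default_panel.coords.table
    genes = [
        g for g in coords.index
        if coords.loc[g, "chromosome"] == "chr1"
    ][:100]
    adjacent = [
        np.corrcoef(cn[genes[i]], cn[genes[i + 1]])[0, 1] for i in range(0, 60, 3)
    ]
    rng = np.random.default_rng(0)
    random_pairs = []
    all_genes = list(cn.columns)
    for _ in range(20):
        a, b = rng.choice(len(all_genes), 2, replace=False)
        random_pairs.append(np.corrcoef(cn[all_genes[a]], cn[all_genes[b]])[0, 1])
    assert np.mean(adjacent) > np.mean(random_pairs) + 0.2


def test_isg_expression_elevated_in_group(small_panel):
    expr = small_panel.expression.values
    isg = small_panel.truth.isg_genes
    grp = expr.loc[small_panel.metadata.group_lines, isg].mean().mean()
    ref = expr.loc[small_panel.metadata.reference_lines, isg].mean().mean()
    assert grp > ref


def test_evaluate_recovery_arithmetic():
    truth_genes = [f"S{i}" for i in range(20)]
    neutral = [f"N{i}" for i in range(50)]
    from depsel.synthetic_data import TruthTables

    truth = TruthTables(
        group_selective=truth_genes,
        reference_selective=[],
        common_essential=[],
        neutral=neutral,
        biomarkers=pd.DataFrame(),
        window_anchor={},
        isg_genes=[],
    )
    # 18 of 20 recovered, one neutral false positive
    status = {g: "group_selective" for g in truth_genes[:18]}
    status[neutral[0]] = "group_selective"
    calls = pd.DataFrame(
        {
            "relaxed_status": [
                status.get(g, "not_selective") for g in truth_genes + neutral
            ]
        },
        index=truth_genes + neutral,
    )
    out = evaluate_recovery(calls, truth)
    assert out["sensitivity"] == pytest.approx(0.9)
    assert out["precision"] == pytest.approx(18 / 19)
    assert out["fp_neutral"] == 1
    assert out["tn_neutral"] == 49
    # exact agreement and empty calls
    perfect = calls.copy()
    perfect["relaxed_status"] = [
        "group_selective" if g in truth_genes else "not_selective"
        for g in perfect.index
    ]
    assert evaluate_recovery(perfect, truth)["precision"] == 1.0
    empty = calls.copy()
    empty["relaxed_status"] = "not_selective"
    out_e = evaluate_recovery(empty, truth)
    assert out_e["sensitivity"] == 0.0 and out_e["specificity"] == 1.0
    # universe mismatch
    with pytest.raises(ValueError, match="universe"):
        evaluate_recovery(calls.iloc[:5], truth)


def test_inconsistent_class_counts_rejected():
    with pytest.raises(ValueError, match="exceed"):
        SyntheticPanelConfig(n_genes=50, n_common_essential=40, n_group_selective=20)
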