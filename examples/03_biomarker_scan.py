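"""Scan genomic features for biomarkers of one dependency.

Correlates a dependency gene's gene-effect profile with every copy-number
feature (pairwise-complete Pearson r plus a univariate regression per
feature) and shows that the planted paralog-loss biomarker ranks at the
top.
"""

from depsel import (
    SyntheticPanelConfig,
    dependency_feature_correlations,
    simulate_panel,
)

panel = simulate_panel(SyntheticPanelConfig(seed=7))
bm = panel.truth.biomarkers.query("feature_kind == 'copy_number'").iloc[0]
dep = bm["dependency_gene"]

scan = dependency_feature_correlations(
    panel.gene_effect.values[dep], panel.copy_number
)
print(f"top copy-number correlates of the {dep} dependency:")
print(scan[["r", "slope", "p_reg", "n_obs"]].head(5))
rank = list(scan.index).index(bm["feature_id"]) + 1
print(f"\nplanted paralog partner {bm['feature_id']} ranks #{rank}")
# Positive r means lower copy number tracks a more negative gene effect
# (stronger dependency) - the paralog-loss / CYCLOPS signature.
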