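"""Co-essentiality networks and confidence-filtered interaction networks.

Genes that act together tend to show correlated essentiality across a large
cell-line panel. Here gene pairs are connected when the Pearson correlation
of their dependency-probability profiles across the panel reaches a
threshold (default 0.18, inclusive). Known protein-protein interactions are
handled analogously: edges from a local interaction table are kept at
confidence >= 0.4 and the subgraph induced on the gene list is returned,
with unconnected genes retained as isolated nodes.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .iodata import InteractionTable, ScoreMatrix

log = logging.getLogger("depsel")

__all__ = ["profile_correlations", "build_network", "filter_interaction_edges"]


def profile_correlations(
    matrix: ScoreMatrix, genes: Sequence[str], min_pair_obs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between gene score profiles.

    Returns ``(r, n_obs)``: symmetric DataFrames over ``genes``. A pair with
    fewer than ``min_pair_obs`` complete observations, or with a constant
    profile on the complete index, gets NaN (constant profiles are logged).
    Diagonal is 1 where the gene has any observations.
    """
    missing = [g for g in genes if g not in matrix.values.columns]
    if missing:
        raise KeyError(f"genes absent from score matrix: {missing[:5]}")
    sub = matrix.values[list(genes)]
    k = len(genes)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    arr = sub.to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0 if np.isfinite(arr[:, i]).any() else np.nan
        n[i, i] = int(np.isfinite(arr[:, i]).sum())
    for i, j in itertools.combinations(range(k), 2):
        both = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
        nij = int(both.sum())
        n[i, j] = n[j, i] = nij
        if nij < min_pair_obs:
            continue
        x, y = arr[both, i], arr[both, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            const = genes[i] if np.ptp(x) == 0 else genes[j]
            log.warning("constant profile for gene %s over pair index; r missing", const)
            continue
        r[i, j] = r[j, i] = float(np.corrcoef(x, y)[0, 1])
    idx = pd.Index(genes)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def build_network(
    correlations: pd.DataFrame,
    threshold: float = 0.18,
    node_scores: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Threshold a correlation table into an undirected co-essentiality graph.

    Edge iff r >= threshold (inclusive); edge attribute ``weight`` = r. All
    genes appear as nodes, so singletons are the isolated nodes; graph
    attributes carry ``threshold``, ``components`` (lists of members of each
    connected component with >=2 genes) and ``singletons``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    g = nx.Graph(threshold=float(threshold))
    genes = list(correlations.index)
    for gene in genes:
        score = None if node_scores is None else node_scores.get(gene)
        g.add_node(gene, score=score)
    for a, b in itertools.combinations(genes, 2):
        r = correlations.loc[a, b]
        if np.isfinite(r) and r >= threshold:
            g.add_edge(a, b, weight=float(r))
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    g.graph["components"] = sorted(comps)
    g.graph["singletons"] = sorted(x for x in g.nodes if g.degree(x) == 0)
    return g


def filter_interaction_edges(
    table: InteractionTable,
    genes: Sequence[str],
    min_conf: float = 0.4,
    node_scores: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Induced interaction subgraph on ``genes`` at confidence >= min_conf.

    Edges touching genes outside the list are dropped (count logged). Genes
    without a surviving edge remain as isolated nodes, mirroring the manual
    re-adding of singletons in the published network figure.
    """
    gene_set = set(genes)
    g = nx.Graph(threshold=float(min_conf))
    for gene in genes:
        score = None if node_scores is None else node_scores.get(gene)
        g.add_node(gene, score=score)
    n_unknown = 0
    for _, row in table.edges.iterrows():
        a, b, conf = row["gene_a"], row["gene_b"], float(row["confidence"])
        if a not in gene_set or b not in gene_set:
            n_unknown += 1
            continue
        if conf >= min_conf:
            g.add_edge(a, b, weight=conf)
    if n_unknown:
        log.info("dropped %d edge(s) touching genes outside the list", n_unknown)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    g.graph["components"] = sorted(comps)
    g.graph["singletons"] = sorted(x for x in g.nodes if g.degree(x) == 0)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Serialize a network as a TSV edge list (gene_a, gene_b, weight)."""
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d.get("weight")}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
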