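"""Enrichment statistics: ES running sum, permutation null, hypergeometric,
network list enrichment and the list-size-normalized AUC."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from depsel import (
    GeneSetCollection,
    RankedList,
    gsea_permutation,
    hypergeom_overlap_test,
    listsize_auc,
    network_list_enrichment,
    preranked_enrichment_score,
)

from oracles import es_oracle, hypergeom_tail_oracle


def test_lone_hit_at_top_and_bottom():
    rl = RankedList(list("ABCD"), [3, 2, 1, 0.5])
    top = preranked_enrichment_score(rl, {"A"})
    assert top["ES"] == pytest.approx(1.0)
    assert top["leading_edge"] == ["A"]
    bottom = preranked_enrichment_score(rl, {"D"})
    assert bottom["ES"] == pytest.approx(-1.0)
    assert bottom["leading_edge"] == ["D"]


def test_first_k_equal_metrics_reach_full_deviation():
    rl = RankedList(list("ABCDEF"), [1, 1, 1, 0.9, 0.8, 0.7])
    res = preranked_enrichment_score(rl, {"A", "B", "C"})
    assert res["ES"] == pytest.approx(1.0)


def test_es_matches_exhaustive_enumeration_for_all_subsets():
    rng = np.random.default_rng(0)
    for n in (4, 7, 10):
        metric = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        rl = RankedList(genes, metric)
        for k in range(1, n):
            for subset in itertools.combinations(range(n), k):
                hits = [i in subset for i in range(n)]
                expected = es_oracle(list(rl.metric), hits)
                got = preranked_enrichment_score(rl, {genes[i] for i in subset})["ES"]
                if abs(abs(got) - abs(expected)) < 1e-9 and np.sign(got) != np.sign(
                    expected
                ):
                    # positive/negative deviations tied to within rounding;
                    # the reported sign is then arbitrary
                    continue
                assert got == pytest.approx(expected, abs=1e-12), (n, subset)


def test_es_input_validation():
    rl = RankedList(list("ABC"), [3, 2, 1])
    with pytest.raises(ValueError):
        preranked_enrichment_score(rl, {"Z"})
    with pytest.raises(ValueError):
        preranked_enrichment_score(rl, {"A", "B", "C"})


def test_permutation_p_floor_and_determinism():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(1000)]
    rl = RankedList(genes, np.linspace(3, 0.01, 1000))
    sets = GeneSetCollection({"top": set(genes[:10])})
    res1 = gsea_permutation(rl, sets, n_perm=1000, seed=42)[0]
    assert res1.p_perm == pytest.approx(1 / 1001)
    assert res1.es == pytest.approx(1.0)
    res2 = gsea_permutation(rl, sets, n_perm=1000, seed=42)[0]
    assert (res1.es, res1.nes, res1.p_perm) == (res2.es, res2.nes, res2.p_perm)
    assert res1.nes is not None and np.sign(res1.nes) == np.sign(res1.es)


def test_permutation_null_is_uniform():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(500)]
    rl = RankedList(genes, rng.normal(size=500))
    sets = GeneSetCollection(
        {f"s{i}": set(rng.choice(genes, 15, replace=False)) for i in range(100)}
    )
    res = gsea_permutation(rl, sets, n_perm=500, seed=3)
    p = [r.p_perm for r in res]
    assert stats.kstest(p, "uniform").statistic < 0.12


def test_hypergeom_matches_enumeration():
    universe = {f"u{i}" for i in range(10)}
    gene_set = set(list(universe)[:3])
    gene_list = set(list(universe)[1:4])  # overlap k = 2
    out = hypergeom_overlap_test(gene_list, gene_set, universe)
    assert out["k"] == 2
    assert out["p"] == pytest.approx(22 / 120)
    assert out["p"] == pytest.approx(hypergeom_tail_oracle(10, 3, 3, 2))
    # k = 0: tail includes everything
    disjoint = set(list(universe)[4:7])
    assert hypergeom_overlap_test(disjoint, gene_set, universe)["p"] == pytest.approx(
        hypergeom_tail_oracle(10, 3, 3, 0)
    )
    with pytest.raises(ValueError):
        hypergeom_overlap_test({"u0"}, gene_set, set())


def test_network_enrichment_star_graph_matches_brute_force():
    g = nx.star_graph(10)  # hub 0, leaves 1..10
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    leaves = [f"n{i}" for i in range(1, 11)]
    gene_set = {"n0"}
    gene_list = set(leaves[:3])
    out = network_list_enrichment(gene_list, gene_set, g, n_perm=2000, seed=0)
    assert out["statistic"] == 3
    # all nodes share one degree decile except the hub; a random 3-list from
    # the leaf stratum always touches the hub 3 times unless it includes n0
    assert 0 < out["p"] <= 1
    out2 = network_list_enrichment(gene_list, gene_set, g, n_perm=2000, seed=0)
    assert out == out2  # determinism


def test_network_enrichment_disjoint_components():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("c", "d")])
    out = network_list_enrichment({"a", "b"}, {"c", "d"}, g, n_perm=200, seed=1)
    assert out["statistic"] == 0
    assert out["p"] > 0.5


def test_network_enrichment_null_calibration():
    rng = np.random.default_rng(5)
    g = nx.gnm_random_graph(150, 600, seed=7)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    nodes = list(g.nodes)
    gene_set = set(rng.choice(nodes, 25, replace=False))
    pvals = []
    for i in range(150):
        gl = set(rng.choice(nodes, 20, replace=False))
        pvals.append(
            network_list_enrichment(gl, gene_set, g, n_perm=200, seed=i)["p"]
        )
    assert stats.kstest(pvals, "uniform").statistic < 0.12


def test_auc_endpoints_and_midpoint():
    ones = pd.Series(1.0, index=range(1, 201))
    assert listsize_auc(ones).auc == pytest.approx(0.0)
    zeros = pd.Series(0.0, index=range(1, 201))
    assert listsize_auc(zeros).auc == pytest.approx(1.0)
    half = pd.Series(1e-26, index=range(1, 201))
    assert listsize_auc(half).auc == pytest.approx(0.5)


def test_auc_monotone_and_bounded():
    rng = np.random.default_rng(6)
    p = pd.Series(rng.uniform(0, 1, 200), index=range(1, 201))
    base = listsize_auc(p).auc
    assert 0 <= base <= 1
    p2 = p.copy()
    p2.loc[37] = p2.loc[37] / 10  # lowering one p_adj can only raise the AUC
    assert listsize_auc(p2).auc >= base


def test_auc_rejects_gaps_and_bad_values():
    with pytest.raises(ValueError, match="missing"):
        listsize_auc(pd.Series(0.5, index=range(2, 201)))
    bad = pd.Series(0.5, index=range(1, 201))
    bad.loc[5] = 1.5
    with pytest.raises(ValueError):
        listsize_auc(bad)
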