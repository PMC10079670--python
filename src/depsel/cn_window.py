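"""Copy-number neighborhood enrichment around a nominated anchor gene.

When a dependency correlates with copy number of a gene, neighboring genes
on the same chromosome typically co-vary (copy-number segments are long),
so the true driver is ambiguous. This scan asks whether the dependency's
copy-number correlates are enriched for physical neighbors of a nominated
anchor: for each window span w on a grid (default 5e5..5e6 bp, step 5e5),
the genes whose midpoints fall within the centered span form a gene set
that is tested by pre-ranked enrichment against the full list of
copy-number correlates ranked by decreasing r. The selected window is the
one with the smallest permutation p (ties: larger |ES|, then smaller w).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import RankedList, _null_es_from_positions, preranked_enrichment_score
from .iodata import GeneCoords, RunConfig

log = logging.getLogger("depsel")

__all__ = ["WindowResult", "WindowScanResult", "genes_in_window", "window_enrichment_scan"]


@dataclass
class WindowResult:
    window_bp: int
    members: set[str]
    n_in_ranking: int
    es: float
    p_perm: float


@dataclass
class WindowScanResult:
    anchor: str
    windows: list[WindowResult]
    selected: WindowResult
    seed: int | None


def genes_in_window(
    anchor: str,
    coords: GeneCoords,
    window_bp: int,
    include_anchor: bool = True,
    inclusive: bool = True,
) -> set[str]:
    """Genes on the anchor's chromosome whose midpoints lie within a
    centered span of total width ``window_bp`` (half-width each side)."""
    if anchor not in coords:
        raise KeyError(f"anchor gene {anchor!r} absent from coordinates")
    if window_bp <= 0:
        raise ValueError("window span must be positive")
    mid = coords.midpoint(anchor)
    chrom = coords.chromosome(anchor)
    half = window_bp / 2.0
    tab = coords.table
    on_chrom = tab[tab["chromosome"] == chrom]
    d = (on_chrom["midpoint"] - mid).abs()
    sel = d <= half if inclusive else d < half
    members = set(on_chrom.index[sel])
    if not include_anchor:
        members.discard(anchor)
    else:
        members.add(anchor)
    return members


def window_enrichment_scan(
    anchor: str,
    coords: GeneCoords,
    ranked_correlates: pd.DataFrame,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> WindowScanResult:
    """Scan the window grid and select the maximally enriched span.

    ``ranked_correlates`` is a biomarker-scan table (indexed by feature/gene
    symbol, column ``r``) ranked by decreasing correlation with the
    dependency; rows with missing r are ignored. Each window's member set is
    tested by the pre-ranked running-sum statistic with a same-size random
    gene-set null of ``config.n_permutations`` draws.
    """
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    ranked = ranked_correlates[ranked_correlates["r"].notna()]
    if len(ranked) < 100:
        raise ValueError(f"ranked correlate list covers {len(ranked)} genes, need >=100")
    ranking = RankedList(list(ranked.index.astype(str)), ranked["r"].to_numpy())
    gene_pos = set(ranking.genes)

    rng = np.random.default_rng(seed)
    n = len(ranking)
    windows: list[WindowResult] = []
    for w in config.window_grid():
        members = genes_in_window(
            anchor,
            coords,
            w,
            include_anchor=config.window_include_anchor,
            inclusive=config.window_inclusive_bounds,
        )
        inter = members & gene_pos
        if not inter:
            log.warning("window %d bp: no members in the ranked list; skipped", w)
            continue
        if len(inter) >= n:
            log.warning("window %d bp covers the whole ranked list; skipped", w)
            continue
        obs = preranked_enrichment_score(ranking, inter)
        k = len(inter)
        pos = np.empty((config.n_permutations, k), dtype=np.int64)
        for i in range(config.n_permutations):
            pos[i] = rng.choice(n, size=k, replace=False)
        pos.sort(axis=1)
        null = _null_es_from_positions(pos, ranking.metric, 1.0)
        es = obs["ES"]
        n_extreme = int(np.sum(np.abs(null) >= abs(es)))
        p = (1 + n_extreme) / (1 + config.n_permutations)
        windows.append(WindowResult(w, members, k, es, p))

    if not windows:
        raise ValueError("every window was skipped; nothing to select")
    selected = min(windows, key=lambda r: (r.p_perm, -abs(r.es), r.window_bp))
    return WindowScanResult(anchor, windows, selected, seed)
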