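"""Modified z-scores (ZMAD), signature scoring and lineage ranking.

Expression signatures (here, a 38-gene interferon-stimulated-gene core set)
are summarized per cell line as the mean modified z-score of the signature
genes. The modified z-score centers each gene on its median across cell
lines and scales by an absolute-deviation statistic — by default the mean
absolute deviation about the median computed on raw TPM values; the
conventional median-absolute-deviation variant is available as an option.
Lineage-level comparison ranks the disease group against all annotated
lineages with at least two cell lines, after dropping unannotated lines and
configured exclusion labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iodata import FeatureKind, FeatureMatrix, PanelMetadata

log = logging.getLogger("depsel")

__all__ = [
    "ZmadMatrix",
    "SignatureScores",
    "LineageRanking",
    "zmad_transform",
    "signature_score",
    "lineage_ranking",
]

_SCALE_MODES = ("mean_abs_dev_from_median", "median_abs_dev")


@dataclass
class ZmadMatrix:
    values: pd.DataFrame  # cell lines x genes
    center: pd.Series  # per-gene median
    scale: pd.Series  # per-gene absolute-deviation statistic
    scale_mode: str
    excluded_genes: list[str] = field(default_factory=list)


@dataclass
class SignatureScores:
    scores: pd.Series  # per cell line
    n_genes_used: pd.Series
    signature_name: str


@dataclass
class LineageRanking:
    table: pd.DataFrame  # index lineage; columns n_lines, median_score
    group_rank: int  # 1 = highest median
    group_label: str
    exclusion_log: dict[str, list[str]]


def zmad_transform(
    expr: FeatureMatrix,
    scale_mode: str = "mean_abs_dev_from_median",
    allow_log_kind: bool = False,
) -> ZmadMatrix:
    """Per-gene modified z-scores across cell lines.

    Expects raw-TPM expression; pass ``allow_log_kind=True`` to accept
    log2(TPM+1) input explicitly. Genes with zero scale (constant across
    lines) are dropped and listed in ``excluded_genes``.
    """
    if expr.kind is not FeatureKind.expression_tpm:
        if not (allow_log_kind and expr.kind is FeatureKind.expression_log2tpm):
            raise ValueError(
                f"ZMAD expects expression_tpm input, got {expr.kind.value} "
                "(pass allow_log_kind=True for expression_log2tpm)"
            )
    if scale_mode not in _SCALE_MODES:
        raise ValueError(f"scale_mode must be one of {_SCALE_MODES}")
    vals = expr.values
    if vals.shape[0] < 3:
        raise ValueError("need >=3 cell lines")
    center = vals.median(axis=0)
    absdev = (vals - center).abs()
    if scale_mode == "mean_abs_dev_from_median":
        scale = absdev.mean(axis=0)
    else:
        scale = absdev.median(axis=0)
    keep = scale > 0
    excluded = sorted(scale.index[~keep.fillna(False)])
    if excluded:
        log.warning("dropping %d zero-scale gene(s) from ZMAD: %s%s",
                    len(excluded), excluded[:5], "..." if len(excluded) > 5 else "")
    z = (vals.loc[:, keep] - center[keep]) / scale[keep]
    return ZmadMatrix(z, center[keep], scale[keep], scale_mode, excluded)


def signature_score(
    zmad: ZmadMatrix, signature: set[str], name: str = "signature"
) -> SignatureScores:
    """Per-cell-line mean ZMAD over the signature genes present."""
    present = sorted(signature & set(zmad.values.columns))
    if not present:
        raise ValueError(
            f"no signature genes present in the matrix; missing: {sorted(signature)[:10]}"
        )
    sub = zmad.values[present]
    scores = sub.mean(axis=1)
    n_used = sub.notna().sum(axis=1)
    scores = scores.where(n_used > 0)
    return SignatureScores(scores, n_used, name)


def lineage_ranking(
    scores: SignatureScores,
    meta: PanelMetadata,
    min_lines: int = 2,
    exclude: tuple[str, ...] = ("Engineered",),
    group_label: str = "group",
) -> LineageRanking:
    """Rank the disease group's median score against annotated lineages.

    The group (metadata ``group_flag``) forms its own category regardless of
    its lineage annotation. Reference lines without lineage annotation,
    lineages in ``exclude``, and lineages with fewer than ``min_lines``
    lines are dropped (all logged). Rank 1 = highest median; ties broken by
    lineage name.
    """
    meta_t = meta.table.loc[meta.table.index.intersection(scores.scores.index)]
    s = scores.scores.loc[meta_t.index]
    exclusion_log: dict[str, list[str]] = {
        "no_annotation": [],
        "excluded_label": [],
        "too_few_lines": [],
    }

    group_lines = meta_t.index[meta_t["group_flag"]]
    if len(group_lines) == 0:
        raise ValueError("query group absent from scored cell lines")
    rows = {group_label: s.loc[group_lines]}

    ref = meta_t[~meta_t["group_flag"]]
    no_annot = ref.index[ref["lineage"].isna()]
    exclusion_log["no_annotation"] = list(no_annot)
    annotated = ref[ref["lineage"].notna()]
    for lineage, sub in annotated.groupby("lineage"):
        lineage = str(lineage)
        if lineage in exclude:
            exclusion_log["excluded_label"].append(lineage)
            continue
        if len(sub) < min_lines:
            exclusion_log["too_few_lines"].append(lineage)
            continue
        rows[lineage] = s.loc[sub.index]

    table = pd.DataFrame(
        {
            "n_lines": {k: int(v.notna().sum()) for k, v in rows.items()},
            "median_score": {k: float(v.median()) for k, v in rows.items()},
        }
    )
    # descending median, ties broken by lineage name for determinism
    table = table.iloc[
        np.lexsort((table.index.astype(str), -table["median_score"].to_numpy()))
    ]
    group_rank = int(np.where(table.index == group_label)[0][0]) + 1
    return LineageRanking(table, group_rank, group_label, exclusion_log)
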