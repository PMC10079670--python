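"""Synthetic screening panels with planted ground truth.

The generator emulates the structure of a DepMap-style panel — a large
reference collection (default 500 lines) plus a small disease group
(default 4 lines) screened over ~1000 genes — with planted gene classes:

* common essential genes (negative gene effect in every line),
* group-selective genes (negative effect only in the disease group),
* reference-selective genes (negative effect only in the reference panel),
* neutral genes (effect centered at zero).

Dependency probabilities are a monotone logistic transform of gene effect
plus small independent noise, clipped to [0, 1]. Genes are laid out on
synthetic chromosomes at fixed spacing; copy number is generated from
shared segments so physical neighbors co-vary, and three biomarker signals
are planted: a paralog-loss pair (low partner copy number tracks a stronger
dependency, with the partner's whole segment co-varying so the window scan
has a neighbor block to find), a mutation-pathway pair (mutated lines gain
a dependency), and an elevated interferon-stimulated-gene expression
signature in the disease group. Expression is coupled to copy number
(dosage), so copy-number correlates reappear as expression correlates.

All randomness flows from a single seed through named substreams, so
enabling or resizing one planted structure does not perturb the draws of
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iodata import (
    FeatureKind,
    FeatureMatrix,
    GeneCoords,
    Measure,
    PanelMetadata,
    ScoreMatrix,
)

__all__ = [
    "SyntheticPanelConfig",
    "TruthTables",
    "SyntheticPanel",
    "simulate_panel",
    "evaluate_recovery",
]

_ISG_GENES = (
    "ADAR,BST2,CASP1,CMPK2,CXCL10,DDX60,DHX58,EIF2AK2,EPSTI1,GBP4,HERC6,"
    "IFI35,IFIH1,IFIT2,IFIT3,IRF7,ISG15,ISG20,MX1,NMI,OASL,OGFR,PARP12,"
    "PARP14,PNPT1,PSME2,RSAD2,RTP4,SAMD9L,SP110,STAT2,TDRD7,TRAFD1,TRIM14,"
    "TRIM21,TRIM25,UBE2L6,USP18"
).split(",")

# fixed substream labels: adding a class must not perturb other draws
_STREAMS = {
    "layout": 0,
    "effects": 1,
    "probability": 2,
    "copy_number": 3,
    "expression": 4,
    "mutation": 5,
    "missing": 6,
}


@dataclass
class SyntheticPanelConfig:
    """Panel dimensions, planted-class counts and effect sizes.

    Defaults mirror the study conditions: 4 disease-group lines against a
    ~500-line reference panel, 1000 genes with 20 planted group-selective
    dependencies at gene effect -1.0 and observation noise sd 0.2.
    """

    n_reference: int = 500
    n_group: int = 4
    n_genes: int = 1000
    n_common_essential: int = 50
    n_group_selective: int = 20
    n_reference_selective: int = 5
    group_effect: float = -1.0
    common_effect: float = -1.0
    noise_sd: float = 0.2
    # logistic gene-effect -> dependency-probability mapping
    prob_steepness: float = 6.0
    prob_midpoint: float = -0.5
    prob_noise_sd: float = 0.02
    # chromosome layout
    n_chrom: int = 5
    gene_spacing_bp: int = 100_000
    gene_length_bp: int = 20_000
    # copy number: segment structure and planted paralog pair
    cn_segment_genes: int = 8
    cn_sd: float = 0.5
    cn_gene_jitter_sd: float = 0.15
    cn_block_halfwidth_genes: int = 2
    cn_dependency_beta: float = 0.6
    # planted mutation-pathway pair
    n_background_mutation_features: int = 50
    mutation_prevalence: float = 0.15
    mutation_effect: float = 1.0
    # ISG elevation in the disease group (units of per-gene expression sd)
    isg_shift: float = 3.0
    n_lineages: int = 20
    plant_exclusion_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        n_classes = (
            self.n_common_essential
            + self.n_group_selective
            + self.n_reference_selective
        )
        if n_classes > self.n_genes:
            raise ValueError(
                f"planted class counts ({n_classes}) exceed n_genes ({self.n_genes})"
            )
        if self.n_genes - n_classes < len(_ISG_GENES):
            raise ValueError("too few neutral genes to host the ISG signature")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is required and must be an integer")


@dataclass
class TruthTables:
    group_selective: list[str]
    reference_selective: list[str]
    common_essential: list[str]
    neutral: list[str]
    biomarkers: pd.DataFrame  # dependency_gene, feature_id, feature_kind, expected_sign
    window_anchor: dict
    isg_genes: list[str]


@dataclass
class SyntheticPanel:
    gene_effect: ScoreMatrix
    dependency_probability: ScoreMatrix
    expression: FeatureMatrix
    copy_number: FeatureMatrix
    mutations: FeatureMatrix
    coords: GeneCoords
    metadata: PanelMetadata
    truth: TruthTables
    config: SyntheticPanelConfig


def _rng(cfg: SyntheticPanelConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


def simulate_panel(config: SyntheticPanelConfig | None = None) -> SyntheticPanel:
    """Generate a panel; deterministic given ``config.seed``."""
    cfg = config or SyntheticPanelConfig()

    lines = [f"GRP{i:02d}" for i in range(cfg.n_group)] + [
        f"REF{i:04d}" for i in range(cfg.n_reference)
    ]
    is_group = np.array([c.startswith("GRP") for c in lines])
    n_lines = len(lines)

    # --- layout: class assignment and chromosome placement -----------------
    rng = _rng(cfg, "layout")
    perm = rng.permutation(cfg.n_genes)
    n_ce, n_gs, n_rs = (
        cfg.n_common_essential,
        cfg.n_group_selective,
        cfg.n_reference_selective,
    )
    idx_ce = perm[:n_ce]
    idx_gs = perm[n_ce : n_ce + n_gs]
    idx_rs = perm[n_ce + n_gs : n_ce + n_gs + n_rs]
    idx_neutral = perm[n_ce + n_gs + n_rs :]

    names = [f"SYN{i:04d}" for i in range(cfg.n_genes)]
    # 38 neutral genes carry the real ISG symbols so the packaged signature
    # file exercises the scoring path end-to-end
    isg_idx = idx_neutral[: len(_ISG_GENES)]
    for j, gi in enumerate(isg_idx):
        names[gi] = _ISG_GENES[j]

    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chrom))
    chroms, starts = [], []
    for i in range(cfg.n_genes):
        chroms.append(f"chr{i // per_chrom + 1}")
        pos_on_chrom = i % per_chrom
        starts.append(pos_on_chrom * cfg.gene_spacing_bp)
    coords = GeneCoords(
        pd.DataFrame(
            {
                "chromosome": chroms,
                "start": starts,
                "end": [s + cfg.gene_length_bp for s in starts],
            },
            index=pd.Index(names, name="gene"),
        )
    )

    # planted paralog pair: dependency = a group-selective gene; partner
    # (anchor) = a neutral gene placed away from chromosome edges
    dep_cn = names[idx_gs[0]]
    anchor_candidates = [
        gi
        for gi in idx_neutral[len(_ISG_GENES) :]
        if cfg.cn_block_halfwidth_genes
        <= (gi % per_chrom)
        < per_chrom - cfg.cn_block_halfwidth_genes
    ]
    anchor_gi = int(anchor_candidates[0])
    anchor = names[anchor_gi]
    block_gis = [
        anchor_gi + d
        for d in range(-cfg.cn_block_halfwidth_genes, cfg.cn_block_halfwidth_genes + 1)
    ]
    block_genes = [names[g] for g in block_gis]

    # planted mutation pair: dependency = a neutral gene; mutated lines gain it
    dep_mut_gi = int(
        [gi for gi in idx_neutral[len(_ISG_GENES) :] if gi not in set(block_gis)][1]
    )
    dep_mut = names[dep_mut_gi]

    # --- gene effects -------------------------------------------------------
    rng = _rng(cfg, "effects")
    base = np.zeros((n_lines, cfg.n_genes))
    base[:, idx_ce] = cfg.common_effect
    base[np.ix_(is_group, idx_gs)] = cfg.group_effect
    base[np.ix_(~is_group, idx_rs)] = cfg.group_effect
    effect = base + rng.normal(0.0, cfg.noise_sd, size=base.shape)

    # --- copy number (needed before finishing effects: paralog coupling) ----
    rng_cn = _rng(cfg, "copy_number")
    cn_dev = np.empty((n_lines, cfg.n_genes))
    seg_len = max(1, cfg.cn_segment_genes)
    for start in range(0, cfg.n_genes, seg_len):
        stop = min(start + seg_len, cfg.n_genes)
        # segments never span chromosomes materially (per_chrom % seg_len
        # boundaries are a tolerable simplification)
        seg = rng_cn.normal(0.0, cfg.cn_sd, size=(n_lines, 1))
        cn_dev[:, start:stop] = seg
    cn_dev += rng_cn.normal(0.0, cfg.cn_gene_jitter_sd, size=cn_dev.shape)
    # planted block: the anchor's segment deviation is shared by the whole block
    anchor_seg = rng_cn.normal(0.0, cfg.cn_sd, size=n_lines)
    for gi in block_gis:
        cn_dev[:, gi] = anchor_seg + rng_cn.normal(
            0.0, cfg.cn_gene_jitter_sd, size=n_lines
        )
    copy_number = 2.0 + cn_dev

    # paralog coupling: low partner copy number -> more negative effect
    effect[:, names.index(dep_cn)] += cfg.cn_dependency_beta * anchor_seg

    # --- mutations ----------------------------------------------------------
    rng_mut = _rng(cfg, "mutation")
    mut_feature_gis = [
        gi
        for gi in idx_neutral[len(_ISG_GENES) :]
        if gi not in set(block_gis) and gi != dep_mut_gi
    ][2 : 2 + cfg.n_background_mutation_features]
    mut_pathway_gi = int(mut_feature_gis[0])  # planted pathway gene
    mut_pathway = names[mut_pathway_gi]
    mut_mat = (
        rng_mut.random((n_lines, len(mut_feature_gis))) < cfg.mutation_prevalence
    ).astype(float)
    mut_cols = [names[g] for g in mut_feature_gis]
    planted_mut = mut_mat[:, 0]
    # mutated lines gain the dependency (effect shifts negative)
    effect[:, dep_mut_gi] -= cfg.mutation_effect * planted_mut

    # --- dependency probability --------------------------------------------
    rng_p = _rng(cfg, "probability")
    logistic = 1.0 / (
        1.0 + np.exp(cfg.prob_steepness * (effect - cfg.prob_midpoint))
    )
    prob = np.clip(
        logistic + rng_p.normal(0.0, cfg.prob_noise_sd, size=effect.shape), 0.0, 1.0
    )

    # --- expression (TPM), dosage-coupled to copy number, ISG-shifted -------
    rng_e = _rng(cfg, "expression")
    mu = rng_e.uniform(2.0, 50.0, size=cfg.n_genes)
    sd = 0.25 * mu
    expr = rng_e.normal(mu, sd, size=(n_lines, cfg.n_genes))
    expr *= np.clip(copy_number, 0.0, None) / 2.0
    isg_cols = np.array(sorted(isg_idx))
    expr[np.ix_(is_group, isg_cols)] += cfg.isg_shift * sd[isg_cols]
    expr = np.clip(expr, 0.0, None)

    # --- metadata -----------------------------------------------------------
    lineages: list[str | None] = []
    for i, c in enumerate(lines):
        if is_group[i]:
            lineages.append("disease_group")
        else:
            lineages.append(f"lineage_{(i - cfg.n_group) % cfg.n_lineages + 1:02d}")
    if cfg.plant_exclusion_labels and cfg.n_reference >= cfg.n_lineages + 3:
        lineages[-1] = None  # no annotation
        lineages[-2] = "Engineered"
        lineages[-3] = "singleton_lineage"
    meta = PanelMetadata(
        pd.DataFrame(
            {"group_flag": is_group, "lineage": lineages},
            index=pd.Index(lines, name="cell_line_id"),
        )
    )

    gene_idx = pd.Index(names)
    line_idx = pd.Index(lines)
    truth = TruthTables(
        group_selective=sorted(names[g] for g in idx_gs),
        reference_selective=sorted(names[g] for g in idx_rs),
        common_essential=sorted(names[g] for g in idx_ce),
        neutral=sorted(names[g] for g in idx_neutral),
        biomarkers=pd.DataFrame(
            [
                {
                    "dependency_gene": dep_cn,
                    "feature_id": anchor,
                    "feature_kind": "copy_number",
                    "expected_sign": 1,
                },
                {
                    "dependency_gene": dep_cn,
                    "feature_id": anchor,
                    "feature_kind": "expression_tpm",
                    "expected_sign": 1,
                },
                {
                    "dependency_gene": dep_mut,
                    "feature_id": mut_pathway,
                    "feature_kind": "mutation_binary",
                    "expected_sign": -1,
                },
            ]
        ),
        window_anchor={
            "anchor": anchor,
            "dependency_gene": dep_cn,
            "block_genes": block_genes,
            "block_span_bp": (len(block_genes) - 1) * cfg.gene_spacing_bp,
        },
        isg_genes=sorted(names[g] for g in isg_idx),
    )

    return SyntheticPanel(
        gene_effect=ScoreMatrix(
            pd.DataFrame(effect, index=line_idx, columns=gene_idx), Measure.gene_effect
        ),
        dependency_probability=ScoreMatrix(
            pd.DataFrame(prob, index=line_idx, columns=gene_idx),
            Measure.dependency_probability,
        ),
        expression=FeatureMatrix(
            pd.DataFrame(expr, index=line_idx, columns=gene_idx),
            FeatureKind.expression_tpm,
        ),
        copy_number=FeatureMatrix(
            pd.DataFrame(copy_number, index=line_idx, columns=gene_idx),
            FeatureKind.copy_number,
        ),
        mutations=FeatureMatrix(
            pd.DataFrame(mut_mat, index=line_idx, columns=pd.Index(mut_cols)),
            FeatureKind.mutation_binary,
        ),
        coords=coords,
        metadata=meta,
        truth=truth,
        config=cfg,
    )


def evaluate_recovery(
    calls: pd.DataFrame, truth: TruthTables, status_col: str = "relaxed_status"
) -> dict:
    """Confusion statistics of a nomination table against planted truth.

    Sensitivity is over planted group-selective genes (called
    ``group_selective`` in ``status_col``); specificity is over planted
    neutral genes; precision is over all ``group_selective`` calls.
    """
    universe = set(calls.index)
    planted = set(truth.group_selective)
    neutral = set(truth.neutral)
    if not planted <= universe or not neutral <= universe:
        raise ValueError("calls do not cover the truth-table gene universe")
    called = set(calls.index[calls[status_col] == "group_selective"])
    tp = len(called & planted)
    fn = len(planted - called)
    fp_neutral = len(called & neutral)
    tn_neutral = len(neutral - called)
    fp_total = len(called - planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "specificity": tn_neutral / len(neutral) if neutral else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
        "tp": tp,
        "fn": fn,
        "fp_neutral": fp_neutral,
        "fp_total": fp_total,
        "tn_neutral": tn_neutral,
        "n_called": len(called),
        "n_planted": len(planted),
    }
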