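"""Moderated two-group differential essentiality and selectivity nomination.

A disease group (here, a handful of chordoma lines) is compared against a
large reference panel gene by gene. The per-gene effect is the difference of
group means of the screen score — the coefficient a two-group linear model
reports, conventionally labelled "log2 fold-change" even though the scores
themselves are not log-ratios. Per-gene variances are shrunk toward a
common prior by empirical-Bayes moderation (the limma squeezeVar model):
sample variances s^2 with df residual degrees of freedom are assumed scaled
chi-square around a gene-level variance drawn from a scaled inverse
chi-square prior with hyperparameters (d0, s0^2), estimated by moment
matching on log s^2. The moderated t uses the posterior variance

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

and a t reference distribution with d0 + df degrees of freedom.

Selective dependencies are then nominated by two gates. Relaxed: effect-score
P < 0.02, |lfc| > 0.4 on gene effect and |lfc| > 0.3 on dependency
probability. Stringent: P < 0.01 and |lfc| > 0.5 on both score types.
Direction: group-selective calls additionally require mean group dependency
probability > 0.5 with positive probability-lfc; reference-selective calls
require mean group probability <= 0.5 with negative probability-lfc.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .iodata import Measure, PanelMetadata, RunConfig, ScoreMatrix

log = logging.getLogger("depsel")

__all__ = [
    "ModerationParams",
    "SelectivityStatus",
    "group_difference",
    "empirical_bayes_moderation",
    "bh_adjust",
    "differential_table",
    "nominate_selective",
]


@dataclass(frozen=True)
class ModerationParams:
    """Hyperparameters of the variance prior: prior df d0 (may be inf), prior
    variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


class SelectivityStatus(str, enum.Enum):
    group_selective = "group_selective"
    reference_selective = "reference_selective"
    not_selective = "not_selective"


def group_difference(matrix: ScoreMatrix, meta: PanelMetadata) -> pd.DataFrame:
    """Per-gene two-group summary statistics.

    Rows with missing values are dropped per gene before computing means and
    the pooled within-group variance. Returns a DataFrame indexed by gene
    with columns ``lfc`` (group mean - reference mean), ``s2`` (pooled
    variance), ``df`` (n1 + n2 - 2), ``mean_group``, ``mean_reference``,
    ``n_group``, ``n_reference`` and boolean ``usable`` (>=2 complete
    observations in each arm).
    """
    meta.require_two_per_arm()
    absent = meta.covers(matrix.cell_lines)
    if absent:
        raise ValueError(f"cell lines missing from metadata: {absent[:5]}")

    vals = matrix.values
    grp = vals.loc[[c for c in vals.index if c in set(meta.group_lines)]]
    ref = vals.loc[[c for c in vals.index if c in set(meta.reference_lines)]]

    n1 = grp.notna().sum(axis=0).astype(float)
    n2 = ref.notna().sum(axis=0).astype(float)
    m1 = grp.mean(axis=0)
    m2 = ref.mean(axis=0)
    # ddof=1 sums of squares; arms with n<2 contribute NaN and are unusable
    ss1 = ((grp - m1) ** 2).sum(axis=0, min_count=1)
    ss2 = ((ref - m2) ** 2).sum(axis=0, min_count=1)
    df = n1 + n2 - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (ss1 + ss2) / df
    usable = (n1 >= 2) & (n2 >= 2)
    out = pd.DataFrame(
        {
            "lfc": m1 - m2,
            "s2": s2,
            "df": df,
            "mean_group": m1,
            "mean_reference": m2,
            "n_group": n1.astype(int),
            "n_reference": n2.astype(int),
            "usable": usable,
        }
    )
    n_bad = int((~usable).sum())
    if n_bad:
        log.warning("%d gene(s) with <2 usable observations in an arm excluded", n_bad)
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_moderation_params(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Estimate (d0, s0^2) by moment matching on z = log s^2.

    E[z] = log s0^2 + digamma(d0/2) - log(d0/2) + log(df/2) - digamma(df/2)
    Var[z] = trigamma(df/2) + trigamma(d0/2)

    When the empirical variance of z does not exceed trigamma(df/2) (no
    excess dispersion), d0 = inf and s0^2 = exp(mean adjustment), so the
    posterior variance collapses to s0^2 for every gene.
    """
    mask = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if mask.sum() < 10:
        raise ValueError(
            "fewer than 10 genes with positive finite variance; supply explicit "
            "ModerationParams"
        )
    z = np.log(s2[mask])
    dfm = df[mask]
    e = z - special.digamma(dfm / 2.0) + np.log(dfm / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    # subtract the expected sampling variance of z given df
    excess = evar - float(np.mean(special.polygamma(1, dfm / 2.0)))
    if excess <= 0:
        return ModerationParams(np.inf, float(np.exp(emean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    # E[log sigma^2] = log s0^2 + log(d0/2) - digamma(d0/2) under the prior
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0, s0_sq)


def empirical_bayes_moderation(
    rows: pd.DataFrame, params: ModerationParams | None = None
) -> tuple[pd.DataFrame, ModerationParams]:
    """Add moderated t-statistics and two-sided P-values to a
    :func:`group_difference` table.

    Genes flagged unusable keep NaN statistics. Genes with s2 = 0 receive the
    pure-shrinkage posterior variance d0*s0^2/(d0+df) rather than an infinite
    t. With d0 = inf the posterior variance is s0^2 for all genes and the
    reference distribution is normal.
    """
    out = rows.copy()
    usable = out["usable"].to_numpy(dtype=bool)
    s2 = out["s2"].to_numpy(dtype=float)
    df = out["df"].to_numpy(dtype=float)
    if params is None:
        params = fit_moderation_params(s2[usable], df[usable])

    d0, s0_sq = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * np.where(np.isfinite(s2), s2, 0.0)) / (d0 + df)
        df_total = d0 + df

    n1 = out["n_group"].to_numpy(dtype=float)
    n2 = out["n_reference"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t_mod = out["lfc"].to_numpy(dtype=float) / se
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t_mod)),
            2.0 * stats.t.sf(np.abs(t_mod), np.where(df_total > 0, df_total, 1.0)),
        )
    t_mod = np.where(usable, t_mod, np.nan)
    p = np.where(usable, p, np.nan)
    out["s2_post"] = np.where(usable, s2_post, np.nan)
    out["t_mod"] = t_mod
    out["P"] = p
    return out, params


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN entries propagate."""
    arr = np.asarray(p, dtype=float)
    if np.nanmin(arr, initial=1.0) < 0 or np.nanmax(arr, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        q[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)
    return q


def differential_table(
    matrix: ScoreMatrix,
    meta: PanelMetadata,
    params: ModerationParams | None = None,
    lfc_as_ratio_of_means: bool = False,
) -> pd.DataFrame:
    """Full differential analysis for one score matrix: group statistics,
    moderated t, P and BH Q.

    ``lfc_as_ratio_of_means`` replaces the reported effect with
    log2(mean_group / mean_reference) where both means are positive (NaN
    otherwise); tests and P-values always use the mean-difference
    coefficient. Off by default.
    """
    rows = group_difference(matrix, meta)
    rows, _ = empirical_bayes_moderation(rows, params)
    rows["Q"] = bh_adjust(rows["P"])
    if lfc_as_ratio_of_means:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(
                (rows["mean_group"] > 0) & (rows["mean_reference"] > 0),
                np.log2(rows["mean_group"] / rows["mean_reference"]),
                np.nan,
            )
        rows["lfc_ratio"] = ratio
    return rows


def nominate_selective(
    diff_effect: pd.DataFrame,
    diff_prob: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Apply the stringent and relaxed selectivity gates.

    ``diff_effect`` / ``diff_prob`` are :func:`differential_table` outputs on
    the gene-effect and dependency-probability matrices. Genes present in
    only one table are excluded (logged). Returns a DataFrame indexed by
    gene with columns ``stringent_status``, ``relaxed_status`` (values of
    :class:`SelectivityStatus`) and ``stringent_criteria`` /
    ``relaxed_criteria`` listing the named magnitude criteria passed.
    """
    config = config or RunConfig()
    common = diff_effect.index.intersection(diff_prob.index)
    dropped = len(diff_effect.index.symmetric_difference(diff_prob.index))
    if dropped:
        log.warning("%d gene(s) present in only one differential table excluded", dropped)
    e = diff_effect.loc[common]
    p = diff_prob.loc[common]

    p_eff = e["P"].to_numpy(dtype=float)
    p_prob = p["P"].to_numpy(dtype=float)
    lfc_eff = e["lfc"].to_numpy(dtype=float)
    lfc_prob = p["lfc"].to_numpy(dtype=float)
    mean_group_prob = p["mean_group"].to_numpy(dtype=float)

    relaxed_crit = {
        "effect_P<%.3g" % config.relaxed_p_effect: p_eff < config.relaxed_p_effect,
        "|effect_lfc|>%.3g" % config.relaxed_lfc_effect: np.abs(lfc_eff)
        > config.relaxed_lfc_effect,
        "|prob_lfc|>%.3g" % config.relaxed_lfc_prob: np.abs(lfc_prob)
        > config.relaxed_lfc_prob,
    }
    stringent_crit = {
        "effect_P<%.3g" % config.stringent_p: p_eff < config.stringent_p,
        "prob_P<%.3g" % config.stringent_p: p_prob < config.stringent_p,
        "|effect_lfc|>%.3g" % config.stringent_lfc: np.abs(lfc_eff)
        > config.stringent_lfc,
        "|prob_lfc|>%.3g" % config.stringent_lfc: np.abs(lfc_prob)
        > config.stringent_lfc,
    }

    def _status(magnitude_pass: np.ndarray, apply_direction: bool) -> list[str]:
        cutoff = config.direction_prob_cutoff
        grp_dir = (mean_group_prob > cutoff) & (lfc_prob > 0)
        ref_dir = (mean_group_prob <= cutoff) & (lfc_prob < 0)
        statuses = []
        for i, ok in enumerate(magnitude_pass):
            if not ok or np.isnan(lfc_prob[i]) or np.isnan(mean_group_prob[i]):
                statuses.append(SelectivityStatus.not_selective.value)
            elif not apply_direction:
                statuses.append(
                    SelectivityStatus.group_selective.value
                    if lfc_prob[i] > 0
                    else SelectivityStatus.reference_selective.value
                )
            elif grp_dir[i]:
                statuses.append(SelectivityStatus.group_selective.value)
            elif ref_dir[i]:
                statuses.append(SelectivityStatus.reference_selective.value)
            else:
                statuses.append(SelectivityStatus.not_selective.value)
        return statuses

    with np.errstate(invalid="ignore"):
        relaxed_pass = np.logical_and.reduce(list(relaxed_crit.values()))
        stringent_pass = np.logical_and.reduce(list(stringent_crit.values()))

    out = pd.DataFrame(index=common)
    out["relaxed_status"] = _status(relaxed_pass, apply_direction=True)
    out["stringent_status"] = _status(
        stringent_pass, apply_direction=config.direction_at_stringent
    )
    out["relaxed_criteria"] = [
        ";".join(name for name, v in relaxed_crit.items() if v[i])
        for i in range(len(common))
    ]
    out["stringent_criteria"] = [
        ";".join(name for name, v in stringent_crit.items() if v[i])
        for i in range(len(common))
    ]
    out["mean_group_prob"] = mean_group_prob
    out["lfc_effect"] = lfc_eff
    out["lfc_prob"] = lfc_prob
    out["P_effect"] = p_eff
    out["P_prob"] = p_prob
    return out
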