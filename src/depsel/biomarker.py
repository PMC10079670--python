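"""Biomarker scans: correlate a dependency profile with genomic features.

For one dependency gene, its gene-effect profile across the panel is
correlated (Pearson, pairwise-complete observations) with every feature of
a feature matrix — expression log2(TPM+1), gene-level copy number, or binary
mutation indicators — and each pair additionally gets a univariate ordinary
least-squares fit predicting gene effect from the feature. Results are
ranked lists of correlates, not significance calls: mutation correlates are
conventionally ranked by increasing r (loss-of-dependency mutations first),
copy-number and expression correlates by decreasing r.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .iodata import FeatureKind, FeatureMatrix

__all__ = [
    "ConstantPredictorError",
    "InsufficientObservationsError",
    "univariate_linear_fit",
    "dependency_feature_correlations",
]


class ConstantPredictorError(ValueError):
    """The predictor is constant over the complete index; no slope exists."""


class InsufficientObservationsError(ValueError):
    """Fewer complete pairs than the minimum overlap."""


def univariate_linear_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS fit y = slope*x + intercept on complete pairs.

    Returns slope, intercept, r, p_reg (two-sided t-test on the slope with
    n_obs - 2 df) and n_obs. A perfect fit reports the smallest positive
    float rather than exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientObservationsError(f"need >=3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ConstantPredictorError("predictor is constant")
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p_reg": p,
        "n_obs": n,
    }


def dependency_feature_correlations(
    dep_profile: pd.Series,
    features: FeatureMatrix,
    min_overlap: int = 3,
    ascending: bool | None = None,
) -> pd.DataFrame:
    """Scan every feature against one dependency profile.

    ``dep_profile`` is a gene-effect vector indexed by cell line. Returns one
    row per feature with columns ``r``, ``n_obs``, ``slope``, ``intercept``,
    ``p_reg``, ``reason`` (NaN, ``"constant"`` or ``"insufficient_n"``),
    sorted by r. Sort order defaults to the figure convention for the
    feature kind: ascending for mutations, descending otherwise; override
    with ``ascending``.
    """
    shared = features.values.index.intersection(dep_profile.index)
    if len(shared) == 0:
        raise ValueError("no shared cell lines between profile and features")
    y_all = dep_profile.loc[shared].to_numpy(dtype=float)
    feat = features.values.loc[shared]
    arr = feat.to_numpy(dtype=float)
    y_ok = np.isfinite(y_all)

    rows = []
    for j, fid in enumerate(feat.columns):
        x = arr[:, j]
        ok = y_ok & np.isfinite(x)
        n = int(ok.sum())
        rec = {
            "feature_id": fid,
            "feature_kind": features.kind.value,
            "r": np.nan,
            "n_obs": n,
            "slope": np.nan,
            "intercept": np.nan,
            "p_reg": np.nan,
            "reason": np.nan,
        }
        if n < min_overlap:
            rec["reason"] = "insufficient_n"
        elif np.ptp(x[ok]) == 0 or np.ptp(y_all[ok]) == 0:
            rec["reason"] = "constant"
        else:
            fit = univariate_linear_fit(x[ok], y_all[ok])
            rec.update(
                r=fit["r"],
                slope=fit["slope"],
                intercept=fit["intercept"],
                p_reg=fit["p_reg"],
                n_obs=fit["n_obs"],
            )
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("feature_id")
    if ascending is None:
        ascending = features.kind is FeatureKind.mutation_binary
    return out.sort_values("r", ascending=ascending, na_position="last", kind="stable")


def mutation_features(
    calls: pd.DataFrame, cell_lines: list[str], with_any: bool = True
) -> FeatureMatrix:
    """Build binary mutation features from a long call table.

    ``calls`` has columns ``cell_line_id``, ``gene`` and optionally
    ``variant_class``. One feature per (gene, variant_class) named
    ``"GENE|class"`` when classes are present, plus a per-gene any-mutation
    feature named by the bare symbol when ``with_any``.
    """
    cols: dict[str, set[str]] = {}
    has_class = "variant_class" in calls.columns
    for _, row in calls.iterrows():
        gene = str(row["gene"])
        line = str(row["cell_line_id"])
        if has_class and pd.notna(row["variant_class"]):
            cols.setdefault(f"{gene}|{row['variant_class']}", set()).add(line)
        if with_any or not has_class:
            cols.setdefault(gene, set()).add(line)
    mat = pd.DataFrame(0.0, index=pd.Index(cell_lines), columns=sorted(cols))
    for fid, lines in cols.items():
        mat.loc[mat.index.isin(lines), fid] = 1.0
    return FeatureMatrix(mat, FeatureKind.mutation_binary)
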