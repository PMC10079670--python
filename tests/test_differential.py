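"""Moderated differential essentiality and the nomination gates."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depsel import (
    Measure,
    ModerationParams,
    PanelMetadata,
    RunConfig,
    ScoreMatrix,
    bh_adjust,
    differential_table,
    empirical_bayes_moderation,
    group_difference,
    nominate_selective,
)
from depsel.differential import fit_moderation_params

from oracles import bh_oracle, moderated_t_oracle, moment_match_oracle


def _two_arm_matrix(group_rows, ref_rows, measure=Measure.gene_effect):
    group_rows = np.atleast_2d(np.asarray(group_rows, float))
    ref_rows = np.atleast_2d(np.asarray(ref_rows, float))
    vals = np.vstack([group_rows, ref_rows])
    lines = [f"g{i}" for i in range(group_rows.shape[0])] + [
        f"r{i}" for i in range(ref_rows.shape[0])
    ]
    cols = [f"G{j}" for j in range(vals.shape[1])]
    meta = PanelMetadata(
        pd.DataFrame(
            {
                "group_flag": [True] * group_rows.shape[0]
                + [False] * ref_rows.shape[0],
                "lineage": "x",
            },
            index=pd.Index(lines),
        )
    )
    return ScoreMatrix(pd.DataFrame(vals, index=lines, columns=cols), measure), meta


def test_group_difference_matches_pooled_variance_formula():
    grp = np.array([-1.2, -1.0, -1.1, -0.9])
    ref = np.array([0.0, -0.1, 0.1, -0.2, 0.2])
    m, meta = _two_arm_matrix(grp[:, None], ref[:, None])
    rows = group_difference(m, meta)
    lfc = grp.mean() - ref.mean()
    s2 = ((grp - grp.mean()) ** 2).sum() + ((ref - ref.mean()) ** 2).sum()
    s2 /= len(grp) + len(ref) - 2
    assert rows.loc["G0", "lfc"] == pytest.approx(lfc, abs=1e-12)
    assert rows.loc["G0", "s2"] == pytest.approx(s2, abs=1e-12)
    assert rows.loc["G0", "df"] == len(grp) + len(ref) - 2


def test_group_difference_missing_values_and_unusable_rows():
    grp = np.array([[0.9, 0.9], [0.9, np.nan], [0.9, np.nan], [0.9, np.nan]])
    ref = np.full((5, 2), 0.1)
    m, meta = _two_arm_matrix(grp, ref)
    rows = group_difference(m, meta)
    assert rows.loc["G0", "lfc"] == pytest.approx(0.8)
    assert rows.loc["G0", "df"] == 7
    # only one usable group observation in G1
    assert not rows.loc["G1", "usable"]
    assert rows.loc["G1", "n_group"] == 1


def test_moderation_matches_formula_oracle_on_200_gene_table():
    rng = np.random.default_rng(42)
    n1, n2 = 4, 30
    grp = rng.normal(0, 1, size=(n1, 200)) * rng.uniform(0.5, 2, size=200)
    ref = rng.normal(0, 1, size=(n2, 200)) * rng.uniform(0.5, 2, size=200)
    m, meta = _two_arm_matrix(grp, ref)
    rows = group_difference(m, meta)
    out, params = empirical_bayes_moderation(rows)

    d0_o, s0_o = moment_match_oracle(
        rows["s2"].to_numpy(), rows["df"].to_numpy()
    )
    assert params.d0 == pytest.approx(d0_o, rel=1e-6)
    assert params.s0_sq == pytest.approx(s0_o, rel=1e-8)
    t_o, p_o = moderated_t_oracle(
        rows["lfc"].to_numpy(),
        rows["s2"].to_numpy(),
        rows["df"].to_numpy(),
        rows["n_group"].to_numpy(),
        rows["n_reference"].to_numpy(),
        params.d0,
        params.s0_sq,
    )
    np.testing.assert_allclose(out["t_mod"].to_numpy(), t_o, atol=1e-10)
    np.testing.assert_allclose(out["P"].to_numpy(), p_o, atol=1e-10)


def test_moderation_agrees_with_limma_reference(tmp_path):
    """Cross-check hyperparameters, t and P against R limma on one table."""
    rng = np.random.default_rng(7)
    n1, n2 = 4, 20
    scale = rng.uniform(0.3, 3.0, size=60)  # real variance dispersion: finite d0
    grp = rng.normal(0, 1, size=(n1, 60)) * scale
    ref = rng.normal(0.2, 1, size=(n2, 60)) * scale
    m, meta = _two_arm_matrix(grp, ref)
    rows = group_difference(m, meta)
    out, params = empirical_bayes_moderation(rows)

    mat = np.vstack([grp, ref]).T  # genes x samples for limma
    flat = ",".join(f"{v:.12g}" for v in mat.ravel())
    rscript = f"""
suppressMessages(library(limma))
x <- matrix(c({flat}), nrow={mat.shape[0]}, byrow=TRUE)
design <- cbind(1, c(rep(1, {n1}), rep(0, {n2})))
fit <- eBayes(lmFit(x, design))
cat("RES", fit$df.prior, fit$s2.prior, "\\n")
cat("RES", paste(fit$t[,2], collapse=","), "\\n")
cat("RES", paste(fit$p.value[,2], collapse=","), "\\n")
"""
    script = tmp_path / "limma_check.R"
    script.write_text(rscript)
    res = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert res.returncode == 0, res.stderr
    lines = [
        l[4:] for l in res.stdout.splitlines() if l.startswith("RES ")
    ]
    d0_r, s0_r = map(float, lines[0].split())
    t_r = np.array(list(map(float, lines[1].split(","))))
    p_r = np.array(list(map(float, lines[2].split(","))))
    assert params.d0 == pytest.approx(d0_r, rel=1e-4)
    assert params.s0_sq == pytest.approx(s0_r, rel=1e-4)
    np.testing.assert_allclose(out["t_mod"].to_numpy(), t_r, rtol=1e-6)
    np.testing.assert_allclose(out["P"].to_numpy(), p_r, rtol=1e-5)


def test_moderation_degenerate_and_zero_variance_rules():
    # identical s2 everywhere -> no excess dispersion -> d0 = inf
    rng = np.random.default_rng(1)
    lfc = rng.normal(size=20)
    rows = pd.DataFrame(
        {
            "lfc": lfc,
            "s2": np.full(20, 0.5),
            "df": np.full(20, 10.0),
            "n_group": 4,
            "n_reference": 8,
            "usable": True,
        },
        index=[f"G{i}" for i in range(20)],
    )
    out, params = empirical_bayes_moderation(rows)
    assert np.isinf(params.d0)
    expected_t = lfc / np.sqrt(params.s0_sq * (1 / 4 + 1 / 8))
    np.testing.assert_allclose(out["t_mod"], expected_t, atol=1e-12)
    # zero sample variance -> pure shrinkage, finite t
    rows2 = rows.copy()
    rows2["s2"] = np.where(np.arange(20) % 2 == 0, 0.05, 5.0)  # real dispersion
    rows2.loc["G0", "s2"] = 0.0
    out2, params2 = empirical_bayes_moderation(rows2)
    assert np.isfinite(params2.d0)
    assert np.isfinite(out2.loc["G0", "t_mod"])
    expected = params2.d0 * params2.s0_sq / (params2.d0 + 10.0)
    assert out2.loc["G0", "s2_post"] == pytest.approx(expected, rel=1e-10)


def test_moderation_limits_match_plain_t_and_z():
    rng = np.random.default_rng(2)
    rows = pd.DataFrame(
        {
            "lfc": rng.normal(size=10),
            "s2": rng.uniform(0.2, 2.0, size=10),
            "df": np.full(10, 8.0),
            "n_group": 5,
            "n_reference": 5,
            "usable": True,
        }
    )
    lo, _ = empirical_bayes_moderation(rows, ModerationParams(1e-8, 1.0))
    t_plain = rows["lfc"] / np.sqrt(rows["s2"] * (1 / 5 + 1 / 5))
    np.testing.assert_allclose(lo["t_mod"], t_plain, rtol=1e-6)
    hi, _ = empirical_bayes_moderation(rows, ModerationParams(1e8, 0.7))
    t_fixed = rows["lfc"] / np.sqrt(0.7 * (1 / 5 + 1 / 5))
    np.testing.assert_allclose(hi["t_mod"], t_fixed, rtol=1e-6)


def test_moderation_refuses_tiny_tables():
    s2 = np.array([0.5] * 5)
    df = np.array([4.0] * 5)
    with pytest.raises(ValueError, match="10"):
        fit_moderation_params(s2, df)


def test_zero_lfc_gives_t_zero_p_one():
    rows = pd.DataFrame(
        {
            "lfc": [0.0] * 12,
            "s2": np.linspace(0.1, 1.0, 12),
            "df": 6.0,
            "n_group": 4,
            "n_reference": 4,
            "usable": True,
        }
    )
    out, _ = empirical_bayes_moderation(rows)
    assert (out["t_mod"] == 0).all()
    np.testing.assert_allclose(out["P"], 1.0)


# --- BH ---------------------------------------------------------------------


def test_bh_matches_enumeration_oracle():
    p = [0.01, 0.02, 0.04]
    np.testing.assert_allclose(bh_adjust(np.array(p)), bh_oracle(p), atol=1e-15)
    np.testing.assert_allclose(bh_adjust(np.array(p)), [0.03, 0.03, 0.04], atol=1e-15)
    assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)
    same = bh_adjust(np.array([0.2, 0.2, 0.2]))
    np.testing.assert_allclose(same, 0.2)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_properties(p):
    p = np.asarray(p)
    q = bh_adjust(p)
    np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
    # order invariance
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-12)
    # step-up structure: q >= p, q <= 1, and q is monotone in the rank of p
    assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range_and_propagates_nan():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.5]))
    q = bh_adjust(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1]) and not np.isnan(q[0])


# --- nomination gates ---------------------------------------------------------


def _calls_df(**kw):
    base = dict(
        P=0.001,
        lfc=1.0,
        s2=0.1,
        df=10.0,
        mean_group=0.9,
        mean_reference=0.1,
        n_group=4,
        n_reference=8,
        usable=True,
        t_mod=5.0,
        Q=0.01,
    )
    base.update(kw)
    return pd.DataFrame(base, index=["GENE"])


@pytest.mark.parametrize(
    "p_eff, lfc_eff, lfc_prob, mean_gp, relaxed, stringent",
    [
        # straddles the relaxed thresholds from the published gates
        (0.015, 0.45, 0.35, 0.8, "group_selective", "not_selective"),
        # fails the relaxed P criterion
        (0.03, 1.0, 0.9, 0.9, "not_selective", "not_selective"),
        # reference-selective: low group probability, negative lfc
        (0.001, -0.9, -0.6, 0.3, "reference_selective", "reference_selective"),
        # stringent pass requires > 0.5 on both measures
        (0.005, 0.6, 0.6, 0.9, "group_selective", "group_selective"),
        # direction gate blocks: magnitudes pass but group prob too low
        (0.001, 0.9, 0.8, 0.3, "not_selective", "not_selective"),
    ],
)
def test_nomination_gates(p_eff, lfc_eff, lfc_prob, mean_gp, relaxed, stringent):
    diff_eff = _calls_df(P=p_eff, lfc=lfc_eff)
    diff_prob = _calls_df(P=p_eff, lfc=lfc_prob, mean_group=mean_gp)
    calls = nominate_selective(diff_eff, diff_prob, RunConfig())
    assert calls.loc["GENE", "relaxed_status"] == relaxed
    assert calls.loc["GENE", "stringent_status"] == stringent


def test_gate_monotonicity_lowering_thresholds_keeps_nominations(default_panel):
    meta = default_panel.metadata
    diff_eff = differential_table(default_panel.gene_effect, meta)
    diff_prob = differential_table(default_panel.dependency_probability, meta)
    strict = nominate_selective(diff_eff, diff_prob, RunConfig())
    loose = nominate_selective(
        diff_eff,
        diff_prob,
        RunConfig(relaxed_p_effect=0.05, relaxed_lfc_effect=0.2, relaxed_lfc_prob=0.1),
    )
    nominated_strict = set(strict.index[strict["relaxed_status"] != "not_selective"])
    nominated_loose = set(loose.index[loose["relaxed_status"] != "not_selective"])
    assert nominated_strict <= nominated_loose


def test_gene_universe_mismatch_is_excluded():
    diff_eff = pd.concat([_calls_df(), _calls_df().rename(index={"GENE": "ONLY_E"})])
    diff_prob = _calls_df()
    calls = nominate_selective(diff_eff, diff_prob)
    assert list(calls.index) == ["GENE"]
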