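"""End-to-end orchestration: simulate/load -> differential -> nomination ->
networks -> biomarkers -> window scan -> signatures, with a JSON report.

Stages whose inputs are absent are skipped and noted in the report; any
hard error aborts with the stage name. The report echoes the full
configuration and the seed, records per-stage output paths, and (when
planted truth is available) recovery metrics, so a run is self-describing
and byte-reproducible given the same seed and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .biomarker import dependency_feature_correlations
from .cn_window import window_enrichment_scan
from .coessentiality import build_network, profile_correlations, write_edge_list
from .differential import differential_table, nominate_selective
from .iodata import (
    FeatureKind,
    Measure,
    RunConfig,
    load_isg_core_signature,
    read_feature_table,
    read_gene_coords,
    read_metadata,
    read_score_matrix,
    write_feature_table,
    write_gene_coords,
    write_metadata,
    write_score_matrix,
)
from .signatures import lineage_ranking, signature_score, zmad_transform
from .synthetic_data import SyntheticPanelConfig, evaluate_recovery, simulate_panel

log = logging.getLogger("depsel")

__all__ = ["run_pipeline"]


def _universe_hash(index) -> str:
    h = hashlib.sha256()
    for g in index:
        h.update(str(g).encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def run_pipeline(
    config: RunConfig | None = None,
    inputs: dict | str = "simulate",
    out_dir: str | Path = "depsel_run",
    panel_config: SyntheticPanelConfig | None = None,
) -> dict:
    """Execute all pipeline stages and write a machine-readable report.

    ``inputs`` is either the string ``"simulate"`` (generate a synthetic
    panel from ``panel_config``, defaulting to the study conditions with
    the run seed) or a dict of file paths with keys ``effect``, ``prob``,
    ``meta`` and optionally ``expression_tpm``, ``copy_number``,
    ``mutations``, ``coords``. Returns the report dict (also written to
    ``report.json``).
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "skipped": [],
    }

    truth = None
    coords = None
    expression = copy_number = mutations = None
    stage = "load"
    try:
        if inputs == "simulate":
            pc = panel_config or SyntheticPanelConfig(seed=config.seed)
            panel = simulate_panel(pc)
            effect, prob, meta = (
                panel.gene_effect,
                panel.dependency_probability,
                panel.metadata,
            )
            expression, copy_number, mutations = (
                panel.expression,
                panel.copy_number,
                panel.mutations,
            )
            coords, truth = panel.coords, panel.truth
            write_score_matrix(effect, out / "gene_effect.csv")
            write_score_matrix(prob, out / "dependency_probability.csv")
            write_metadata(meta, out / "metadata.csv")
            write_feature_table(expression, out / "expression_tpm.csv")
            write_feature_table(copy_number, out / "copy_number.csv")
            write_feature_table(mutations, out / "mutations.csv")
            write_gene_coords(coords, out / "genes.bed")
            report["stages"]["simulate"] = {
                "panel_config": {
                    k: v for k, v in asdict(pc).items()
                },
                "files": sorted(p.name for p in out.glob("*.csv")) + ["genes.bed"],
            }
        else:
            effect = read_score_matrix(inputs["effect"], Measure.gene_effect)
            prob = read_score_matrix(inputs["prob"], Measure.dependency_probability)
            meta = read_metadata(inputs["meta"])
            if "expression_tpm" in inputs:
                expression = read_feature_table(
                    inputs["expression_tpm"], FeatureKind.expression_tpm
                )
            if "copy_number" in inputs:
                copy_number = read_feature_table(
                    inputs["copy_number"], FeatureKind.copy_number
                )
            if "mutations" in inputs:
                mutations = read_feature_table(
                    inputs["mutations"], FeatureKind.mutation_binary
                )
            if "coords" in inputs:
                coords = read_gene_coords(inputs["coords"])

        # --- differential + nomination -------------------------------------
        stage = "differential"
        diff_eff = differential_table(
            effect, meta, lfc_as_ratio_of_means=config.lfc_as_ratio_of_means
        )
        diff_prob = differential_table(prob, meta)
        calls = nominate_selective(diff_eff, diff_prob, config)
        merged = calls.copy()
        merged["Q_effect"] = diff_eff.loc[merged.index, "Q"]
        merged["Q_prob"] = diff_prob.loc[merged.index, "Q"]
        merged.to_csv(out / "differential.tsv", sep="\t")
        relaxed = sorted(
            calls.index[calls["relaxed_status"] == "group_selective"]
        )
        stringent = sorted(
            calls.index[calls["stringent_status"] == "group_selective"]
        )
        report["stages"]["differential"] = {
            "universe_hash": _universe_hash(calls.index),
            "n_genes": int(len(calls)),
            "relaxed_group_selective": relaxed,
            "stringent_group_selective": stringent,
            "file": "differential.tsv",
        }
        if truth is not None:
            report["stages"]["recovery"] = {
                "relaxed": evaluate_recovery(calls, truth, "relaxed_status"),
                "stringent": evaluate_recovery(calls, truth, "stringent_status"),
            }

        # --- co-essentiality network ---------------------------------------
        stage = "coessentiality"
        if len(relaxed) >= 2:
            corr, _ = profile_correlations(prob, relaxed, config.min_pair_obs)
            node_scores = diff_prob.loc[relaxed, "mean_group"].to_dict()
            net = build_network(corr, config.coessentiality_threshold, node_scores)
            write_edge_list(net, out / "coessentiality_edges.tsv")
            report["stages"]["coessentiality"] = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "components": net.graph["components"],
                "singletons": net.graph["singletons"],
                "file": "coessentiality_edges.tsv",
            }
        else:
            report["skipped"].append("coessentiality (fewer than 2 nominated genes)")

        # --- biomarker scans -------------------------------------------------
        stage = "biomarker"
        feature_sets = {
            "copy_number": copy_number,
            "expression_tpm": expression,
            "mutations": mutations,
        }
        scans = {}
        for gene in relaxed:
            prof = effect.values[gene]
            for kind_name, fm in feature_sets.items():
                if fm is None:
                    continue
                tab = dependency_feature_correlations(prof, fm, config.min_pair_obs)
                fname = f"correlates_{gene}_{kind_name}.tsv"
                tab.to_csv(out / fname, sep="\t")
                scans[f"{gene}:{kind_name}"] = fname
        if scans:
            report["stages"]["biomarker"] = {"files": scans}
        else:
            report["skipped"].append("biomarker (no feature matrices)")

        # --- copy-number window scan ----------------------------------------
        stage = "cn_window"
        if coords is not None and copy_number is not None and truth is not None:
            anchor = truth.window_anchor["anchor"]
            dep = truth.window_anchor["dependency_gene"]
            ranked = dependency_feature_correlations(
                effect.values[dep], copy_number, config.min_pair_obs, ascending=False
            )
            scan = window_enrichment_scan(anchor, coords, ranked, config)
            report["stages"]["cn_window"] = {
                "anchor": anchor,
                "dependency_gene": dep,
                "selected_window_bp": scan.selected.window_bp,
                "selected_p": scan.selected.p_perm,
                "selected_es": scan.selected.es,
                "windows": [
                    {"w": r.window_bp, "p": r.p_perm, "es": r.es, "n": r.n_in_ranking}
                    for r in scan.windows
                ],
            }
        elif coords is None:
            report["skipped"].append("cn_window (no gene coordinates)")
        else:
            report["skipped"].append("cn_window (no anchor nomination available)")

        # --- ISG signature ----------------------------------------------------
        stage = "signatures"
        if expression is not None:
            zmad = zmad_transform(expression, config.zmad_scale_mode)
            isg = load_isg_core_signature()
            scores = signature_score(zmad, isg["ISG_CORE"], "ISG_CORE")
            ranking = lineage_ranking(
                scores,
                meta,
                min_lines=config.lineage_min_lines,
                exclude=tuple(config.lineage_exclude),
            )
            ranking.table.to_csv(out / "isg_lineage_ranking.tsv", sep="\t")
            report["stages"]["signatures"] = {
                "group_rank": ranking.group_rank,
                "n_lineages_retained": int(len(ranking.table)) - 1,
                "exclusions": ranking.exclusion_log,
                "file": "isg_lineage_ranking.tsv",
            }
        else:
            report["skipped"].append("signatures (no expression matrix)")

    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
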