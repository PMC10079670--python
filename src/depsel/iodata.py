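"""Data model and file I/O shared by all analysis stages.

Matrices follow the DepMap tabular convention: one header row of gene
identifiers (optionally ``"SYMBOL (ID)"``, reduced to ``SYMBOL`` on read),
one leading column of cell-line identifiers, numeric or empty cells.
Coordinates are 0-based half-open (BED); gene sets are GMT; interaction
edges are TSV with a confidence column.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("depsel")

__all__ = [
    "Measure",
    "FeatureKind",
    "ScoreMatrix",
    "PanelMetadata",
    "FeatureMatrix",
    "GeneCoords",
    "GeneSetCollection",
    "InteractionTable",
    "RunConfig",
    "read_score_matrix",
    "write_score_matrix",
    "read_feature_table",
    "write_feature_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_coords",
    "write_gene_coords",
    "read_metadata",
    "write_metadata",
    "read_interaction_table",
    "load_isg_core_signature",
]

_SYMBOL_ID_RE = re.compile(r"^\s*(\S.*?)\s*\(\s*[^)]*\)\s*$")


class Measure(str, enum.Enum):
    """What a screen score matrix measures."""

    gene_effect = "gene_effect"
    dependency_probability = "dependency_probability"


class FeatureKind(str, enum.Enum):
    """What a feature matrix contains."""

    expression_log2tpm = "expression_log2tpm"
    expression_tpm = "expression_tpm"
    copy_number = "copy_number"
    mutation_binary = "mutation_binary"


def _strip_symbol_id(header: str) -> str:
    """Reduce a DepMap-style ``"SYMBOL (ID)"`` header to ``SYMBOL``."""
    m = _SYMBOL_ID_RE.match(header)
    return m.group(1) if m else header.strip()


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if not i:
            raise ValueError(f"empty {what} identifier")
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ScoreMatrix:
    """Cell lines x genes matrix of screen scores.

    ``values`` is a float DataFrame (rows: cell-line ids, columns: gene
    symbols); NaN marks missing. Dependency-probability values must lie in
    [0, 1] where present.
    """

    values: pd.DataFrame
    measure: Measure

    def __post_init__(self) -> None:
        self.measure = Measure(self.measure)
        _check_unique(self.values.index.astype(str), "cell line")
        _check_unique(self.values.columns.astype(str), "gene")
        if self.measure is Measure.dependency_probability:
            bad = self.values[(self.values < 0) | (self.values > 1)]
            stacked = bad.stack()
            if len(stacked):
                cell, gene = stacked.index[0]
                raise ValueError(
                    "dependency probability outside [0, 1]: "
                    f"value {stacked.iloc[0]!r} at (cell line {cell!r}, gene {gene!r}); "
                    f"{len(stacked)} offending cell(s) total"
                )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def load_report(self) -> dict:
        return {
            "rows": int(self.values.shape[0]),
            "cols": int(self.values.shape[1]),
            "missing": self.n_missing,
        }


@dataclass
class PanelMetadata:
    """Per-cell-line annotations: disease-group membership and lineage.

    ``table`` is indexed by cell-line id with columns ``group_flag`` (bool)
    and ``lineage`` (string or NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index.astype(str), "cell line")
        missing = {"group_flag", "lineage"} - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table["group_flag"] = self.table["group_flag"].astype(bool)

    @property
    def group_lines(self) -> list[str]:
        return list(self.table.index[self.table["group_flag"]])

    @property
    def reference_lines(self) -> list[str]:
        return list(self.table.index[~self.table["group_flag"]])

    def require_two_per_arm(self) -> None:
        if len(self.group_lines) < 2 or len(self.reference_lines) < 2:
            raise ValueError(
                "differential analysis needs >=2 group and >=2 reference lines; "
                f"got {len(self.group_lines)} group, {len(self.reference_lines)} reference"
            )

    def covers(self, cell_lines: Iterable[str]) -> list[str]:
        """Return cell lines absent from the metadata (empty if fully covered)."""
        return [c for c in cell_lines if c not in self.table.index]


@dataclass
class FeatureMatrix:
    """Cell lines x features matrix for biomarker scans.

    Feature ids are gene symbols, optionally suffixed ``"GENE|variant_class"``
    for per-variant-class mutation indicators.
    """

    values: pd.DataFrame
    kind: FeatureKind

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        _check_unique(self.values.index.astype(str), "cell line")
        _check_unique(self.values.columns.astype(str), "feature")
        if self.kind is FeatureKind.mutation_binary:
            arr = self.values.to_numpy(dtype=float)
            ok = np.isnan(arr) | (arr == 0) | (arr == 1)
            if not ok.all():
                r, c = np.argwhere(~ok)[0]
                raise ValueError(
                    f"mutation value not in {{0, 1}}: {arr[r, c]!r} at "
                    f"(cell line {self.values.index[r]!r}, feature {self.values.columns[c]!r})"
                )
        elif self.kind is FeatureKind.expression_tpm:
            if (self.values < 0).any().any():
                stacked = self.values[self.values < 0].stack()
                cell, feat = stacked.index[0]
                raise ValueError(
                    f"negative TPM value {stacked.iloc[0]!r} at "
                    f"(cell line {cell!r}, feature {feat!r})"
                )

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def load_report(self) -> dict:
        return {
            "rows": int(self.values.shape[0]),
            "cols": int(self.values.shape[1]),
            "missing": self.n_missing,
        }


@dataclass
class GeneCoords:
    """Gene genomic intervals, 0-based half-open, one record per symbol.

    ``table`` is indexed by gene symbol with columns ``chromosome``,
    ``start``, ``end`` and derived ``midpoint`` = floor((start + end) / 2).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index.astype(str), "gene")
        bad = self.table[self.table["start"] >= self.table["end"]]
        if len(bad):
            g = bad.index[0]
            raise ValueError(
                f"gene {g!r}: start {bad.loc[g, 'start']} >= end {bad.loc[g, 'end']}"
            )
        if (self.table["start"] < 0).any():
            raise ValueError("negative interval start")
        if "midpoint" not in self.table.columns:
            self.table = self.table.assign(
                midpoint=(self.table["start"] + self.table["end"]) // 2
            )

    def midpoint(self, gene: str) -> int:
        return int(self.table.loc[gene, "midpoint"])

    def chromosome(self, gene: str) -> str:
        return str(self.table.loc[gene, "chromosome"])

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with a provenance string."""

    sets: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class InteractionTable:
    """Undirected interaction edges with confidence in [0, 1].

    Edges are normalized on construction: endpoints sorted, self-edges
    dropped, duplicate pairs collapsed to their maximum confidence.
    """

    edges: pd.DataFrame  # columns gene_a, gene_b, confidence

    def __post_init__(self) -> None:
        e = self.edges.copy()
        if not {"gene_a", "gene_b", "confidence"} <= set(e.columns):
            raise ValueError("interaction table needs columns gene_a, gene_b, confidence")
        if ((e["confidence"] < 0) | (e["confidence"] > 1)).any():
            raise ValueError("interaction confidence outside [0, 1]")
        n_self = int((e["gene_a"] == e["gene_b"]).sum())
        if n_self:
            log.warning("dropping %d self-edge(s) from interaction table", n_self)
            e = e[e["gene_a"] != e["gene_b"]]
        lo = e[["gene_a", "gene_b"]].min(axis=1)
        hi = e[["gene_a", "gene_b"]].max(axis=1)
        e = pd.DataFrame({"gene_a": lo, "gene_b": hi, "confidence": e["confidence"]})
        e = (
            e.groupby(["gene_a", "gene_b"], as_index=False)["confidence"]
            .max()
            .reset_index(drop=True)
        )
        self.edges = e


@dataclass
class RunConfig:
    """All thresholds and seeds of a pipeline run; YAML-serializable.

    Defaults are the published analysis constants: nomination gates
    (stringent P < 0.01 with |lfc| > 0.5 on both score types; relaxed
    P < 0.02, |lfc effect| > 0.4, |lfc probability| > 0.3; direction gate at
    mean group dependency probability 0.5), co-essentiality edge threshold
    0.18, interaction confidence 0.4, window grid 5e5..5e6 bp step 5e5, and
    the normalized-AUC constants G = 200, p_min = 52.
    """

    stringent_p: float = 0.01
    stringent_lfc: float = 0.5
    relaxed_p_effect: float = 0.02
    relaxed_lfc_effect: float = 0.4
    relaxed_lfc_prob: float = 0.3
    direction_prob_cutoff: float = 0.5
    direction_at_stringent: bool = True
    lfc_as_ratio_of_means: bool = False
    coessentiality_threshold: float = 0.18
    interaction_min_confidence: float = 0.4
    min_pair_obs: int = 3
    window_min_bp: int = 500_000
    window_max_bp: int = 5_000_000
    window_step_bp: int = 500_000
    window_include_anchor: bool = True
    window_inclusive_bounds: bool = True
    n_permutations: int = 1000
    auc_list_max: int = 200
    auc_p_min: float = 52.0
    zmad_scale_mode: str = "mean_abs_dev_from_median"
    lineage_min_lines: int = 2
    lineage_exclude: tuple[str, ...] = ("Engineered",)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stringent_p",
            "stringent_lfc",
            "relaxed_p_effect",
            "relaxed_lfc_effect",
            "relaxed_lfc_prob",
            "coessentiality_threshold",
            "interaction_min_confidence",
            "window_min_bp",
            "window_max_bp",
            "window_step_bp",
            "n_permutations",
            "auc_list_max",
            "auc_p_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an explicit integer")

    def window_grid(self) -> list[int]:
        return list(
            range(self.window_min_bp, self.window_max_bp + 1, self.window_step_bp)
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["lineage_exclude"] = list(self.lineage_exclude)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "lineage_exclude" in d:
            d["lineage_exclude"] = tuple(d["lineage_exclude"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# tabular readers / writers


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".bed", ".txt"} else ","


def _read_matrix(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    use_sep = _sniff_sep(path, sep)
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter=use_sep))
    raw_cols = [_strip_symbol_id(c) for c in header[1:]]
    _check_unique(raw_cols, "gene/feature")  # pandas would mangle duplicates
    df = pd.read_csv(path, sep=use_sep, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = raw_cols
    _check_unique(df.index, "cell line")
    na_tokens = {"", "NA", "NaN", "nan", "na"}
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df.iloc[:, j]
        cleaned = raw.where(~raw.astype(str).str.strip().isin(na_tokens))
        try:
            out[col] = pd.to_numeric(cleaned)
        except (ValueError, TypeError):
            for i, v in enumerate(cleaned):
                if pd.isna(v):
                    continue
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell {v!r} at (row {df.index[i]!r}, column {col!r}) "
                        f"in {path}"
                    ) from None
            raise
    return out


def read_score_matrix(
    path: str | Path, measure: Measure | str, sep: str | None = None
) -> ScoreMatrix:
    """Read a DepMap-style score matrix (CSV/TSV; empty or NA cells = missing)."""
    m = ScoreMatrix(_read_matrix(path, sep), Measure(measure))
    log.info("loaded score matrix %s: %s", path, m.load_report())
    return m


def write_score_matrix(m: ScoreMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sniff_sep(path, sep))


def read_feature_table(
    path: str | Path, kind: FeatureKind | str, sep: str | None = None
) -> FeatureMatrix:
    """Read a feature matrix; values validated per kind."""
    m = FeatureMatrix(_read_matrix(path, sep), FeatureKind(kind))
    log.info("loaded feature table %s (%s): %s", path, m.kind.value, m.load_report())
    return m


def write_feature_table(m: FeatureMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sniff_sep(path, sep))


def read_metadata(path: str | Path, sep: str | None = None) -> PanelMetadata:
    """Read panel metadata (columns: cell_line_id, group_flag, lineage)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0)
    truthy = {"true", "1", "yes", "group"}
    df["group_flag"] = [
        str(v).strip().lower() in truthy for v in df["group_flag"]
    ]
    df["lineage"] = df["lineage"].where(df["lineage"].notna() & (df["lineage"] != ""))
    return PanelMetadata(df)


def write_metadata(meta: PanelMetadata, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    out = meta.table.copy()
    out.index.name = "cell_line_id"
    out.to_csv(path, sep=_sniff_sep(path, sep))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(parts)} field(s), need >=3"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = {g.strip() for g in parts[2:] if g.strip()}
            sets[name] = members
    if not sets:
        log.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, provenance=str(path)) if sets else GeneSetCollection(
        {}, provenance=str(path)
    )


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.items():
            fh.write("\t".join([name, coll.provenance or "na", *sorted(members)]) + "\n")


def read_gene_coords(path: str | Path) -> GeneCoords:
    """Read gene intervals from BED (chrom, start, end, name; 0-based half-open)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not parts[3].strip():
                raise ValueError(f"{path}:{lineno}: BED line needs chrom/start/end/name")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"]).set_index(
        "gene"
    )
    return GeneCoords(df)


def write_gene_coords(coords: GeneCoords, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, row in coords.table.iterrows():
            fh.write(
                f"{row['chromosome']}\t{int(row['start'])}\t{int(row['end'])}\t{gene}\n"
            )


def read_interaction_table(path: str | Path, sep: str | None = None) -> InteractionTable:
    """Read an undirected edge list TSV (gene_a, gene_b, confidence)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    return InteractionTable(df[["gene_a", "gene_b", "confidence"]])


def load_isg_core_signature() -> GeneSetCollection:
    """Load the packaged 38-gene interferon-stimulated-gene core signature."""
    with resources.as_file(
        resources.files("depsel").joinpath("data/isg_core.gmt")
    ) as p:
        return read_gene_sets(p)
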