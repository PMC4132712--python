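"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated UTF-8 with a header row and "." as the
decimal point. Lines starting with ``#`` are provenance/comment lines and are
skipped on read. Gene and sample identifiers are case-sensitive opaque
strings; no symbol normalization is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigurationError, FormatError, InputError

#: Reserved negative-control condition label (a scramble siRNA in the assay).
DEFAULT_CONTROL_LABEL = "NC"

CT_COLUMNS = ["condition", "gene", "replicate", "ct_target", "ct_reference"]
MATRIX_COLUMNS = [
    "knockdown",
    "measured_gene",
    "mean_ddct",
    "sd_ddct",
    "log2_ratio",
    "ratio",
    "p_value",
    "n",
]


# ---------------------------------------------------------------------------
# Expression compendium
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCompendium:
    """Gene x sample non-negative expression matrix with sample groups.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample, in
        arbitrary linear-scale units (CAGE tags-per-million, microarray
        intensity).
    groups
        Series mapping every sample (index) to its group label, e.g.
        ``"fibroblast"`` or a cell-type name.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            gene_i, samp_i = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                "non-finite expression value at gene "
                f"{self.values.index[gene_i]!r}, sample "
                f"{self.values.columns[samp_i]!r}"
            )
        if (arr < 0).any():
            gene_i, samp_i = np.argwhere(arr < 0)[0]
            raise FormatError(
                "negative expression value at gene "
                f"{self.values.index[gene_i]!r}, sample "
                f"{self.values.columns[samp_i]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise AnnotationError(
                f"samples missing a group label: {', '.join(map(repr, missing))}"
            )
        # restrict annotation to the matrix's samples, preserving matrix order
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        """Samples carrying ``group`` as their label, in matrix order."""
        return list(self.groups.index[self.groups == group])


def read_group_annotation(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) TSV into a Series."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: group annotation needs columns (sample, group)")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample in annotation: {dup!r}")
    return pd.Series(
        df[group_col].astype(str).to_numpy(), index=df[sample_col].astype(str)
    )


def read_expression_matrix(
    path: str | Path, group_annotation: str | Path | pd.Series | Mapping[str, str]
) -> ExpressionCompendium:
    """Read a gene x sample expression TSV plus its sample-group annotation.

    First column holds gene identifiers; remaining columns are samples. Every
    sample column must appear in the annotation.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    values = df.set_index(gene_col)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if isinstance(group_annotation, (str, Path)):
        groups = read_group_annotation(group_annotation)
    elif isinstance(group_annotation, pd.Series):
        groups = group_annotation.astype(str)
    else:
        groups = pd.Series(dict(group_annotation), dtype=str)
    return ExpressionCompendium(values=values, groups=groups)


def write_expression_matrix(
    compendium: ExpressionCompendium,
    path: str | Path,
    groups_path: str | Path | None = None,
    header: Sequence[str] = (),
) -> None:
    """Write the compendium matrix (and optionally its annotation) as TSV."""
    out = compendium.values.copy()
    out.insert(0, "gene", out.index)
    _write_tsv(out, path, header)
    if groups_path is not None:
        ann = pd.DataFrame(
            {"sample": compendium.groups.index, "group": compendium.groups.to_numpy()}
        )
        _write_tsv(ann, groups_path, header)


# ---------------------------------------------------------------------------
# CT tables
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold records for one Matrix-RNAi run.

    One row per (condition, measured gene, biological replicate) carrying the
    target-gene CT and the reference-gene (GAPDH) CT. ``control_label`` names
    the negative-control (scramble siRNA) condition, which must be present.
    """

    records: pd.DataFrame
    control_label: str = DEFAULT_CONTROL_LABEL
    replicate_count: int = 4

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = [c for c in CT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"CT table missing columns: {missing_cols}")
        df = df[CT_COLUMNS].copy()
        df["condition"] = df["condition"].astype(str)
        df["gene"] = df["gene"].astype(str)
        try:
            df["replicate"] = df["replicate"].astype(int)
            df[["ct_target", "ct_reference"]] = df[
                ["ct_target", "ct_reference"]
            ].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric CT table value ({exc})") from exc
        cts = df[["ct_target", "ct_reference"]].to_numpy()
        if not np.isfinite(cts).all() or (cts <= 0).any():
            bad = df.iloc[int(np.argwhere(~(np.isfinite(cts) & (cts > 0)))[0][0])]
            raise FormatError(
                "CT values must be finite and > 0; offending record "
                f"({bad.condition!r}, {bad.gene!r}, replicate {bad.replicate})"
            )
        key = ["condition", "gene", "replicate"]
        if df.duplicated(key).any():
            bad = df[df.duplicated(key)].iloc[0]
            raise FormatError(
                "duplicate CT record for "
                f"({bad.condition!r}, {bad.gene!r}, replicate {bad.replicate})"
            )
        if self.control_label not in set(df["condition"]):
            raise InputError(
                f"negative-control condition {self.control_label!r} absent from table"
            )
        self.records = df

    @property
    def conditions(self) -> list[str]:
        """All conditions in first-appearance order, control included."""
        return list(dict.fromkeys(self.records["condition"]))

    @property
    def knockdowns(self) -> list[str]:
        return [c for c in self.conditions if c != self.control_label]

    def delta_cts(self, condition: str, gene: str) -> pd.Series:
        """Replicate-indexed ΔCT (target − reference) for one cell."""
        sub = self.records[
            (self.records["condition"] == condition) & (self.records["gene"] == gene)
        ]
        return pd.Series(
            (sub["ct_target"] - sub["ct_reference"]).to_numpy(),
            index=sub["replicate"].to_numpy(),
        ).sort_index()


def read_ct_table(
    path: str | Path, control_label: str = DEFAULT_CONTROL_LABEL
) -> CtTable:
    """Read a long-format CT table TSV; the control condition must be present."""
    df = _read_tsv(path)
    return CtTable(records=df, control_label=control_label)


def write_ct_table(table: CtTable, path: str | Path, header: Sequence[str] = ()) -> None:
    _write_tsv(table.records, path, header)


# ---------------------------------------------------------------------------
# Perturbation matrix (summarized, S3-style entry point)
# ---------------------------------------------------------------------------


def read_perturbation_matrix(path: str | Path):
    """Read a summarized perturbation matrix from long-format TSV.

    Accepts the full statistic set written by :func:`write_perturbation_matrix`
    or a reduced table carrying at least (knockdown, measured_gene,
    log2_ratio[, p_value]) — the pre-summarized entry point for published
    supplementary matrices that ship ratios and p-values but not raw CTs.
    """
    from .ddct import DdctStat, PerturbationMatrix

    df = _read_tsv(path)
    for col in ("knockdown", "measured_gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: perturbation matrix missing column {col!r}")
    if "log2_ratio" not in df.columns and "mean_ddct" not in df.columns:
        raise FormatError(f"{path}: need a log2_ratio or mean_ddct column")
    cells = {}
    for _, row in df.iterrows():
        kd = str(row["knockdown"])
        gene = str(row["measured_gene"])
        if "log2_ratio" in df.columns and not _isna(row.get("log2_ratio")):
            log2_ratio = float(row["log2_ratio"])
            mean_ddct = -log2_ratio
        else:
            mean_ddct = float(row["mean_ddct"])
            log2_ratio = -mean_ddct
        stat = DdctStat(
            knockdown=kd,
            measured_gene=gene,
            mean_ddct=mean_ddct,
            sd_ddct=_optfloat(row.get("sd_ddct"), default=math.nan),
            p_value=_optfloat(row.get("p_value"), default=math.nan),
            n=int(row["n"]) if "n" in df.columns and not _isna(row.get("n")) else 0,
        )
        if (kd, gene) in cells:
            raise FormatError(f"{path}: duplicate cell ({kd!r}, {gene!r})")
        cells[(kd, gene)] = stat
    tfs = sorted({k for k, _ in cells} | {g for _, g in cells})
    return PerturbationMatrix(tfs=tfs, cells=cells)


def write_perturbation_matrix(matrix, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write a perturbation matrix as long-format TSV (one row per cell)."""
    _write_tsv(matrix.to_frame(), path, header)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_SIGN_RELATION = {"activating": "activates", "inhibiting": "inhibits"}
_RELATION_SIGN = {v: k for k, v in _SIGN_RELATION.items()}


def write_network(
    network, path: str | Path, format: str = "tsv", header: Sequence[str] = ()
) -> None:
    """Write a regulatory network as SIF, TSV or GraphML.

    SIF lines are ``source<TAB>relation<TAB>target`` with relation in
    {activates, inhibits} (Cytoscape simple interaction format); TSV adds
    log2_ratio and p_value columns; GraphML carries the same attributes.
    """
    path = Path(path)
    if format == "sif":
        lines = [f"# {h}" for h in header]
        lines += [
            f"{e.source}\t{_SIGN_RELATION[e.sign]}\t{e.target}" for e in network.edges
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "tsv":
        df = pd.DataFrame(
            {
                "source": [e.source for e in network.edges],
                "relation": [_SIGN_RELATION[e.sign] for e in network.edges],
                "target": [e.target for e in network.edges],
                "log2_ratio": [e.log2_ratio for e in network.edges],
                "p_value": [e.p_value for e in network.edges],
            }
        )
        _write_tsv(df, path, header)
    elif format == "graphml":
        g = network.to_networkx()
        nx.write_graphml(g, path)
    else:
        raise ConfigurationError(
            f"unknown network format {format!r}; use sif, tsv or graphml"
        )


def read_network(path: str | Path, format: str = "tsv"):
    """Read a network written by :func:`write_network` back into memory."""
    from .network import RegulatoryEdge, RegulatoryNetwork

    path = Path(path)
    edges = []
    nodes: list[str] = []
    if format == "sif":
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            src, rel, tgt = line.split("\t")
            edges.append(
                RegulatoryEdge(
                    source=src,
                    target=tgt,
                    sign=_RELATION_SIGN[rel],
                    log2_ratio=math.nan,
                    p_value=math.nan,
                )
            )
    elif format == "tsv":
        df = _read_tsv(path)
        for _, row in df.iterrows():
            edges.append(
                RegulatoryEdge(
                    source=str(row["source"]),
                    target=str(row["target"]),
                    sign=_RELATION_SIGN[str(row["relation"])],
                    log2_ratio=_optfloat(row.get("log2_ratio"), default=math.nan),
                    p_value=_optfloat(row.get("p_value"), default=math.nan),
                )
            )
    elif format == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        for src, tgt, data in g.edges(data=True):
            edges.append(
                RegulatoryEdge(
                    source=src,
                    target=tgt,
                    sign=data["sign"],
                    log2_ratio=float(data.get("log2_ratio", math.nan)),
                    p_value=float(data.get("p_value", math.nan)),
                )
            )
    else:
        raise ConfigurationError(
            f"unknown network format {format!r}; use sif, tsv or graphml"
        )
    for e in edges:
        for n in (e.source, e.target):
            if n not in nodes:
                nodes.append(n)
    return RegulatoryNetwork(nodes=nodes, edges=edges)


def write_node_attributes(
    network,
    path: str | Path,
    classes: Mapping[str, str] | None = None,
    efficacy: Mapping[str, float] | None = None,
    header: Sequence[str] = (),
) -> None:
    """Write per-node attribute TSV: node, out_degree, in_degree, class, efficacy."""
    rows = []
    for node in network.nodes:
        rows.append(
            {
                "node": node,
                "out_degree": network.out_degree[node],
                "in_degree": network.in_degree[node],
                "class": (classes or {}).get(node, ""),
                "knockdown_efficacy": (efficacy or {}).get(node, math.nan),
            }
        )
    _write_tsv(pd.DataFrame(rows), path, header)


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", dtype=None)


def _write_tsv(df: pd.DataFrame, path: str | Path, header: Sequence[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        not isinstance(value, (int, float)) and pd.isna(value)
    )


def _optfloat(value, default: float) -> float:
    if _isna(value):
        return default
    return float(value)
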