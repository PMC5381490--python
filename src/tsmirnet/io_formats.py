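"""Readers and writers for the standard formats the pipeline touches.

Genomic intervals are BED-convention throughout: 0-based, half-open
``[start, end)``.  Expression tables, target tables, tissue labels and PPI
edge lists are tab-separated text with a header row.  Networks are emitted
as SIF, GraphML, or a self-describing edge TSV; every writer has a matching
reader and the pair round-trips the typed edge multiset and node attributes.

The tissue vocabulary is fixed to the twelve human tissues the analysis is
defined over; readers match tissue names case-insensitively but always
return the canonical lower-case labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: The twelve tissues every expression matrix and per-tissue statistic runs over.
TISSUES: tuple[str, ...] = (
    "heart",
    "skeletal muscle",
    "lung",
    "bone",
    "kidney",
    "liver",
    "placenta",
    "testis",
    "brain",
    "spleen",
    "thymus",
    "pancreas",
)

NETWORK_FORMATS = ("sif", "graphml", "edge-tsv")


class FormatError(ValueError):
    """A file could not be parsed in the expected dialect."""


class SchemaError(FormatError):
    """A parsed file has the wrong columns / tissue set."""


class ValidationError(FormatError):
    """A parsed file violates a value-level invariant (negative copy number...)."""


# ---------------------------------------------------------------------------
# TFBS / BED
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFBSRecord:
    """One ChIP-seq transcription-factor binding site, 0-based half-open."""

    tf_name: str
    chrom: str
    start: int
    end: int
    score: float | None = None
    source_tissue: str | None = None

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValidationError("TFBSRecord requires a non-empty tf_name")
        if self.start < 0:
            raise ValidationError(f"TFBS start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"TFBS start must be < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValidationError(f"TFBS score must be non-negative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_tfbs_bed(path: str | Path) -> list[TFBSRecord]:
    """Read TF binding sites from a BED file (>=4 columns, name = TF symbol).

    Column 5 is kept as the score when numeric and non-negative, otherwise
    ignored (UCSC track dialects vary).  ``track``/``browser``/``#`` lines
    are skipped.  Malformed lines raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    records: list[TFBSRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: BED line needs >=4 columns "
                    f"(chrom, start, end, name), got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if not name:
                raise FormatError(f"{path}:{lineno}: empty name column")
            score: float | None = None
            if len(fields) >= 5:
                try:
                    candidate = float(fields[4])
                    if candidate >= 0:
                        score = candidate
                except ValueError:
                    score = None
            tissue = fields[5] if len(fields) >= 6 and fields[5] not in ("", ".") else None
            try:
                records.append(
                    TFBSRecord(name, chrom, start, end, score=score, source_tissue=tissue)
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_tfbs_bed(records: Iterable[TFBSRecord], path: str | Path) -> None:
    """Write TFBS records back out as BED; coordinates are preserved bit-exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fields = [rec.chrom, str(rec.start), str(rec.end), rec.tf_name]
            if rec.score is not None or rec.source_tissue is not None:
                fields.append("" if rec.score is None else format(rec.score, "g"))
            if rec.source_tissue is not None:
                fields.append(rec.source_tissue)
            fh.write("\t".join(fields) + "\n")


def write_bed_intervals(
    intervals: Iterable[tuple[str, int, int, str, str]], path: str | Path
) -> None:
    """Write generic (chrom, start, end, name, strand) rows as BED6."""
    with Path(path).open("w") as fh:
        for chrom, start, end, name, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Non-negative copy numbers for entities (miRNAs or TFs) over the 12 tissues.

    Thin wrapper over a pandas DataFrame whose columns are exactly the
    canonical tissue labels, in canonical order, and whose index holds
    unique entity identifiers.
    """

    def __init__(self, data: pd.DataFrame, tissues: Sequence[str] = TISSUES):
        tissues = tuple(tissues)
        if list(data.columns) != list(tissues):
            raise SchemaError(
                f"expected columns {list(tissues)}, got {list(data.columns)}"
            )
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate entity ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative values")
        self.data = data.astype(float)
        self.tissues = tissues

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    def row(self, entity_id: str) -> np.ndarray:
        return self.data.loc[entity_id].to_numpy(dtype=float)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.data.index

    def __len__(self) -> int:
        return len(self.data)


def _canonicalize_tissue_columns(
    columns: Sequence[str], expected: Sequence[str]
) -> list[str]:
    lookup = {t.strip().lower(): t for t in expected}
    out: list[str] = []
    for col in columns:
        key = str(col).strip().lower().replace("_", " ")
        if key not in lookup:
            raise SchemaError(f"unknown tissue column {col!r}; expected one of {list(expected)}")
        out.append(lookup[key])
    return out


def read_expression_table(
    path: str | Path, expected_tissues: Sequence[str] = TISSUES
) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column entity ids, 12 tissue columns.

    Columns are matched to ``expected_tissues`` case-insensitively and
    reordered into canonical order.  Missing/extra tissues raise
    :class:`SchemaError`; negative values, missing cells, or duplicate ids
    raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    canonical = _canonicalize_tissue_columns(df.columns, expected_tissues)
    if len(set(canonical)) != len(canonical):
        raise SchemaError(f"{path}: duplicated tissue columns")
    df.columns = canonical
    missing = [t for t in expected_tissues if t not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing tissue columns {missing}")
    df = df[list(expected_tissues)]
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric expression cell ({exc})") from exc
    return ExpressionMatrix(df, expected_tissues)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="entity")


# ---------------------------------------------------------------------------
# Target tables, tissue labels, PPI
# ---------------------------------------------------------------------------

TARGET_COLUMNS = ["mirna", "gene", "evidence", "context_score"]


def validate_target_table(df: pd.DataFrame, origin: str = "target table") -> pd.DataFrame:
    """Check the verified/predicted evidence contract on a target table.

    ``evidence == 'predicted'`` rows must carry a context score;
    ``evidence == 'verified'`` rows must not.
    """
    for col in ("mirna", "gene", "evidence"):
        if col not in df.columns:
            raise SchemaError(f"{origin}: missing column {col!r}")
    if "context_score" not in df.columns:
        df = df.assign(context_score=np.nan)
    bad_evidence = set(df["evidence"]) - {"verified", "predicted"}
    if bad_evidence:
        raise ValidationError(f"{origin}: unknown evidence values {sorted(bad_evidence)}")
    scores = pd.to_numeric(df["context_score"], errors="coerce")
    predicted = df["evidence"] == "predicted"
    if scores[predicted].isna().any():
        raise ValidationError(f"{origin}: predicted rows must carry a context_score")
    if scores[~predicted].notna().any():
        raise ValidationError(f"{origin}: verified rows must not carry a context_score")
    out = df.copy()
    out["context_score"] = scores
    return out[TARGET_COLUMNS]


def read_target_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_target_table(df, origin=str(path))


def write_target_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_target_table(df).to_csv(path, sep="\t", index=False)


def read_tissue_gene_labels(
    path: str | Path, expected_tissues: Sequence[str] = TISSUES
) -> pd.DataFrame:
    """Read (gene, tissue) tissue-specific expression labels."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "tissue"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    df = df.copy()
    df["tissue"] = _canonicalize_tissue_columns(df["tissue"], expected_tissues)
    return df[["gene", "tissue"]]


def read_ppi_table(path: str | Path) -> pd.DataFrame:
    """Read an undirected protein-protein interaction edge list (two id columns)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: PPI table needs two id columns")
    df = df.iloc[:, :2]
    df.columns = ["protein_a", "protein_b"]
    return df


def read_mirna_annotation(path: str | Path) -> pd.DataFrame:
    """Read a miRNA locus table (name, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    required = ["name", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[required].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: locus with start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: strand must be '+' or '-'")
    return df


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read an experimental TSS table (mirna, chrom, tss)."""
    df = pd.read_csv(path, sep="\t")
    required = ["mirna", "chrom", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[required].copy()
    df["tss"] = df["tss"].astype(int)
    return df


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (alias, mature) miRNA alias map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: alias table needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------


def _edge_sort_key(item):
    u, v, data = item
    return (data.get("edge_type", ""), str(u), str(v), json.dumps(data, sort_keys=True))


def write_network(graph: nx.MultiDiGraph, path: str | Path, format: str = "edge-tsv") -> None:
    """Write a typed regulatory graph as SIF, GraphML or edge TSV.

    SIF keeps only (source, interaction, target) triples — the interaction
    token is the edge type with ``-`` for ``_``.  GraphML and edge-TSV carry
    every node and edge attribute.  Output row order is deterministic.
    """
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    if format == "sif":
        with path.open("w") as fh:
            for u, v, data in sorted(graph.edges(data=True), key=_edge_sort_key):
                token = data.get("edge_type", "edge").replace("_", "-")
                fh.write(f"{u}\t{token}\t{v}\n")
    elif format == "graphml":
        # GraphML attribute values must be scalars; None attributes are dropped.
        clean = nx.MultiDiGraph()
        for node, attrs in graph.nodes(data=True):
            clean.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, key, attrs in graph.edges(keys=True, data=True):
            clean.add_edge(u, v, key=key, **{k: v for k, v in attrs.items() if v is not None})
        nx.write_graphml(clean, path)
    else:  # edge-tsv
        with path.open("w") as fh:
            fh.write("kind\tsource\ttarget\ttype\tattrs\n")
            for node in sorted(graph.nodes, key=str):
                attrs = {k: v for k, v in graph.nodes[node].items() if k != "node_type"}
                fh.write(
                    "node\t%s\t\t%s\t%s\n"
                    % (node, graph.nodes[node].get("node_type", ""), json.dumps(attrs, sort_keys=True))
                )
            for u, v, data in sorted(graph.edges(data=True), key=_edge_sort_key):
                attrs = {k: v for k, v in data.items() if k != "edge_type"}
                fh.write(
                    "edge\t%s\t%s\t%s\t%s\n"
                    % (u, v, data.get("edge_type", ""), json.dumps(attrs, sort_keys=True))
                )


def read_network(path: str | Path, format: str = "edge-tsv") -> nx.MultiDiGraph:
    """Read a graph written by :func:`write_network` (same format token)."""
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    graph = nx.MultiDiGraph()
    if format == "sif":
        with path.open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(f"{path}: bad SIF line {line!r}")
                u, token, v = parts
                graph.add_edge(u, v, edge_type=token.replace("-", "_"))
    elif format == "graphml":
        loaded = nx.read_graphml(path, force_multigraph=True)
        for node, attrs in loaded.nodes(data=True):
            graph.add_node(node, **attrs)
        for u, v, key, attrs in loaded.edges(keys=True, data=True):
            graph.add_edge(u, v, key=key, **attrs)
    else:
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("kind\t"):
                raise FormatError(f"{path}: missing edge-tsv header")
            for line in fh:
                kind, a, b, typ, attrs_json = line.rstrip("\n").split("\t")
                attrs = json.loads(attrs_json) if attrs_json else {}
                if kind == "node":
                    graph.add_node(a, node_type=typ or None, **attrs)
                    if typ == "":
                        del graph.nodes[a]["node_type"]
                elif kind == "edge":
                    graph.add_edge(a, b, edge_type=typ, **attrs)
                else:
                    raise FormatError(f"{path}: unknown record kind {kind!r}")
    return graph


def edge_multiset(graph: nx.MultiDiGraph) -> list[tuple[str, str, str]]:
    """The typed edge multiset (source, edge_type, target), sorted — for round trips."""
    return sorted(
        (str(u), data.get("edge_type", ""), str(v)) for u, v, data in graph.edges(data=True)
    )
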