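"""Assembly of the four-layer regulatory graph and its edge-count summaries.

One :class:`networkx.MultiDiGraph` per tissue (or "all"): TF->miRNA,
TF->gene and miRNA->gene layers are directed; PPI edges are semantically
undirected and stored once with ``edge_type='ppi'``.  Nodes carry a
``node_type`` in {tf, mirna, gene}; TF nodes can be annotated with their
focal-tissue TSVT and specificity category.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import TISSUES
from .regulation import EDGE_TYPES, RegulatoryEdge
from .specificity import SpecificityProfile

#: Display labels for the edge-count summary rows.
EDGE_TYPE_LABELS = {
    "ppi": "Protein-protein interactions",
    "tf_gene": "Edges TF->target genes",
    "mirna_gene": "Edges TS miRNAs->target genes",
    "tf_mirna": "Edges TF->TS miRNA",
}

_ENDPOINT_TYPES = {
    "tf_mirna": ("tf", "mirna"),
    "tf_gene": ("tf", "gene"),
    "mirna_gene": ("mirna", "gene"),
    "ppi": ("protein", "protein"),
}

# a TF is also a protein-coding gene product; these pairs may coexist on a node
_COMPATIBLE = {frozenset(("tf", "gene")), frozenset(("tf", "protein")),
               frozenset(("gene", "protein"))}


class NodeTypeConflictError(ValueError):
    """An entity id is used with incompatible node types across layers."""


def _resolve_type(existing: str | None, new: str, entity: str) -> str:
    if existing is None or existing == new:
        return new
    pair = frozenset((existing, new))
    if pair in _COMPATIBLE:
        # tf wins over gene/protein; gene wins over bare protein
        for preferred in ("tf", "gene"):
            if preferred in pair:
                return preferred
    raise NodeTypeConflictError(
        f"entity {entity!r} used both as {existing} and as {new}"
    )


def _edge_in_tissue(edge: RegulatoryEdge, tissue: str) -> bool:
    # tissue-agnostic edges (empty attribution) participate in every view
    return tissue == "all" or not edge.tissues or tissue in edge.tissues


def build_network(
    tf_mirna: Iterable[RegulatoryEdge] = (),
    tf_gene: Iterable[RegulatoryEdge] = (),
    mirna_gene: Iterable[RegulatoryEdge] = (),
    ppi: Iterable[RegulatoryEdge] = (),
    tissue: str = "all",
    tf_profiles: Mapping[str, SpecificityProfile] | None = None,
) -> nx.MultiDiGraph:
    """Union the four edge layers into one typed multigraph.

    ``tissue`` filters edges on their tissue attribution ("all" keeps
    everything; tissue-agnostic edges are kept in every view).  Parallel
    edges of different types between the same pair are retained.  TF nodes
    get ``tsvt``/``category`` attributes from ``tf_profiles`` when given.
    """
    if tissue != "all" and tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    graph = nx.MultiDiGraph(tissue=tissue)
    node_types: dict[str, str] = {}

    layers = (
        ("tf_mirna", tf_mirna),
        ("tf_gene", tf_gene),
        ("mirna_gene", mirna_gene),
        ("ppi", ppi),
    )
    for expected_type, edges in layers:
        src_type, dst_type = _ENDPOINT_TYPES[expected_type]
        for edge in edges:
            if edge.edge_type != expected_type:
                raise ValueError(
                    f"edge {edge.source}->{edge.target} has type {edge.edge_type}, "
                    f"expected {expected_type}"
                )
            if not _edge_in_tissue(edge, tissue):
                continue
            node_types[edge.source] = _resolve_type(
                node_types.get(edge.source), src_type, edge.source
            )
            node_types[edge.target] = _resolve_type(
                node_types.get(edge.target), dst_type, edge.target
            )
            attrs: dict = {"edge_type": edge.edge_type}
            if edge.tissues:
                attrs["tissues"] = ",".join(sorted(edge.tissues))
            if edge.site_count is not None:
                attrs["site_count"] = int(edge.site_count)
            if edge.evidence is not None:
                attrs["evidence"] = edge.evidence
            if edge.score is not None:
                attrs["score"] = float(edge.score)
            graph.add_edge(edge.source, edge.target, **attrs)

    for node, node_type in node_types.items():
        # PPI-only endpoints default to gene (protein products of genes)
        graph.nodes[node]["node_type"] = "gene" if node_type == "protein" else node_type
    if tf_profiles:
        for node, node_type in node_types.items():
            profile = tf_profiles.get(node)
            if profile is None or graph.nodes[node]["node_type"] != "tf":
                continue
            if profile.category is not None:
                graph.nodes[node]["category"] = profile.category
            if tissue != "all" and tissue in profile.tsvt:
                graph.nodes[node]["tsvt"] = float(profile.tsvt[tissue])
    return graph


def edges_of_type(graph: nx.MultiDiGraph, edge_type: str) -> list[tuple[str, str]]:
    return [
        (u, v) for u, v, data in graph.edges(data=True) if data.get("edge_type") == edge_type
    ]


def summarize_edge_counts(
    graphs: Mapping[str, nx.MultiDiGraph],
    tissues: Sequence[str] = TISSUES,
) -> pd.DataFrame:
    """Edge counts per type and tissue, with row and column totals.

    Rows are the four interaction layers (labelled as in the published
    summary table), columns the 12 tissues plus "total"; the "total" row
    sums the layers.
    """
    table = pd.DataFrame(
        0, index=[EDGE_TYPE_LABELS[t] for t in EDGE_TYPES], columns=list(tissues)
    )
    for tissue in tissues:
        graph = graphs.get(tissue)
        if graph is None:
            continue
        for edge_type in EDGE_TYPES:
            table.loc[EDGE_TYPE_LABELS[edge_type], tissue] = len(
                edges_of_type(graph, edge_type)
            )
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "interactions"
    return table
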