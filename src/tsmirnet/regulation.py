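"""Post-scan analytics on TF–miRNA regulatory relations.

Covers the tissue-occurrence distribution of TF–miRNA relations, consistent
same-tissue TF–miRNA pairs, verified-first target-gene selection, and the
per-tissue Fisher's-exact enrichment of target genes among tissue-specific
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, TISSUES, validate_target_table
from .specificity import SpecificityProfile, TSCall

logger = logging.getLogger(__name__)

EDGE_TYPES = ("tf_mirna", "tf_gene", "mirna_gene", "ppi")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A typed edge of the multi-layer network, with optional tissue attribution.

    ``tissues`` is the set of tissues the edge is attributed to; an empty set
    means tissue-agnostic (the edge participates in every per-tissue view).
    """

    edge_type: str
    source: str
    target: str
    tissues: frozenset[str] = frozenset()
    site_count: int | None = None
    evidence: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        unknown = set(self.tissues) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissues {sorted(unknown)} on edge "
                             f"{self.source}->{self.target}")


@dataclass
class OccurrenceResult:
    """Tissue-occurrence statistics of TF->miRNA relations."""

    per_edge: pd.DataFrame          # tf, mirna, n_tissues, tissues
    histogram: pd.Series            # occurrence count (0..12) -> number of edges
    per_tissue: pd.DataFrame        # tissue x occurrence-count fractions
    skipped_tfs: list[str] = field(default_factory=list)


def tissue_occurrence(
    edges: Iterable[RegulatoryEdge],
    tf_expr: ExpressionMatrix,
    presence_threshold: float = 0.0,
) -> OccurrenceResult:
    """In how many tissues can each TF->miRNA relation occur?

    A relation occurs in tissue t when its TF's copy number there is
    strictly above ``presence_threshold`` (default 0).  Returns the per-edge
    occurrence counts, the histogram of edges over occurrence counts 0..12,
    and, per tissue, the fraction of that tissue's edges in each occurrence
    bin.  Edges whose TF is absent from the matrix are excluded (and listed).
    """
    tissues = list(tf_expr.tissues)
    rows = []
    skipped: list[str] = []
    for edge in edges:
        if edge.edge_type != "tf_mirna":
            raise ValueError("tissue_occurrence expects tf_mirna edges")
        if edge.source not in tf_expr:
            if edge.source not in skipped:
                logger.warning("TF %s absent from expression matrix; edge skipped", edge.source)
                skipped.append(edge.source)
            continue
        expr_row = tf_expr.row(edge.source)
        present = [t for t, x in zip(tissues, expr_row) if x > presence_threshold]
        rows.append(
            {
                "tf": edge.source,
                "mirna": edge.target,
                "n_tissues": len(present),
                "tissues": ",".join(present),
            }
        )
    per_edge = pd.DataFrame(rows, columns=["tf", "mirna", "n_tissues", "tissues"])
    counts = np.zeros(13, dtype=int)
    for n in per_edge["n_tissues"]:
        counts[n] += 1
    histogram = pd.Series(counts, index=range(13), name="n_edges")
    histogram.index.name = "n_tissues"

    per_tissue = pd.DataFrame(0.0, index=tissues, columns=range(1, 13))
    for tissue in tissues:
        mask = per_edge["tissues"].str.split(",").apply(lambda ts, t=tissue: t in ts)
        sub = per_edge[mask & (per_edge["n_tissues"] > 0)]
        if len(sub):
            frac = sub["n_tissues"].value_counts(normalize=True)
            for n, f in frac.items():
                per_tissue.loc[tissue, n] = f
    return OccurrenceResult(per_edge, histogram, per_tissue, skipped)


def find_consistent_pairs(
    edges: Iterable[RegulatoryEdge],
    tf_profiles: Mapping[str, SpecificityProfile],
    ts_calls: Mapping[str, TSCall] | Iterable[TSCall],
    tsvt_threshold: float = -2.5,
) -> pd.DataFrame:
    """TF->miRNA relations where both partners are specific to the same tissue.

    Emits one (tissue, tf, mirna) row per shared tissue: the edge exists, the
    TF's TSVT in that tissue exceeds ``tsvt_threshold``, and the miRNA's
    tissue-specific call includes that tissue (either tissue for dual-tissue
    miRNAs).
    """
    if not isinstance(ts_calls, Mapping):
        ts_calls = {c.mirna_name: c for c in ts_calls}
    rows = []
    for edge in edges:
        if edge.edge_type != "tf_mirna":
            continue
        profile = tf_profiles.get(edge.source)
        call = ts_calls.get(edge.target)
        if profile is None or call is None:
            continue
        tf_tissues = {t for t, v in profile.tsvt.items() if v > tsvt_threshold}
        for tissue in sorted(tf_tissues & set(call.tissues)):
            rows.append({"tissue": tissue, "tf": edge.source, "mirna": edge.target})
    out = pd.DataFrame(rows, columns=["tissue", "tf", "mirna"])
    return out.drop_duplicates().sort_values(["tissue", "tf", "mirna"]).reset_index(drop=True)


def select_targets(
    mirna: str,
    verified: pd.DataFrame,
    predicted: pd.DataFrame,
    score_cutoff: float = -0.3,
) -> pd.DataFrame:
    """Verified-first target selection for one miRNA.

    If any experimentally verified (miRNA, gene) rows exist, exactly those
    are returned and the predicted table is ignored.  Otherwise predicted
    rows with total context score strictly below ``score_cutoff`` are
    returned.  Both inputs are validated target tables.
    """
    verified = validate_target_table(verified, "verified targets")
    predicted = validate_target_table(predicted, "predicted targets")
    mine = verified[verified["mirna"] == mirna]
    if len(mine):
        return mine.reset_index(drop=True)
    pred = predicted[
        (predicted["mirna"] == mirna) & (predicted["context_score"] < score_cutoff)
    ]
    return pred.reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """Per-tissue Fisher's-exact enrichment of targets among tissue-specific genes."""

    tissue: str
    table: tuple[tuple[int, int], tuple[int, int]]
    proportion: float | None
    odds_ratio: float | None
    p_value: float | None
    adjusted_p: float | None = None

    @property
    def tested(self) -> bool:
        return self.p_value is not None


def _labels_to_map(gene_labels) -> dict[str, set[str]]:
    if isinstance(gene_labels, pd.DataFrame):
        out: dict[str, set[str]] = {}
        for gene, tissue in zip(gene_labels["gene"], gene_labels["tissue"]):
            out.setdefault(gene, set()).add(tissue)
        return out
    return {g: (set(t) if not isinstance(t, str) else {t}) for g, t in gene_labels.items()}


def target_tissue_enrichment(
    targets_by_tissue: Mapping[str, Iterable[str]],
    gene_labels,
    background: Iterable[str],
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Are tissue-t miRNA targets enriched among tissue-t-specific genes?

    For each tissue t the 2x2 table crosses (target of t's miRNAs vs other
    background genes) with (labelled specific-in-t vs not); Fisher's exact
    test (``alternative`` defaults to two-sided, "greater" gives the
    one-sided enrichment variant) plus Benjamini–Hochberg adjustment across
    the tested tissues.  ``proportion`` is the fraction of t's targets
    labelled specific in t.  Tissues with no targets are flagged (no test).
    """
    labels = _labels_to_map(gene_labels)
    universe = set(background)
    results: list[EnrichmentResult] = []
    for tissue in TISSUES:
        if tissue not in targets_by_tissue:
            continue
        targets = set(targets_by_tissue[tissue])
        extra = targets - universe
        if extra:
            raise ValueError(f"{tissue}: targets outside background universe: {sorted(extra)[:5]}")
        if not targets:
            results.append(EnrichmentResult(tissue, ((0, 0), (0, 0)), None, None, None))
            continue
        specific = {g for g in universe if tissue in labels.get(g, ())}
        a = len(targets & specific)
        b = len(targets) - a
        rest = universe - targets
        c = len(rest & specific)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        results.append(
            EnrichmentResult(
                tissue=tissue,
                table=((a, b), (c, d)),
                proportion=a / len(targets),
                odds_ratio=float(odds),
                p_value=float(p),
            )
        )
    tested = [r for r in results if r.tested]
    if tested:
        _, adj, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, q in zip(tested, adj):
            r.adjusted_p = float(q)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per tissue)."""
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        rows.append(
            {
                "tissue": r.tissue,
                "n_targets": a + b,
                "n_specific_targets": a,
                "proportion": r.proportion,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "significant_raw": (r.p_value is not None and r.p_value < 0.05),
            }
        )
    return pd.DataFrame(rows)
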