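"""The curated catalog of experimentally supported tissue-specific miRNAs.

Ships as package data: the 12-tissue catalog of mature TS miRNAs, the
genomic-context clusters reported alongside it (members named as annotated,
mixing precursor copies like ``miR-1-2`` with mature names), and the small
alias map (``miR-208a`` -> ``miR-208`` and similar precursor-family
aliases).  After name normalization the catalog resolves to 116 distinct
mature miRNAs, 12 of them specific to exactly two tissues; clustered-member
fractions per tissue (e.g. 40/43 in placenta, 9/14 in testis) are recomputed
from these tables, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .genomics import normalize_mirna_name
from .io_formats import TISSUES


def _data_path(name: str):
    return resources.files("tsmirnet").joinpath("data", name)


def load_alias_map() -> dict[str, str]:
    with resources.as_file(_data_path("mirna_aliases.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["alias"], df["mature"]))


def load_catalog() -> pd.DataFrame:
    """(tissue, raw_name, mirna) — one row per printed tissue/miRNA entry."""
    alias = load_alias_map()
    with resources.as_file(_data_path("ts_mirna_catalog.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"mirna": "raw_name"})
    df["mirna"] = [normalize_mirna_name(n, alias) for n in df["raw_name"]]
    return df[["tissue", "raw_name", "mirna"]]


def load_clusters(known_mature=None) -> pd.DataFrame:
    """(tissue, cluster, raw_member, mirna) — cluster members normalized.

    Precursor copy suffixes are stripped against the catalog's mature
    vocabulary plus the alias keys, then aliases applied.
    """
    alias = load_alias_map()
    if known_mature is None:
        known_mature = set(load_catalog()["mirna"])
    with resources.as_file(_data_path("ts_mirna_clusters.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"member": "raw_member"})
    df["mirna"] = [
        normalize_mirna_name(n, alias, known_mature) for n in df["raw_member"]
    ]
    return df[["tissue", "cluster", "raw_member", "mirna"]]


@dataclass
class CatalogSummary:
    """Distinct/dual-tissue counts and per-tissue clustered fractions."""

    n_distinct: int
    dual_tissue: tuple[str, ...]
    per_tissue: pd.DataFrame  # tissue, n_mirnas, n_clustered, pct_clustered


def summarize_catalog() -> CatalogSummary:
    """Recount the catalog: distinct mature miRNAs, dual-tissue ones, clustering.

    A tissue's clustered fraction is the number of its distinct mature
    miRNAs that appear in any of its clusters, over its distinct total.
    """
    catalog = load_catalog()
    clusters = load_clusters()
    per_mirna_tissues = catalog.groupby("mirna")["tissue"].apply(lambda s: frozenset(s))
    dual = tuple(sorted(per_mirna_tissues[per_mirna_tissues.map(len) == 2].index))

    rows = []
    for tissue in TISSUES:
        members = set(catalog.loc[catalog["tissue"] == tissue, "mirna"])
        clustered = set(clusters.loc[clusters["tissue"] == tissue, "mirna"]) & members
        rows.append(
            {
                "tissue": tissue,
                "n_mirnas": len(members),
                "n_clustered": len(clustered),
                "pct_clustered": 100.0 * len(clustered) / len(members) if members else 0.0,
            }
        )
    return CatalogSummary(
        n_distinct=catalog["mirna"].nunique(),
        dual_tissue=dual,
        per_tissue=pd.DataFrame(rows),
    )
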