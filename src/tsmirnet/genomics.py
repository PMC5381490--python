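"""Genomic geometry: miRNA naming, cluster calling, TSS/promoter logic, TFBS scanning.

All coordinates are 0-based half-open.  "Upstream" is always relative to the
transcribed strand: a promoter is 5 kb upstream plus 1 kb downstream of the
TSS, which on the minus strand is the genomic interval
``[tss - downstream, tss + upstream)``.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import TFBSRecord
from .regulation import RegulatoryEdge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiRNALocus:
    """A miRNA hairpin locus with its normalized mature name."""

    raw_name: str
    canonical_name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.raw_name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.raw_name}: strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """The 5' coordinate: left edge on +, right edge on -."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class MiRNACluster:
    """>=2 miRNA loci within 10 kb of each other on the same strand."""

    members: tuple[MiRNALocus, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")
        strands = {m.strand for m in self.members}
        chroms = {m.chrom for m in self.members}
        if len(strands) != 1 or len(chroms) != 1:
            raise ValueError("cluster members must share chromosome and strand")

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def strand(self) -> str:
        return self.members[0].strand

    @property
    def span_start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def span_end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def five_prime(self) -> int:
        """The cluster's transcriptional start: 5'-most coordinate on its strand."""
        return self.span_start if self.strand == "+" else self.span_end


@dataclass(frozen=True)
class PromoterRegion:
    """The putative TF-binding window around a TSS (upstream + downstream)."""

    owner: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    tss_source: str  # experimental | cluster_start | locus_start


_PREFIX_RE = re.compile(r"^(hsa-)?(mir|miR|MIR|Mir)-", re.IGNORECASE)
_COPY_SUFFIX_RE = re.compile(r"-(1|2|3)$")


def normalize_mirna_name(
    raw: str,
    alias_map: Mapping[str, str] | None = None,
    known_mature: Iterable[str] | None = None,
) -> str:
    """Normalize a miRNA annotation name to its canonical mature form.

    Steps, in order: case-normalize the prefix ("mir-"/"hsa-miR-" -> "miR-");
    strip a trailing precursor copy suffix "-1"/"-2"/"-3" when the remaining
    stem is a known mature name (or alias); apply the alias map last
    (e.g. miR-208a -> miR-208).  Unknown names pass through prefix-normalized.
    """
    if not raw:
        raise ValueError("empty miRNA name")
    name = raw.strip()
    if _PREFIX_RE.match(name):
        name = "miR-" + _PREFIX_RE.sub("", name)
    alias_map = dict(alias_map or {})
    known = set(known_mature or ()) | set(alias_map)
    stem = _COPY_SUFFIX_RE.sub("", name)
    if stem != name and stem in known:
        name = stem
    return alias_map.get(name, name)


def loci_from_frame(
    annotation: pd.DataFrame,
    alias_map: Mapping[str, str] | None = None,
    known_mature: Iterable[str] | None = None,
) -> list[MiRNALocus]:
    """Build normalized loci from an annotation frame (name/chrom/start/end/strand)."""
    return [
        MiRNALocus(
            raw_name=row["name"],
            canonical_name=normalize_mirna_name(row["name"], alias_map, known_mature),
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
        )
        for _, row in annotation.iterrows()
    ]


def call_mirna_clusters(
    loci: Iterable[MiRNALocus], max_gap_bp: int = 10_000
) -> list[MiRNACluster]:
    """Group loci into clusters: same chromosome and strand, consecutive gaps <= 10 kb.

    The gap between positional neighbours is ``next.start - previous.end``
    (floored at 0 for overlaps).  Singletons are not clusters.  Output is
    ordered by (chrom, strand, span_start) and invariant to input order.
    """
    by_group: dict[tuple[str, str], list[MiRNALocus]] = defaultdict(list)
    for locus in loci:
        by_group[(locus.chrom, locus.strand)].append(locus)

    clusters: list[MiRNACluster] = []
    for key in sorted(by_group):
        members = sorted(by_group[key], key=lambda m: (m.start, m.end, m.canonical_name))
        run: list[MiRNALocus] = [members[0]]
        run_end = members[0].end
        for locus in members[1:]:
            gap = max(0, locus.start - run_end)
            if gap <= max_gap_bp:
                run.append(locus)
                run_end = max(run_end, locus.end)
            else:
                if len(run) >= 2:
                    clusters.append(MiRNACluster(tuple(run)))
                run = [locus]
                run_end = locus.end
        if len(run) >= 2:
            clusters.append(MiRNACluster(tuple(run)))
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.span_start))
    return clusters


def assign_tss(
    locus: MiRNALocus,
    tss_table: Mapping[str, tuple[str, int]] | None,
    clusters: Sequence[MiRNACluster] = (),
) -> tuple[int, str]:
    """Pick the TSS for a locus: experimental > cluster 5' start > locus 5' end.

    ``tss_table`` maps canonical miRNA names to (chrom, coordinate).  A
    clustered locus without experimental evidence inherits its cluster's
    5'-most coordinate (span_start on +, span_end on -).
    """
    if tss_table and locus.canonical_name in tss_table:
        chrom, tss = tss_table[locus.canonical_name]
        if chrom != locus.chrom:
            raise ValueError(
                f"{locus.canonical_name}: experimental TSS on {chrom} but locus on {locus.chrom}"
            )
        return int(tss), "experimental"
    for cluster in clusters:
        if locus in cluster.members:
            return cluster.five_prime, "cluster_start"
    return locus.five_prime, "locus_start"


def define_promoter(
    tss: int,
    strand: str,
    upstream_bp: int = 5_000,
    downstream_bp: int = 1_000,
    chrom_length: int | None = None,
    chrom: str = "",
    owner: str = "",
    tss_source: str = "experimental",
) -> PromoterRegion:
    """The promoter window around a TSS, strand-aware and clamped to the chromosome.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand the
    mirror image ``[tss - downstream, tss + upstream)``.  ``chrom_length``
    of None skips the right-edge clamp.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if tss < 0 or (chrom_length is not None and tss > chrom_length):
        raise ValueError(f"TSS {tss} outside chromosome [0, {chrom_length}]")
    if strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp
    else:
        start, end = tss - downstream_bp, tss + upstream_bp
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterRegion(owner, chrom, start, end, strand, tss, tss_source)


def promoters_for_loci(
    loci: Sequence[MiRNALocus],
    tss_table: Mapping[str, tuple[str, int]] | None = None,
    max_gap_bp: int = 10_000,
    upstream_bp: int = 5_000,
    downstream_bp: int = 1_000,
    chrom_length: int | None = None,
) -> list[PromoterRegion]:
    """Cluster loci, assign TSSs, and build one promoter per distinct mature miRNA.

    When several loci share a canonical name (precursor copies) the first by
    position wins, so each miRNA owns exactly one promoter.
    """
    clusters = call_mirna_clusters(loci, max_gap_bp)
    promoters: dict[str, PromoterRegion] = {}
    for locus in sorted(loci, key=lambda m: (m.chrom, m.start, m.end)):
        if locus.canonical_name in promoters:
            continue
        tss, source = assign_tss(locus, tss_table, clusters)
        promoters[locus.canonical_name] = define_promoter(
            tss,
            locus.strand,
            upstream_bp,
            downstream_bp,
            chrom_length,
            chrom=locus.chrom,
            owner=locus.canonical_name,
            tss_source=source,
        )
    return list(promoters.values())


def scan_promoters(
    promoters: Sequence[PromoterRegion],
    tfbs: Sequence[TFBSRecord],
    min_overlap_bp: int = 1,
    edge_type: str = "tf_mirna",
) -> list[RegulatoryEdge]:
    """Scan TFBS against promoter windows; one deduplicated edge per (TF, owner) pair.

    An edge exists when at least one binding site of the TF overlaps the
    owner's promoter by ``min_overlap_bp`` or more (half-open arithmetic);
    the number of supporting sites is kept as ``site_count``.  Interval
    trees make this near-linear; a brute-force all-pairs oracle is used to
    test it.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, rec in enumerate(tfbs):
        trees[rec.chrom].addi(rec.start, rec.end, i)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for prom in promoters:
        tree = trees.get(prom.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(prom.start, prom.end):
            rec = tfbs[iv.data]
            overlap = min(prom.end, rec.end) - max(prom.start, rec.start)
            if overlap >= min_overlap_bp:
                counts[(rec.tf_name, prom.owner)] += 1
    return [
        RegulatoryEdge(edge_type=edge_type, source=tf, target=owner, site_count=n)
        for (tf, owner), n in sorted(counts.items())
    ]


@dataclass
class BindingProfile:
    """TSS-relative TF occupancy: per-tissue percentages over 200-bp bins."""

    matrix: pd.DataFrame          # tissues x bins; columns are bin start offsets
    empty_tissues: list[str]      # tissues with zero TFBS (all-zero rows, flagged)
    bin_bp: int


def compute_binding_profile(
    promoters: Sequence[PromoterRegion],
    tfbs_by_tissue: Mapping[str, Sequence[TFBSRecord]],
    bin_bp: int = 200,
    upstream_bp: int = 5_000,
    downstream_bp: int = 1_000,
) -> BindingProfile:
    """Bin TFBS into the TSS-relative window and normalize per tissue.

    The window is ``[-upstream, +downstream)`` in transcription-oriented
    coordinates (on the minus strand offsets run against the genome).  A
    site increments every bin it overlaps, so a site spanning k bins counts
    k times; each tissue's counts are divided by that tissue's total number
    of sites and scaled to percent, so bin percentages may sum above 100.
    """
    window = upstream_bp + downstream_bp
    if window % bin_bp:
        raise ValueError(f"bin width {bin_bp} must divide the {window}-bp window")
    n_bins = window // bin_bp
    bin_starts = [-upstream_bp + i * bin_bp for i in range(n_bins)]

    tissues = list(tfbs_by_tissue)
    matrix = pd.DataFrame(0.0, index=tissues, columns=bin_starts)
    empty: list[str] = []
    for tissue, records in tfbs_by_tissue.items():
        total = len(records)
        if total == 0:
            empty.append(tissue)
            continue
        counts = np.zeros(n_bins)
        for rec in records:
            for prom in promoters:
                if prom.chrom != rec.chrom:
                    continue
                # transcription-relative half-open interval of the site
                if prom.strand == "+":
                    rel_start, rel_end = rec.start - prom.tss, rec.end - prom.tss
                else:
                    rel_start, rel_end = prom.tss - rec.end, prom.tss - rec.start
                lo = max(rel_start, -upstream_bp)
                hi = min(rel_end, downstream_bp)
                if hi <= lo:
                    continue
                first = (lo + upstream_bp) // bin_bp
                last = (hi - 1 + upstream_bp) // bin_bp
                counts[first : last + 1] += 1
        matrix.loc[tissue] = counts / total * 100.0
    return BindingProfile(matrix, empty, bin_bp)
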