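"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

The three generators emulate, at desk scale, the shape of the real inputs:

* a genome fixture — clustered and isolated miRNA loci on one synthetic
  chromosome, experimental TSSs for a fraction of loci, and TFBS drawn from
  a near-TSS mode plus a secondary distal upstream mode, with uniform
  background sites;
* an expression fixture — miRNA and TF copy-number matrices over the 12
  tissues with planted fold-changes (planted rows are set exactly, so the
  fold arithmetic is exact), multiplicative log-normal background noise,
  and one exactly-uniform TF row;
* a target fixture — verified/predicted target tables, tissue-specific gene
  labels and a PPI edge list, with a tunable enrichment effect linking the
  targets of a tissue's miRNAs to that tissue's gene labels
  (``enrichment_effect = 1`` makes labels independent of targeting — the
  null used for type-I-error calibration).

Everything is a pure function of the :class:`FixtureConfig`; identical
configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import genomics
from .io_formats import (
    ExpressionMatrix,
    TFBSRecord,
    TISSUES,
    write_bed_intervals,
    write_expression_table,
    write_target_table,
    write_tfbs_bed,
)

_CHROM = "chrS"

# per-generator seed-stream domains, so generators are independent of call order
_DOM_GENOME, _DOM_EXPR, _DOM_TARGET, _DOM_PLANT = 1, 2, 3, 4


class FixtureConfigError(ValueError):
    """The requested fixture is internally inconsistent or does not fit."""


@dataclass(frozen=True)
class FixtureConfig:
    """All knobs of the synthetic fixtures, with study-condition defaults.

    Defaults mirror the structure the analysis assumes: miRNA clusters under
    the 10-kb rule with roughly half of miRNAs clustered, planted
    tissue-specific fold-changes of 100 (above the 80-fold screen), a
    promoter TFBS mode at the TSS plus a distal mode 3.5 kb upstream, and a
    5x odds effect for target-gene tissue enrichment.
    """

    seed: int = 0
    n_tissues: int = 12
    n_mirnas: int = 60
    n_tfs: int = 30
    n_genes: int = 2_000
    n_clusters: int = 10
    cluster_size: int = 3
    intra_cluster_gap_bp: int = 2_000
    inter_cluster_gap_bp: int = 50_000
    planted_ts_fold: float = 100.0
    n_planted_ts_mirnas: int = 12
    n_planted_ts_tfs: int = 6
    promoter_hit_rate: float = 3.0
    distal_mode_offset_bp: int = 3_500
    distal_fraction: float = 0.3
    enrichment_effect: float = 5.0
    n_targets_per_tissue: int = 200
    ts_gene_label_rate: float = 0.6
    verified_fraction: float = 0.5
    n_ppi: int = 300
    n_background_tfbs: int = 200
    tss_fraction: float = 0.5
    chrom_length: int = 20_000_000
    noise_sigma: float = 0.3
    baseline_expression: float = 10.0

    def validate(self) -> None:
        counts = {
            "n_mirnas": self.n_mirnas,
            "n_tfs": self.n_tfs,
            "n_genes": self.n_genes,
            "n_clusters": self.n_clusters,
            "cluster_size": self.cluster_size,
        }
        for name, value in counts.items():
            if value <= 0:
                raise FixtureConfigError(f"{name} must be positive, got {value}")
        if self.n_tissues != 12:
            raise FixtureConfigError("the analysis is defined over exactly 12 tissues")
        if self.intra_cluster_gap_bp >= self.inter_cluster_gap_bp:
            raise FixtureConfigError("intra-cluster gap must be smaller than inter-cluster gap")
        if self.intra_cluster_gap_bp > 10_000:
            raise FixtureConfigError("intra-cluster gaps above 10 kb would not be clusters")
        if self.inter_cluster_gap_bp <= 10_000:
            raise FixtureConfigError("inter-cluster gap must exceed the 10-kb cluster rule")
        if self.planted_ts_fold <= 1:
            raise FixtureConfigError("planted_ts_fold must exceed 1")
        if self.cluster_size < 2:
            raise FixtureConfigError("cluster_size must be at least 2")
        if self.n_clusters * self.cluster_size > self.n_mirnas:
            raise FixtureConfigError("n_clusters * cluster_size exceeds n_mirnas")
        if self.n_planted_ts_mirnas > self.n_mirnas:
            raise FixtureConfigError("cannot plant more tissue-specific miRNAs than exist")
        if self.n_planted_ts_tfs >= self.n_tfs:
            raise FixtureConfigError("need at least one unplanted TF (the uniform control)")
        if self.n_targets_per_tissue > self.n_genes:
            raise FixtureConfigError("n_genes too small for the requested target-table margins")
        if not 0 <= self.ts_gene_label_rate <= 1:
            raise FixtureConfigError("ts_gene_label_rate must lie in [0, 1]")
        if self.enrichment_effect <= 0:
            raise FixtureConfigError("enrichment_effect must be positive")

    def with_overrides(self, **kwargs) -> "FixtureConfig":
        return replace(self, **kwargs)


def _rng(config: FixtureConfig, domain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), domain]))


def mirna_names(config: FixtureConfig) -> list[str]:
    return [f"miR-s{i:03d}" for i in range(config.n_mirnas)]


def tf_names(config: FixtureConfig) -> list[str]:
    return [f"TF{i:03d}" for i in range(config.n_tfs)]


def gene_names(config: FixtureConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(config.n_genes)]


def planted_assignment(config: FixtureConfig) -> pd.DataFrame:
    """Which entities are planted tissue-specific, and where.

    Shared between the expression and target fixtures so that tissue-t
    miRNAs in the target tables are exactly the ones whose expression is
    planted in t.  Home tissues cycle through the 12-tissue vocabulary.
    The last TF is reserved as the exactly-uniform control.
    """
    config.validate()
    rng = _rng(config, _DOM_PLANT)
    mirnas = rng.choice(mirna_names(config), size=config.n_planted_ts_mirnas, replace=False)
    tfs = rng.choice(
        tf_names(config)[:-1], size=config.n_planted_ts_tfs, replace=False
    )
    rows = [
        {"entity": m, "kind": "mirna", "tissue": TISSUES[i % 12]}
        for i, m in enumerate(sorted(mirnas))
    ]
    rows += [
        {"entity": t, "kind": "tf", "tissue": TISSUES[i % 12]}
        for i, t in enumerate(sorted(tfs))
    ]
    rows.append({"entity": tf_names(config)[-1], "kind": "uniform_tf", "tissue": ""})
    return pd.DataFrame(rows, columns=["entity", "kind", "tissue"])


# ---------------------------------------------------------------------------
# Genome fixture
# ---------------------------------------------------------------------------


@dataclass
class GenomeFixture:
    loci: list[genomics.MiRNALocus]
    tss_table: pd.DataFrame                      # mirna, chrom, tss
    tfbs: list[TFBSRecord]
    gene_tss: pd.DataFrame                       # gene, chrom, tss, strand
    planted_promoter_hits: pd.DataFrame          # tf, mirna (sites fully inside the promoter)
    chrom: str = _CHROM


def generate_genome_fixture(config: FixtureConfig) -> GenomeFixture:
    """Lay out clustered and isolated miRNA loci, TSSs, gene TSSs and TFBS.

    Clusters are blocks of ``cluster_size`` same-strand loci with pairwise
    gaps <= ``intra_cluster_gap_bp``; blocks (cluster or singleton) are
    separated by more than ``inter_cluster_gap_bp``, so the 10-kb caller
    recovers exactly the planted clusters.  TFBS are planted inside each
    miRNA promoter from a near-TSS mode plus a distal upstream mode, with
    uniform background sites elsewhere.
    """
    config.validate()
    rng = _rng(config, _DOM_GENOME)
    names = mirna_names(config)
    tfs = tf_names(config)

    n_clustered = config.n_clusters * config.cluster_size
    blocks: list[list[str]] = [
        names[i * config.cluster_size : (i + 1) * config.cluster_size]
        for i in range(config.n_clusters)
    ] + [[n] for n in names[n_clustered:]]
    order = rng.permutation(len(blocks))

    loci: list[genomics.MiRNALocus] = []
    pos = 100_000
    for bi in order:
        block = blocks[bi]
        strand = "+" if rng.random() < 0.5 else "-"
        for j, name in enumerate(block):
            if j > 0:
                pos += int(rng.integers(100, config.intra_cluster_gap_bp + 1))
            length = int(rng.integers(60, 121))
            loci.append(
                genomics.MiRNALocus(name, name, _CHROM, pos, pos + length, strand)
            )
            pos += length
        pos += config.inter_cluster_gap_bp + int(rng.integers(1, 20_000))
    if pos > config.chrom_length // 2:
        raise FixtureConfigError(
            f"loci span {pos} bp; chromosome of {config.chrom_length} bp leaves no gene zone"
        )
    loci.sort(key=lambda m: m.start)

    # experimental TSSs for a random subset, a little upstream of the 5' end
    tss_rows = []
    chosen = rng.random(len(loci)) < config.tss_fraction
    for locus, has_tss in zip(loci, chosen):
        if not has_tss:
            continue
        shift = int(rng.integers(0, 2_001))
        tss = locus.five_prime - shift if locus.strand == "+" else locus.five_prime + shift
        tss_rows.append({"mirna": locus.canonical_name, "chrom": _CHROM, "tss": max(0, tss)})
    tss_table = pd.DataFrame(tss_rows, columns=["mirna", "chrom", "tss"])

    # gene TSSs in a zone clear of the miRNA loci
    gene_zone_start = pos + config.inter_cluster_gap_bp
    gene_rows = []
    gpos = gene_zone_start
    for gene in gene_names(config):
        gpos += int(rng.integers(4_000, 9_000))
        if gpos >= config.chrom_length - 10_000:
            raise FixtureConfigError("gene TSSs do not fit on the configured chromosome")
        gene_rows.append(
            {
                "gene": gene,
                "chrom": _CHROM,
                "tss": gpos,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    gene_tss = pd.DataFrame(gene_rows, columns=["gene", "chrom", "tss", "strand"])

    # TFBS planted in miRNA promoters: near-TSS mode + distal upstream mode
    tss_map = {r["mirna"]: (_CHROM, int(r["tss"])) for r in tss_rows}
    promoters = genomics.promoters_for_loci(
        loci, tss_map, chrom_length=config.chrom_length
    )
    tfbs: list[TFBSRecord] = []
    hit_rows = []
    for prom in promoters:
        n_sites = rng.poisson(config.promoter_hit_rate)
        for _ in range(n_sites):
            if rng.random() < config.distal_fraction:
                rel = rng.normal(-config.distal_mode_offset_bp, 200.0)
            else:
                rel = rng.normal(-150.0, 300.0)
            width = int(rng.integers(50, 401))
            rel = float(np.clip(rel, -4_999 + width, 999 - width))
            if prom.strand == "+":
                center = prom.tss + rel
            else:
                center = prom.tss - rel
            start = int(center - width // 2)
            start = max(prom.start, min(start, prom.end - width))
            tf = str(rng.choice(tfs))
            tfbs.append(
                TFBSRecord(tf, _CHROM, start, start + width,
                           source_tissue=str(rng.choice(TISSUES)))
            )
            hit_rows.append({"tf": tf, "mirna": prom.owner})

    # background sites scattered genome-wide (also over the gene zone)
    for _ in range(config.n_background_tfbs):
        start = int(rng.integers(0, config.chrom_length - 500))
        width = int(rng.integers(50, 401))
        tfbs.append(
            TFBSRecord(str(rng.choice(tfs)), _CHROM, start, start + width,
                       source_tissue=str(rng.choice(TISSUES)))
        )

    planted = (
        pd.DataFrame(hit_rows, columns=["tf", "mirna"])
        .drop_duplicates()
        .sort_values(["tf", "mirna"])
        .reset_index(drop=True)
    )
    return GenomeFixture(loci, tss_table, tfbs, gene_tss, planted)


# ---------------------------------------------------------------------------
# Expression fixture
# ---------------------------------------------------------------------------


@dataclass
class ExpressionFixture:
    mirna_expr: ExpressionMatrix
    tf_expr: ExpressionMatrix
    truth: pd.DataFrame  # entity, kind, tissue, fold


def _background_matrix(rng, names, config: FixtureConfig) -> pd.DataFrame:
    values = config.baseline_expression * rng.lognormal(
        0.0, config.noise_sigma, size=(len(names), 12)
    )
    return pd.DataFrame(values, index=names, columns=list(TISSUES))


def generate_expression_fixture(config: FixtureConfig) -> ExpressionFixture:
    """Copy-number matrices with exact planted fold-changes.

    A planted entity's home-tissue value is set to ``planted_ts_fold`` times
    the mean of its (sampled) other-tissue values — exactly, not sampled —
    so a fold-f plant has fold-change f under the screen's arithmetic.
    Non-planted rows are near-uniform log-normal noise.  The last TF row is
    exactly constant (the uniform-TSPV control).
    """
    config.validate()
    rng = _rng(config, _DOM_EXPR)
    assignment = planted_assignment(config)

    mirna_df = _background_matrix(rng, mirna_names(config), config)
    tf_df = _background_matrix(rng, tf_names(config), config)

    truth_rows = []
    for _, row in assignment.iterrows():
        entity, kind, tissue = row["entity"], row["kind"], row["tissue"]
        if kind == "uniform_tf":
            tf_df.loc[entity] = 25.0
            truth_rows.append({"entity": entity, "kind": kind, "tissue": "", "fold": 1.0})
            continue
        df = mirna_df if kind == "mirna" else tf_df
        others = [t for t in TISSUES if t != tissue]
        df.loc[entity, tissue] = config.planted_ts_fold * df.loc[entity, others].mean()
        truth_rows.append(
            {"entity": entity, "kind": kind, "tissue": tissue, "fold": config.planted_ts_fold}
        )
    truth = pd.DataFrame(truth_rows, columns=["entity", "kind", "tissue", "fold"])
    return ExpressionFixture(
        ExpressionMatrix(mirna_df), ExpressionMatrix(tf_df), truth
    )


# ---------------------------------------------------------------------------
# Target / label / PPI fixture
# ---------------------------------------------------------------------------


@dataclass
class TargetFixture:
    verified: pd.DataFrame       # mirna, gene, evidence, context_score
    predicted: pd.DataFrame
    gene_labels: pd.DataFrame    # gene, tissue
    ppi: pd.DataFrame            # protein_a, protein_b
    truth: pd.DataFrame          # tissue, mirna, gene (the planted target sets)
    background: list[str]


def generate_target_fixture(config: FixtureConfig) -> TargetFixture:
    """Target tables, tissue-specific gene labels and PPI edges.

    Each gene is independently labelled tissue-specific (one uniformly
    chosen tissue) with probability ``ts_gene_label_rate``.  For each tissue
    with planted miRNAs, ``n_targets_per_tissue`` target genes are sampled
    without replacement, weighting genes labelled in that tissue by
    ``enrichment_effect``; at effect 1 the sampling ignores labels entirely,
    so targeting and labelling are independent (the enrichment null).
    Each planted miRNA is either verified-evidence or predicted-evidence;
    predicted planted rows score below the -0.3 cutoff, and chaff predicted
    rows above the cutoff exercise the filter.
    """
    config.validate()
    rng = _rng(config, _DOM_TARGET)
    genes = np.array(gene_names(config))
    assignment = planted_assignment(config)
    mirna_by_tissue: dict[str, list[str]] = {}
    for _, row in assignment[assignment["kind"] == "mirna"].iterrows():
        mirna_by_tissue.setdefault(row["tissue"], []).append(row["entity"])

    labelled = rng.random(len(genes)) < config.ts_gene_label_rate
    label_tissue = rng.choice(len(TISSUES), size=len(genes))
    gene_labels = pd.DataFrame(
        {
            "gene": genes[labelled],
            "tissue": [TISSUES[i] for i in label_tissue[labelled]],
        }
    )
    label_map = dict(zip(gene_labels["gene"], gene_labels["tissue"]))

    verified_rows, predicted_rows, truth_rows = [], [], []
    for tissue in TISSUES:
        mirnas = mirna_by_tissue.get(tissue)
        if not mirnas:
            continue
        weights = np.where(
            [label_map.get(g) == tissue for g in genes], config.enrichment_effect, 1.0
        )
        weights = weights / weights.sum()
        chosen = rng.choice(genes, size=config.n_targets_per_tissue, replace=False, p=weights)
        owner = rng.choice(mirnas, size=len(chosen))
        for gene, mirna in zip(chosen, owner):
            truth_rows.append({"tissue": tissue, "mirna": mirna, "gene": gene})
    truth = pd.DataFrame(truth_rows, columns=["tissue", "mirna", "gene"])

    planted_mirnas = sorted(set(truth["mirna"])) if len(truth) else []
    verified_kind = {
        m: rng.random() < config.verified_fraction for m in planted_mirnas
    }
    for _, row in truth.iterrows():
        if verified_kind[row["mirna"]]:
            verified_rows.append(
                {"mirna": row["mirna"], "gene": row["gene"],
                 "evidence": "verified", "context_score": np.nan}
            )
        else:
            predicted_rows.append(
                {"mirna": row["mirna"], "gene": row["gene"],
                 "evidence": "predicted",
                 "context_score": float(rng.uniform(-0.8, -0.35))}
            )
    # chaff: weak predicted rows (>= -0.3) on predicted-evidence miRNAs only
    for mirna in planted_mirnas:
        if not verified_kind[mirna]:
            for gene in rng.choice(genes, size=3, replace=False):
                predicted_rows.append(
                    {"mirna": mirna, "gene": str(gene), "evidence": "predicted",
                     "context_score": float(rng.uniform(-0.25, -0.05))}
                )

    proteins = np.array(list(genes) + tf_names(config))
    ppi_pairs = set()
    while len(ppi_pairs) < config.n_ppi:
        a, b = rng.choice(proteins, size=2, replace=False)
        ppi_pairs.add((min(a, b), max(a, b)))
    ppi = pd.DataFrame(sorted(ppi_pairs), columns=["protein_a", "protein_b"])

    cols = ["mirna", "gene", "evidence", "context_score"]
    return TargetFixture(
        verified=pd.DataFrame(verified_rows, columns=cols),
        predicted=pd.DataFrame(predicted_rows, columns=cols),
        gene_labels=gene_labels,
        ppi=ppi,
        truth=truth,
        background=list(genes),
    )


# ---------------------------------------------------------------------------
# Writing a fixture to disk (the formats io_formats reads)
# ---------------------------------------------------------------------------


def write_fixture(config: FixtureConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate all three fixtures and write them in pipeline-ready formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome_fixture(config)
    expr = generate_expression_fixture(config)
    targets = generate_target_fixture(config)

    paths = {name: out / fname for name, fname in [
        ("mirna_loci", "mirna_loci.tsv"),
        ("tss", "mirna_tss.tsv"),
        ("tfbs", "tfbs.bed"),
        ("gene_tss", "gene_tss.tsv"),
        ("mirna_expression", "mirna_expression.tsv"),
        ("tf_expression", "tf_expression.tsv"),
        ("verified_targets", "verified_targets.tsv"),
        ("predicted_targets", "predicted_targets.tsv"),
        ("gene_labels", "gene_labels.tsv"),
        ("ppi", "ppi.tsv"),
        ("truth_expression", "truth_expression.tsv"),
        ("truth_targets", "truth_targets.tsv"),
        ("truth_promoter_hits", "truth_promoter_hits.tsv"),
    ]}

    loci_df = pd.DataFrame(
        [
            {"name": m.raw_name, "chrom": m.chrom, "start": m.start,
             "end": m.end, "strand": m.strand}
            for m in genome.loci
        ]
    )
    loci_df.to_csv(paths["mirna_loci"], sep="\t", index=False)
    genome.tss_table.to_csv(paths["tss"], sep="\t", index=False)
    write_tfbs_bed(genome.tfbs, paths["tfbs"])
    genome.gene_tss.to_csv(paths["gene_tss"], sep="\t", index=False)
    write_expression_table(expr.mirna_expr, paths["mirna_expression"])
    write_expression_table(expr.tf_expr, paths["tf_expression"])
    write_target_table(targets.verified, paths["verified_targets"])
    write_target_table(targets.predicted, paths["predicted_targets"])
    targets.gene_labels.to_csv(paths["gene_labels"], sep="\t", index=False)
    targets.ppi.to_csv(paths["ppi"], sep="\t", index=False)
    expr.truth.to_csv(paths["truth_expression"], sep="\t", index=False)
    targets.truth.to_csv(paths["truth_targets"], sep="\t", index=False)
    genome.planted_promoter_hits.to_csv(paths["truth_promoter_hits"], sep="\t", index=False)
    return paths
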