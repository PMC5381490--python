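"""End-to-end orchestration of the tissue-specific miRNA network analysis.

``run_pipeline`` composes the stages in dependency order — name
normalization, the fold-change screen, cluster calling, TSS and promoter
assignment, TFBS scanning, the TSS-relative binding profile, TF specificity
scoring, occurrence/consistency analytics, target selection, enrichment,
and network assembly — writing every stage's table to the output directory
and returning a manifest of record counts and input checksums.  Identical
configuration and inputs reproduce identical stage outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, genomics, io_formats, network, regulation, specificity

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths plus every tunable constant of the analysis."""

    # inputs
    mirna_loci: str | None = None
    mirna_tss: str | None = None
    tfbs: str | None = None
    mirna_expression: str | None = None
    tf_expression: str | None = None
    verified_targets: str | None = None
    predicted_targets: str | None = None
    gene_labels: str | None = None
    ppi: str | None = None
    gene_tss: str | None = None
    aliases: str | None = None
    # constants (defaults are the analysis profile used throughout)
    fold_threshold: float = 80.0
    max_ts_tissues: int = 2
    cluster_max_gap_bp: int = 10_000
    promoter_upstream_bp: int = 5_000
    promoter_downstream_bp: int = 1_000
    profile_bin_bp: int = 200
    tsvt_threshold: float = -2.5
    category_bounds: tuple[float, float, float, float] = (-160.0, -120.0, -80.0, -60.0)
    context_score_cutoff: float = -0.3
    occurrence_presence_threshold: float = 0.0
    chrom_length: int | None = None
    network_format: str = "edge-tsv"
    seed: int = 0
    out_dir: str = "tsmirnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "category_bounds" in raw:
            raw["category_bounds"] = tuple(raw["category_bounds"])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every invariant violation (empty list means the config is valid)."""
    violations: list[str] = []
    if config.fold_threshold <= 1:
        violations.append("fold_threshold must exceed 1")
    if config.max_ts_tissues not in (1, 2):
        violations.append("max_ts_tissues must be 1 or 2")
    if config.cluster_max_gap_bp < 0:
        violations.append("cluster_max_gap_bp must be non-negative")
    if config.promoter_upstream_bp < 0 or config.promoter_downstream_bp < 0:
        violations.append("promoter window sizes must be non-negative")
    window = config.promoter_upstream_bp + config.promoter_downstream_bp
    if config.profile_bin_bp <= 0 or window % config.profile_bin_bp:
        violations.append(
            f"profile_bin_bp must divide the {window}-bp promoter window"
        )
    bounds = config.category_bounds
    if len(bounds) != 4 or not all(bounds[i] < bounds[i + 1] for i in range(3)):
        violations.append("category_bounds must be 4 strictly increasing values")
    if config.tsvt_threshold > 0:
        violations.append("tsvt_threshold must be <= 0 (TSVT values are non-positive)")
    if config.network_format not in io_formats.NETWORK_FORMATS:
        violations.append(
            f"network_format must be one of {io_formats.NETWORK_FORMATS}"
        )
    return violations


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    tool_version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


class StageError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in dependency order, writing stage outputs to ``out_dir``."""
    violations = validate_config(config)
    if violations:
        raise StageError(f"stage config: invalid configuration: {violations}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    checksums = {
        name: _checksum(path)
        for name, path in cfg_dict.items()
        if isinstance(path, str) and Path(path).is_file()
    }
    manifest = RunManifest(
        config=cfg_dict,
        input_checksums=checksums,
        started=datetime.now(timezone.utc).isoformat(),
    )
    counts = manifest.stage_counts

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        # --- normalize ---------------------------------------------------
        name = stage("normalize")
        alias_map = io_formats.read_alias_table(config.aliases) if config.aliases else {}
        annotation = io_formats.read_mirna_annotation(config.mirna_loci)
        loci = genomics.loci_from_frame(annotation, alias_map)
        counts["loci"] = len(loci)
        pd.DataFrame(
            [
                {"raw_name": m.raw_name, "mirna": m.canonical_name, "chrom": m.chrom,
                 "start": m.start, "end": m.end, "strand": m.strand}
                for m in loci
            ]
        ).to_csv(out / "mirna_loci_normalized.tsv", sep="\t", index=False)

        # --- screen -------------------------------------------------------
        name = stage("screen")
        mirna_expr = io_formats.read_expression_table(config.mirna_expression)
        calls = specificity.screen_ts_mirnas(
            mirna_expr, config.fold_threshold, config.max_ts_tissues
        )
        call_map = {c.mirna_name: c for c in calls}
        counts["ts_mirna_calls"] = len(calls)
        pd.DataFrame(
            [
                {
                    "mirna": c.mirna_name,
                    "tissues": ";".join(c.tissues),
                    "folds": ";".join(f"{c.fold_values[t]:.6g}" for t in c.tissues),
                }
                for c in calls
            ]
        ).to_csv(out / "ts_mirna_calls.tsv", sep="\t", index=False)

        # --- cluster ------------------------------------------------------
        name = stage("cluster")
        clusters = genomics.call_mirna_clusters(loci, config.cluster_max_gap_bp)
        counts["clusters"] = len(clusters)
        pd.DataFrame(
            [
                {"cluster": i + 1, "chrom": c.chrom, "strand": c.strand,
                 "span_start": c.span_start, "span_end": c.span_end,
                 "members": ";".join(m.canonical_name for m in c.members)}
                for i, c in enumerate(clusters)
            ]
        ).to_csv(out / "mirna_clusters.tsv", sep="\t", index=False)

        # --- tss + promoters ----------------------------------------------
        name = stage("promoters")
        tss_map = {}
        if config.mirna_tss:
            tss_df = io_formats.read_tss_table(config.mirna_tss)
            tss_map = {
                genomics.normalize_mirna_name(r["mirna"], alias_map): (r["chrom"], int(r["tss"]))
                for _, r in tss_df.iterrows()
            }
        ts_loci = [m for m in loci if m.canonical_name in call_map]
        promoters = genomics.promoters_for_loci(
            ts_loci,
            tss_map,
            config.cluster_max_gap_bp,
            config.promoter_upstream_bp,
            config.promoter_downstream_bp,
            config.chrom_length,
        )
        counts["promoters"] = len(promoters)
        pd.DataFrame(
            [
                {"mirna": p.owner, "chrom": p.chrom, "start": p.start, "end": p.end,
                 "strand": p.strand, "tss": p.tss, "tss_source": p.tss_source}
                for p in promoters
            ]
        ).to_csv(out / "tss_assignments.tsv", sep="\t", index=False)
        io_formats.write_bed_intervals(
            [(p.chrom, p.start, p.end, p.owner, p.strand) for p in promoters],
            out / "promoters.bed",
        )

        # --- scan -----------------------------------------------------------
        name = stage("scan")
        tfbs = io_formats.read_tfbs_bed(config.tfbs)
        tf_mirna_raw = genomics.scan_promoters(promoters, tfbs)
        # attribute each relation to its miRNA's specific tissue(s)
        tf_mirna = [
            dataclasses.replace(
                e, tissues=frozenset(call_map[e.target].tissues)
            )
            for e in tf_mirna_raw
        ]
        counts["tf_mirna_edges"] = len(tf_mirna)
        pd.DataFrame(
            [
                {"tf": e.source, "mirna": e.target, "site_count": e.site_count,
                 "tissues": ";".join(sorted(e.tissues))}
                for e in tf_mirna
            ]
        ).to_csv(out / "tf_mirna_edges.tsv", sep="\t", index=False)

        # --- profile --------------------------------------------------------
        name = stage("profile")
        by_tissue: dict[str, list] = {}
        for rec in tfbs:
            by_tissue.setdefault(rec.source_tissue or "all", []).append(rec)
        profile = genomics.compute_binding_profile(
            promoters, by_tissue, config.profile_bin_bp,
            config.promoter_upstream_bp, config.promoter_downstream_bp,
        )
        counts["profile_tissues"] = len(profile.matrix)
        profile.matrix.to_csv(out / "binding_profile.tsv", sep="\t", index_label="tissue")

        # --- tspv -----------------------------------------------------------
        name = stage("tspv")
        tf_expr = io_formats.read_expression_table(config.tf_expression)
        tf_profiles = specificity.profile_matrix(
            tf_expr, tsvt_threshold=config.tsvt_threshold, bounds=config.category_bounds
        )
        counts["tf_profiles"] = len(tf_profiles)
        pd.DataFrame(
            [
                {
                    "entity": p.entity_id,
                    "tspv": p.tspv,
                    **{f"tsvt_{t.replace(' ', '_')}": p.tsvt[t] for t in tf_expr.tissues},
                    "category": p.category,
                    "specific_tissues": ";".join(sorted(p.specific_tissues)),
                }
                for p in tf_profiles.values()
            ]
        ).to_csv(out / "tf_specificity.tsv", sep="\t", index=False)

        # --- occurrence -----------------------------------------------------
        name = stage("occurrence")
        occurrence = regulation.tissue_occurrence(
            tf_mirna, tf_expr, config.occurrence_presence_threshold
        )
        counts["occurrence_edges"] = int(occurrence.histogram.sum())
        occurrence.histogram.to_frame().to_csv(out / "occurrence_histogram.tsv", sep="\t")
        occurrence.per_tissue.to_csv(
            out / "occurrence_per_tissue.tsv", sep="\t", index_label="tissue"
        )

        # --- consistent -----------------------------------------------------
        name = stage("consistent")
        consistent = regulation.find_consistent_pairs(
            tf_mirna, tf_profiles, call_map, config.tsvt_threshold
        )
        counts["consistent_pairs"] = len(consistent)
        consistent.to_csv(out / "consistent_pairs.tsv", sep="\t", index=False)

        # --- targets --------------------------------------------------------
        name = stage("targets")
        verified = io_formats.read_target_table(config.verified_targets)
        predicted = io_formats.read_target_table(config.predicted_targets)
        selected_rows = []
        targets_by_tissue: dict[str, set[str]] = {}
        mirna_gene_edges = []
        for call in calls:
            selected = regulation.select_targets(
                call.mirna_name, verified, predicted, config.context_score_cutoff
            )
            for _, row in selected.iterrows():
                for tissue in call.tissues:
                    targets_by_tissue.setdefault(tissue, set()).add(row["gene"])
                    selected_rows.append(
                        {"tissue": tissue, "mirna": row["mirna"], "gene": row["gene"],
                         "evidence": row["evidence"], "context_score": row["context_score"]}
                    )
                mirna_gene_edges.append(
                    regulation.RegulatoryEdge(
                        "mirna_gene", row["mirna"], row["gene"],
                        tissues=frozenset(call.tissues), evidence=row["evidence"],
                        score=None if pd.isna(row["context_score"]) else float(row["context_score"]),
                    )
                )
        counts["selected_targets"] = len(mirna_gene_edges)
        pd.DataFrame(
            selected_rows, columns=["tissue", "mirna", "gene", "evidence", "context_score"]
        ).to_csv(out / "selected_targets.tsv", sep="\t", index=False)

        # --- enrich ---------------------------------------------------------
        name = stage("enrich")
        labels = io_formats.read_tissue_gene_labels(config.gene_labels)
        background = set(labels["gene"]) | {
            g for gs in targets_by_tissue.values() for g in gs
        }
        enrichment = regulation.target_tissue_enrichment(
            targets_by_tissue, labels, background
        )
        counts["enrichment_tests"] = sum(r.tested for r in enrichment)
        regulation.enrichment_frame(enrichment).to_csv(
            out / "target_enrichment.tsv", sep="\t", index=False
        )

        # --- network --------------------------------------------------------
        name = stage("network")
        tf_gene_edges = []
        if config.gene_tss:
            gene_tss = pd.read_csv(config.gene_tss, sep="\t")
            gene_promoters = [
                genomics.define_promoter(
                    int(r["tss"]), r["strand"],
                    config.promoter_upstream_bp, config.promoter_downstream_bp,
                    config.chrom_length, chrom=r["chrom"], owner=r["gene"],
                )
                for _, r in gene_tss.iterrows()
            ]
            gene_universe = {g for gs in targets_by_tissue.values() for g in gs}
            gene_promoters = [p for p in gene_promoters if p.owner in gene_universe]
            tf_gene_edges = genomics.scan_promoters(
                gene_promoters, tfbs, edge_type="tf_gene"
            )
        ppi_edges = []
        if config.ppi:
            ppi_df = io_formats.read_ppi_table(config.ppi)
            ppi_edges = [
                regulation.RegulatoryEdge("ppi", a, b)
                for a, b in zip(ppi_df["protein_a"], ppi_df["protein_b"])
            ]
        graphs = {
            tissue: network.build_network(
                tf_mirna, tf_gene_edges, mirna_gene_edges, ppi_edges,
                tissue=tissue, tf_profiles=tf_profiles,
            )
            for tissue in io_formats.TISSUES
        }
        full = network.build_network(
            tf_mirna, tf_gene_edges, mirna_gene_edges, ppi_edges,
            tissue="all", tf_profiles=tf_profiles,
        )
        counts["network_nodes"] = full.number_of_nodes()
        counts["network_edges"] = full.number_of_edges()
        suffix = {"sif": "sif", "graphml": "graphml", "edge-tsv": "tsv"}[config.network_format]
        io_formats.write_network(full, out / f"network_all.{suffix}", config.network_format)

        name = stage("summarize")
        summary = network.summarize_edge_counts(graphs)
        summary.to_csv(out / "edge_counts.tsv", sep="\t")
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(f"stage {name}: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
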