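"""End-to-end orchestration of the differential motif-enrichment analysis.

Stage order: expression filter (upregulated TFs) -> motif IC filter -> site
prediction in both enhancer sets -> conservation filter -> motif redundancy
collapse -> differential enrichment + selection -> region-gene association ->
term enrichment of motif-positive regions -> predicted-target vs knockdown-DE
overlap. Every stage writes a TSV and logs its counts; the resolved
configuration is serialized next to the outputs so a run can be reproduced
from its output directory alone.

Stages whose inputs are not configured (expression table, TSS annotation,
gene sets, DE table) are skipped with a log message; the core scan/enrichment
stages always run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, expression, formats, genesets, redundancy, regions, scan

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the workflow's standard operating point: FPKM >=
    10, expression fold >= 2, q <= 0.05 for the upregulated-TF shortlist;
    motif information content >= 10 bits; relative match score >= 0.8 and
    site p <= 0.05 for predictions; motif similarity 0.8 for redundancy
    collapse; enrichment fold >= 1.5 at Bonferroni p <= 0.05; term fold >= 2,
    FDR <= 0.05, >= 5 associated genes; 1 Mb association cap.
    """

    # inputs
    enhancers_a: str = ""
    enhancers_b: str = ""
    sequences: str = ""  # FASTA: per-enhancer records or a genome to slice
    motifs: str = ""
    motif_format: str = "meme-minimal"
    ortholog_map: str = ""
    ortholog_seqs: str = ""
    expression_table: str = ""
    tf_catalog: str = ""
    tss_table: str = ""
    gmt: str = ""
    de_table: str = ""
    # thresholds
    fpkm_min: float = 10.0
    expr_fold_min: float = 2.0
    expr_q_max: float = 0.05
    ic_min: float = 10.0
    match_min: float = 0.8
    site_p_max: float = 0.05
    sim_min: float = 0.8
    enrich_fold_min: float = 1.5
    enrich_p_max: float = 0.05
    term_fold_min: float = 2.0
    term_fdr_max: float = 0.05
    term_min_genes: int = 5
    max_distance: int = 1_000_000
    background: str = "uniform"  # or "empirical"
    de_fold_min: float = 1.5
    de_padj_max: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    upregulated_tfs: pd.DataFrame | None
    sites_a: list[scan.BindingSite]
    sites_b: list[scan.BindingSite]
    clusters: list[redundancy.MotifCluster]
    enrichment_results: list[enrichment.MotifEnrichmentResult]
    selected: list[enrichment.MotifEnrichmentResult]
    assignments: pd.DataFrame | None
    term_results: dict[str, pd.DataFrame] = field(default_factory=dict)
    overlap_results: pd.DataFrame | None = None
    counts: dict[str, int] = field(default_factory=dict)


def resolve_sequences(intervals, fasta: dict[str, str]) -> dict[str, str]:
    """Per-enhancer sequences, by record name or by genomic slice.

    If every interval name is a FASTA record id the records are used
    directly; otherwise the intervals are sliced out of chromosome records
    (0-based half-open coordinates).
    """
    if all(iv.name in fasta for iv in intervals):
        return {iv.name: fasta[iv.name] for iv in intervals}
    seqs = {}
    for iv in intervals:
        if iv.chrom not in fasta:
            raise KeyError(f"chromosome {iv.chrom!r} (enhancer {iv.name!r}) not in FASTA")
        chrom_seq = fasta[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(f"enhancer {iv.name!r} extends past end of {iv.chrom!r}")
        seqs[iv.name] = chrom_seq[iv.start : iv.end]
    return seqs


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "resolved_config.yaml")
    counts: dict[str, int] = {}

    def stage(name):
        logger.info("--- stage: %s", name)

    # --- expression filter -------------------------------------------------
    stage("expression filter")
    upregulated = None
    tf_ids: set[str] | None = None
    if config.expression_table:
        expr = formats.read_expression_table(config.expression_table)
        counts["genes_total"] = len(expr)
        upregulated = expression.filter_upregulated(
            expr, config.fpkm_min, config.expr_fold_min, config.expr_q_max
        )
        counts["genes_upregulated"] = len(upregulated)
        if config.tf_catalog:
            catalog = expression.read_tf_catalog(config.tf_catalog)
            upregulated = expression.restrict_to_tfs(upregulated, catalog)
            counts["tfs_upregulated"] = len(upregulated)
        tf_ids = {g.upper() for g in upregulated["gene_id"]}
    else:
        logger.info("no expression table configured; scanning all motifs")

    # --- motif library -----------------------------------------------------
    stage("motif library")
    pwms = formats.read_motif_library(config.motifs, config.motif_format)
    counts["motifs_library"] = len(pwms)
    pwms = scan.filter_by_information_content(pwms, config.ic_min)
    counts["motifs_ic_pass"] = len(pwms)
    if tf_ids is not None:
        pwms = [p for p in pwms if p.motif_id.upper() in tf_ids]
        counts["motifs_of_upregulated_tfs"] = len(pwms)
    if not pwms:
        raise RuntimeError("no motifs left after filtering; nothing to scan")

    # --- sequences ---------------------------------------------------------
    stage("sequence extraction")
    fasta = formats.read_fasta(config.sequences)
    intervals_a = formats.read_bed(config.enhancers_a)
    intervals_b = formats.read_bed(config.enhancers_b)
    counts["enhancers_a"] = len(intervals_a)
    counts["enhancers_b"] = len(intervals_b)
    seqs_a = resolve_sequences(intervals_a, fasta)
    seqs_b = resolve_sequences(intervals_b, fasta)
    if config.background == "empirical":
        bg = scan.empirical_background(list(seqs_a.values()) + list(seqs_b.values()))
        logger.info("empirical background: %s", np.round(bg, 4))
        pwms = [p.with_background(bg) for p in pwms]

    # --- site prediction ---------------------------------------------------
    stage("site prediction")
    sites_a = scan.scan_enhancers(pwms, seqs_a, config.match_min, config.site_p_max)
    sites_b = scan.scan_enhancers(pwms, seqs_b, config.match_min, config.site_p_max)
    counts["sites_a_raw"], counts["sites_b_raw"] = len(sites_a), len(sites_b)

    # --- conservation ------------------------------------------------------
    stage("conservation filter")
    if config.ortholog_map and config.ortholog_seqs:
        ortho_map = formats.read_ortholog_map(config.ortholog_map)
        ortho_seqs = formats.read_fasta(config.ortholog_seqs)
        sites_a = scan.conserved_only(
            scan.apply_conservation(sites_a, pwms, ortho_map, ortho_seqs, config.match_min)
        )
        sites_b = scan.conserved_only(
            scan.apply_conservation(sites_b, pwms, ortho_map, ortho_seqs, config.match_min)
        )
    else:
        logger.info("no ortholog inputs configured; conservation filter disabled")
        sites_a = [dataclasses.replace(s, conserved=True) for s in sites_a]
        sites_b = [dataclasses.replace(s, conserved=True) for s in sites_b]
    counts["sites_a_conserved"], counts["sites_b_conserved"] = len(sites_a), len(sites_b)

    # --- redundancy collapse ----------------------------------------------
    stage("motif redundancy")
    presence_b = enrichment.count_presence(
        sites_b, [iv.name for iv in intervals_b], [p.motif_id for p in pwms]
    )
    clusters = redundancy.cluster_motifs(pwms, presence_b, config.sim_min)
    counts["motif_clusters"] = len(clusters)
    representatives = [c.representative for c in clusters]

    # --- differential enrichment -------------------------------------------
    stage("differential enrichment")
    presence_a = enrichment.count_presence(
        sites_a, [iv.name for iv in intervals_a], [p.motif_id for p in pwms]
    )
    results = enrichment.motif_enrichment(
        presence_b, len(intervals_b), presence_a, len(intervals_a),
        motif_ids=representatives,
        fold_min=config.enrich_fold_min, p_max=config.enrich_p_max,
    )
    selected = enrichment.select_enriched(results, config.enrich_fold_min, config.enrich_p_max)
    counts["motifs_enriched"] = len(selected)
    for r in results:
        logger.info(
            "motif %s: %d/%d vs %d/%d enhancers, fold=%.3g, p_bonf=%.3g%s",
            r.motif_id, r.k_b, r.n_b, r.k_a, r.n_a, r.fold, r.p_bonf,
            " *" if r.passes else "",
        )

    # --- region-gene association and term enrichment -----------------------
    assignments = None
    term_results: dict[str, pd.DataFrame] = {}
    if config.tss_table:
        stage("region-gene association")
        tss = regions.tss_from_frame(formats.read_tss_table(config.tss_table))
        assignments = regions.assign_regions(intervals_b, tss, config.max_distance)
        if config.gmt and selected:
            terms = formats.read_gmt(config.gmt)
            domains = regions.build_domains(tss, config.max_distance)
            by_name = {iv.name: iv for iv in intervals_b}
            for r in selected:
                motif_enh = sorted(
                    {s.enhancer_name for s in sites_b if s.motif_id == r.motif_id}
                )
                motif_regions = [by_name[n] for n in motif_enh]
                term_results[r.motif_id] = genesets.region_term_enrichment(
                    motif_regions, domains, terms
                )
    else:
        logger.info("no TSS table configured; association stages skipped")

    # --- target vs knockdown-DE overlap ------------------------------------
    overlap_df = None
    if config.de_table and assignments is not None and selected:
        stage("target-DE overlap")
        de = formats.read_de_table(config.de_table)
        universe = list(de["gene"])
        _, down = genesets.de_direction_sets(de, config.de_fold_min, config.de_padj_max)
        rows = []
        assigned = assignments.dropna(subset=["gene_id"])
        for r in selected:
            motif_enh = {s.enhancer_name for s in sites_b if s.motif_id == r.motif_id}
            targets = sorted(set(assigned[assigned["region"].isin(motif_enh)]["gene_id"]))
            res = genesets.target_de_overlap(targets, down, universe)
            rows.append(
                {"motif_id": r.motif_id, "n_targets": res.target_set_size,
                 "n_de_down": res.de_set_size, "universe": res.universe_size,
                 "overlap": res.overlap, "hyper_p": res.hyper_p}
            )
        overlap_df = pd.DataFrame(
            rows, columns=["motif_id", "n_targets", "n_de_down", "universe",
                           "overlap", "hyper_p"]
        )

    result = PipelineResult(
        upregulated_tfs=upregulated, sites_a=sites_a, sites_b=sites_b,
        clusters=clusters, enrichment_results=results, selected=selected,
        assignments=assignments, term_results=term_results,
        overlap_results=overlap_df, counts=counts,
    )
    if outdir is not None:
        _write_bundle(result, outdir)
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    if result.upregulated_tfs is not None:
        formats.write_results(result.upregulated_tfs, outdir / "filtered_expression.tsv")
    formats.write_results(scan.sites_to_frame(result.sites_a), outdir / "sites_a.tsv")
    formats.write_results(scan.sites_to_frame(result.sites_b), outdir / "sites_b.tsv")
    cluster_df = pd.DataFrame(
        [{"representative": c.representative, "members": ",".join(c.members),
          "occurrence_count": c.occurrence_count} for c in result.clusters],
        columns=["representative", "members", "occurrence_count"],
    )
    formats.write_results(cluster_df, outdir / "clusters.tsv")
    formats.write_results(
        enrichment.results_to_frame(result.enrichment_results),
        outdir / "motif_enrichment.tsv",
    )
    if result.assignments is not None:
        formats.write_results(result.assignments, outdir / "region_assignments.tsv")
    for motif_id, df in result.term_results.items():
        formats.write_results(df, outdir / f"term_enrichment_{motif_id}.tsv")
    if result.overlap_results is not None:
        formats.write_results(result.overlap_results, outdir / "target_overlap.tsv")
    lines = ["# Pipeline summary", ""]
    for key, val in result.counts.items():
        lines.append(f"- {key}: {val}")
    lines.append("")
    if result.selected:
        lines.append("Selected motifs (fold desc):")
        for r in result.selected:
            lines.append(
                f"- {r.motif_id}: fold={r.fold:.4g} "
                f"({r.k_b}/{r.n_b} vs {r.k_a}/{r.n_a}), p_bonf={r.p_bonf:.3g}"
            )
    else:
        lines.append("No motif passed the enrichment thresholds.")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
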