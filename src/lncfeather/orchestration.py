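"""Single-command pipeline runner: discovery -> coding consensus ->
positional classification -> characterization -> clustering -> differential
expression -> enrichment -> candidate selection, with a stage-by-stage
manifest of counts and thresholds."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, coding_potential, diff_expression, enrichment_candidates
from . import feature_stats, lncrna_classes, transcript_discovery
from .io_formats import (
    read_bed,
    read_chrom_sizes,
    read_expression,
    read_fasta,
    read_gtf,
    read_library_meta,
    read_track,
    write_gtf,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and thresholds; defaults carry the published cutoffs."""

    isotigs_gtf: str
    annotation_gtf: str
    expression_tsv: str
    library_meta_tsv: str
    scores_tsv: str
    catalog_bed: str | None = None
    repeats_bed: str | None = None
    conservation_bedgraph: str | None = None
    chrom_sizes: str | None = None
    term_map_tsv: str | None = None
    transcripts_fasta: str | None = None
    targets_fasta: str | None = None
    targets_bed: str | None = None
    homology_tsv: str | None = None
    selected_clusters: list[str] = field(default_factory=list)

    min_length: int = 200
    min_max_fpkm: float = 1.0
    cpc_cutoff: float = -0.5
    plek_cutoff: float = -0.5
    evalue_threshold: float = 1e-4
    expressed_threshold: float = 1.0
    cluster_cut: float = 0.69
    cluster_metric: str = "correlation"
    q_threshold: float = 0.7
    pseudocount: float = 0.5
    enrich_p: float = 0.01
    enrich_fdr: float = 0.05
    similarity_k: int = 11
    similarity_min_identity: float = 0.8
    similarity_min_length: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _read_homology(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["query_chrom"], df["target_chrom"]))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write outputs plus a manifest to ``outdir``.

    Stages degrade gracefully on empty intermediate sets; optional inputs
    (conservation, repeats, term map, second-species catalog) switch their
    stage off when absent.  The manifest is deterministic for a fixed config
    and input set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"thresholds": {
        "min_length": config.min_length,
        "min_max_fpkm": config.min_max_fpkm,
        "cpc_cutoff": config.cpc_cutoff,
        "plek_cutoff": config.plek_cutoff,
        "evalue_threshold": config.evalue_threshold,
        "expressed_threshold": config.expressed_threshold,
        "cluster_cut": config.cluster_cut,
        "q_threshold": config.q_threshold,
        "enrich_p": config.enrich_p,
        "enrich_fdr": config.enrich_fdr,
    }}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load")
        isotigs = read_gtf(config.isotigs_gtf)
        annotation = read_gtf(config.annotation_gtf)
        meta = read_library_meta(config.library_meta_tsv)
        expr = read_expression(config.expression_tsv, meta)
        scores = coding_potential.CodingScores.from_tsv(config.scores_tsv)
        catalog = read_bed(config.catalog_bed) if config.catalog_bed else []

        stage("discovery")
        retained, retained_expr, report = transcript_discovery.run_discovery(
            isotigs, annotation, expr, catalog,
            config.min_length, config.min_max_fpkm,
        )
        manifest["discovery"] = report.as_dict()
        write_gtf(retained, outdir / "retained.gtf")
        pd.Series(report.novelty, name="novelty").rename_axis("transcript_id").to_csv(
            outdir / "novelty.tsv", sep="\t"
        )

        stage("coding_potential")
        retained_ids = [m.transcript_id for m in retained]
        # merged multi-member transcripts have no direct score row; score them
        # by their most coding-leaning member (conservative)
        score_tbl = scores.table
        rows = {}
        for m in retained:
            members = [t for t in (m.members or (m.transcript_id,)) if t in score_tbl.index]
            if not members:
                raise KeyError(f"no coding scores for transcript {m.transcript_id!r}")
            block = score_tbl.loc[members]
            rows[m.transcript_id] = {
                "cpc_score": block["cpc_score"].max(),
                "plek_score": block["plek_score"].max(),
                "min_domain_evalue": block["min_domain_evalue"].min(),
            }
        merged_scores = coding_potential.CodingScores(
            pd.DataFrame.from_dict(rows, orient="index")
            if rows else score_tbl.iloc[0:0]
        )
        set_cpc = coding_potential.call_noncoding_cpc(
            merged_scores, config.cpc_cutoff, retained_ids)
        set_plek = coding_potential.call_noncoding_plek(
            merged_scores, config.plek_cutoff, retained_ids)
        set_free = coding_potential.call_domain_free(
            merged_scores, config.evalue_threshold, retained_ids)
        lnc_ids = sorted(coding_potential.consensus_lncrnas(set_cpc, set_plek, set_free))
        manifest["coding_potential"] = {
            "cpc_noncoding": len(set_cpc),
            "plek_noncoding": len(set_plek),
            "domain_free": len(set_free),
            "consensus_lncrnas": len(lnc_ids),
        }

        stage("classification")
        by_id = {m.transcript_id: m for m in retained}
        lnc_models = [by_id[t] for t in lnc_ids]
        coding_models = [m for m in annotation if m.biotype == "protein_coding"]
        classes = lncrna_classes.classify_all(lnc_models, coding_models)
        manifest["classes"] = lncrna_classes.class_counts(classes)
        cls_df = pd.DataFrame(
            {
                "transcript_id": lnc_ids,
                "class": [classes[t] for t in lnc_ids],
                "novelty": [report.novelty[t] for t in lnc_ids],
            }
        ).set_index("transcript_id")
        cls_df.to_csv(outdir / "lncrna_classes.tsv", sep="\t")
        if config.chrom_sizes:
            sizes = read_chrom_sizes(config.chrom_sizes)
            dens = lncrna_classes.chromosome_density(lnc_models, sizes)
            manifest["density_per_mb"] = {k: round(v, 4) for k, v in sorted(dens.items())}

        stage("characterization")
        track = read_track(config.conservation_bedgraph) if config.conservation_bedgraph else None
        repeats = read_bed(config.repeats_bed) if config.repeats_bed else []
        groups = {"mRNA": coding_models}
        for cname in lncrna_classes.CLASSES:
            groups[cname] = [by_id[t] for t in lnc_ids if classes[t] == cname]
        groups = {k: v for k, v in groups.items() if v}
        feature_expr = _combined_expression(expr, retained_expr)
        if groups:
            summary = feature_stats.summarize_groups(
                groups, feature_expr, track, repeats)
            summary.to_csv(outdir / "feature_summary.tsv", sep="\t")
            manifest["features"] = {
                g: {"n": int(row["n"]),
                    "median_length": row["median_length"],
                    "mean_exons": round(row["mean_exons"], 3),
                    "te_overlap_fraction": round(row["te_overlap_fraction"], 4)}
                for g, row in summary.iterrows()
            }
        js = feature_stats.js_table(feature_expr.subset(
            [m.transcript_id for ms in groups.values() for m in ms]))
        js.to_csv(outdir / "js_scores.tsv", sep="\t")

        stage("clustering")
        ann_ids = [m.transcript_id for m in annotation]
        cluster_universe = [
            t for t in ann_ids + retained_ids
            if t in coexpression.expressed_filter(feature_expr, config.expressed_threshold)
        ]
        if len(cluster_universe) >= 2:
            scaled = coexpression.zscale(feature_expr, cluster_universe)
            assignment = coexpression.wpgma_cluster(
                scaled, cut=config.cluster_cut, metric=config.cluster_metric)
        else:
            assignment = coexpression.ClusterAssignment(
                {t: "A" for t in cluster_universe},
                linkage_matrix=np.empty((0, 4)),
                cut=config.cluster_cut, ids=cluster_universe)
        assignment.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
        manifest["clustering"] = {
            "n_clustered": len(cluster_universe),
            "n_clusters": assignment.n_clusters,
        }

        stage("differential_expression")
        if cluster_universe:
            de_expr = feature_expr.subset(cluster_universe)
            results, de_called = diff_expression.regional_de_calls(
                de_expr, config.pseudocount, config.q_threshold)
            for name, res in results.items():
                res.to_csv(outdir / f"de_{name}.tsv", sep="\t")
            manifest["differential_expression"] = {
                name: int(res["call"].sum()) for name, res in results.items()
            }
            manifest["differential_expression"]["regional_any"] = len(de_called)
        else:
            de_called = set()
            manifest["differential_expression"] = {"regional_any": 0}

        stage("enrichment")
        if config.term_map_tsv:
            term_map = enrichment_candidates.read_term_map(config.term_map_tsv)
            background = [t for t in cluster_universe if t in set(ann_ids)]
            enr_frames = []
            for label, members in sorted(assignment.members().items()):
                genes = [t for t in members if t in set(ann_ids)]
                if not genes:
                    continue
                res = enrichment_candidates.fisher_enrichment(
                    genes, background, term_map, config.enrich_p, config.enrich_fdr)
                res.insert(0, "cluster", label)
                enr_frames.append(res)
            enrichment = (
                pd.concat(enr_frames, ignore_index=True) if enr_frames
                else pd.DataFrame(columns=["cluster", "term", "k", "n", "K", "N",
                                           "p", "fdr", "significant"])
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["enrichment"] = {
                "tested": len(enrichment),
                "significant": int(enrichment["significant"].sum()) if len(enrichment) else 0,
            }

        stage("candidates")
        if (config.targets_fasta and config.transcripts_fasta and lnc_ids):
            sequences = read_fasta(config.transcripts_fasta)
            # merged transcripts: splice from members is unavailable here; use
            # any member sequence present
            lnc_seqs = {}
            lnc_chroms = {}
            for t in lnc_ids:
                model = by_id[t]
                src = t if t in sequences else next(
                    (mm for mm in model.members if mm in sequences), None)
                if src is not None:
                    lnc_seqs[t] = sequences[src]
                    lnc_chroms[t] = model.chrom
            target_seqs = read_fasta(config.targets_fasta)
            target_chroms = {}
            if config.targets_bed:
                for iv in read_bed(config.targets_bed):
                    target_chroms[iv.name] = iv.chrom
            homology = _read_homology(config.homology_tsv) if config.homology_tsv else None
            hits = enrichment_candidates.cross_species_hits(
                lnc_seqs, lnc_chroms, target_seqs, target_chroms, homology,
                k=config.similarity_k,
                min_identity=config.similarity_min_identity,
                min_length=config.similarity_min_length,
            )
            cluster_labels = {
                t: assignment.labels.get(t, "") for t in lnc_ids
            }
            candidates = enrichment_candidates.select_candidates(
                lnc_ids, cluster_labels, config.selected_clusters, de_called, hits)
            candidates.to_csv(outdir / "candidates.tsv", sep="\t")
            manifest["candidates"] = {
                "n_hits": len(hits),
                "n_candidates": int(candidates["candidate"].sum()),
            }
    except Exception as exc:
        manifest["status"] = "incomplete"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    manifest["status"] = "complete"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _combined_expression(expr, retained_expr):
    """Original table plus rows for merged transcripts absent from it."""
    extra = [t for t in retained_expr.values.index if t not in expr.values.index]
    if not extra:
        return expr
    from .io_formats import ExpressionTable

    combined = pd.concat([expr.values, retained_expr.values.loc[extra]])
    return ExpressionTable(combined, dict(expr.library_meta))
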