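"""End-to-end orchestration of the SuperSAGE analysis.

Stages, in order: (optional) synthesis of the study -> tag extraction ->
TrueQuant deduplication -> artifact reduction -> cross-library filtering
-> tag-to-gene mapping -> counting and CPM normalization -> PerMANOVA
(overall and per treatment group) and NMDS -> NB exact-test differential
expression for both treatment transitions within each population ->
population-specific classification and the up/down chi-squared contrast
-> GO enrichment of up-regulated sets and second-order GO profiles.

Every stage logs its input/output record counts into a run manifest;
re-running with the same config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import (
    differential_expression as de,
    enrichment as enr,
    multivariate as mv,
    synthetic_data as syn,
    tag_mapping_counts as tmc,
    tag_processing as tp,
)
from .config import PipelineConfig
from .containers import (
    SampleMeta,
    TranscriptSet,
    design_from_frame,
    design_to_frame,
    tag_tables_to_frame,
)
from .synthetic_data import GO_IMMUNE

logger = logging.getLogger("sagescape")

#: The two treatment transitions analysed for differential expression.
DE_CONTRASTS = (
    ("control_to_once", "once_exposed", "control"),
    ("once_to_twice", "twice_exposed", "once_exposed"),
)


@dataclass
class RunManifest:
    """Per-stage record counts, parameters and input hashes."""

    config: dict[str, Any]
    stages: list[dict[str, Any]] = field(default_factory=list)
    input_hashes: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, **counts: Any) -> None:
        logger.info("stage=%s %s", stage,
                    " ".join(f"{k}={v}" for k, v in counts.items()))
        self.stages.append({"stage": stage, **counts})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "input_hashes": self.input_hashes,
             "stages": self.stages}, indent=2, default=str))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    manifest: RunManifest
    counts: tmc.GeneCountMatrix
    permanova: dict[str, mv.PermanovaTable]
    nmds: dict[str, mv.NmdsResult]
    de_tables: dict[str, pd.DataFrame]
    population_sets: dict[str, de.PopulationSpecificSets]
    chisq: dict[str, tuple[float, float]]
    enrichment: dict[str, pd.DataFrame]
    profiles: dict[str, pd.Series]


def _synthesize(config: PipelineConfig, out_dir: Path, manifest: RunManifest):
    """Generate the synthetic study and write its raw inputs to disk."""
    transcripts = syn.generate_transcriptome(
        n_genes=config.n_genes,
        variants_per_gene_rate=config.variants_per_gene_rate,
        mean_len=config.mean_len,
        frac_without_anchor=config.frac_without_anchor,
        seed=config.seed)
    design = syn.generate_design()
    genes = transcripts.gene_ids
    immune_genes = genes[: config.n_immune_genes]
    river_down = genes[config.n_immune_genes:
                       config.n_immune_genes + config.n_river_down_genes]
    effects = [
        syn.EffectSpec.for_transition(
            "immune_up_lake", immune_genes, config.immune_log2fc,
            population="lake", transition="control_to_once", direction="up"),
        syn.EffectSpec.for_transition(
            "river_down", river_down, config.river_down_log2fc,
            population="river", transition="control_to_once",
            direction="down"),
    ]
    counts, truth = syn.simulate_counts(
        transcripts, design, baseline_mean=config.baseline_mean,
        dispersion=config.dispersion, effects=effects, seed=config.seed + 1)
    reads = syn.simulate_reads(
        counts, transcripts, barcode_len=config.barcode_len,
        error_rate=config.error_rate,
        pcr_duplication_rate=config.pcr_duplication_rate,
        seed=config.seed + 2)
    dag, annotations = syn.generate_go(
        genes, n_terms=config.n_go_terms, seed=config.seed + 3,
        immune_genes=immune_genes)

    fastq_dir = out_dir / "fastq"
    reads.write_fastq(fastq_dir)
    transcripts.write_fasta(out_dir / "reference.fasta")
    design_to_frame(design).to_csv(out_dir / "design.tsv", sep="\t")
    dag.to_obo(out_dir / "go.obo")
    annotations.to_frame().to_csv(out_dir / "annotations.tsv", sep="\t",
                                  index=False)
    truth.mean.to_csv(out_dir / "truth_mean.tsv", sep="\t",
                      index_label="gene_id")
    reads.gene_truth.to_csv(out_dir / "truth_gene_counts.tsv", sep="\t",
                            index_label="gene_id")
    manifest.record("simulate", n_genes=len(genes),
                    n_transcripts=len(transcripts),
                    n_libraries=len(design),
                    n_reads=sum(len(r) for r in reads.reads.values()),
                    n_skipped_short=reads.n_skipped_short,
                    n_skipped_anchorless=reads.n_skipped_anchorless)
    return fastq_dir, transcripts, design, dag, annotations


def _load_inputs(config: PipelineConfig, manifest: RunManifest):
    fastq_dir = Path(config.fastq_dir)
    reference = TranscriptSet.read_fasta(config.reference_fasta)
    design = design_from_frame(
        pd.read_csv(config.design_tsv, sep="\t", index_col="library_id"))
    dag = enr.load_dag(config.go_obo)
    annotations = enr.AnnotationMap.from_frame(
        pd.read_csv(config.annotation_tsv, sep="\t"))
    for key in ("reference_fasta", "design_tsv", "annotation_tsv", "go_obo"):
        manifest.input_hashes[key] = _hash_file(Path(getattr(config, key)))
    return fastq_dir, reference, design, dag, annotations


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())

    if config.fastq_dir:
        fastq_dir, reference, design, dag, annotations = _load_inputs(
            config, manifest)
    else:
        fastq_dir, reference, design, dag, annotations = _synthesize(
            config, out_dir, manifest)

    # -- extraction and deduplication per library ---------------------------
    tables = []
    for sample in design:
        fastq = fastq_dir / f"{sample.library_id}.fastq"
        if not fastq.exists():
            fastq_gz = fastq.with_suffix(".fastq.gz")
            if not fastq_gz.exists():
                raise FileNotFoundError(
                    f"missing FASTQ for library {sample.library_id!r}: {fastq}")
            fastq = fastq_gz
        manifest.input_hashes[f"fastq:{sample.library_id}"] = _hash_file(fastq)
        observations, log = tp.extract_tags(
            fastq, barcode_len=config.barcode_len, tag_len=config.tag_len,
            anchor=config.anchor)
        table = tp.dedup_truequant(observations, library_id=sample.library_id)
        manifest.record("extract_dedup", library=sample.library_id,
                        n_reads=log.n_reads, n_extracted=log.n_extracted,
                        n_too_short=log.n_too_short,
                        n_bad_anchor=log.n_bad_anchor,
                        n_unique_tags=len(table))
        tables.append(table)

    # -- artifact reduction and occurrence filter ---------------------------
    tables = [tp.reduce_artifacts(t, ratio_threshold=config.artifact_ratio)
              for t in tables]
    before = len({t for tab in tables for t in tab.counts})
    tables = tp.filter_tags(tables, min_libraries=config.min_libraries)
    unique_tags = sorted({t for tab in tables for t in tab.counts})
    manifest.record("filter", n_tags_before=before,
                    n_tags_after=len(unique_tags))
    tag_tables_to_frame(tables).to_csv(out_dir / "tag_counts.tsv", sep="\t",
                                       index=False)

    # -- mapping and counting ----------------------------------------------
    assignments = tmc.assign_all(unique_tags, reference,
                                 max_mismatch=config.max_mismatch)
    tmc.assignments_to_frame(assignments).to_csv(
        out_dir / "assignments.tsv", sep="\t", index=False)
    counts, map_log = tmc.build_gene_counts(assignments, tables)
    counts = tmc.normalize_cpm(counts)
    counts.write_tsv(out_dir / "gene_counts_raw.tsv", "raw")
    counts.write_tsv(out_dir / "gene_counts_cpm.tsv", "normalized")
    manifest.record("map_count", **{k: v for k, v in map_log.items()},
                    n_genes_detected=int((counts.raw.sum(axis=1) > 0).sum()))

    # -- multivariate statistics -------------------------------------------
    dist = mv.correlation_distance(counts)
    libs_by_treatment = {
        t: [s.library_id for s in design if s.treatment == t]
        for t in ("control", "once_exposed", "twice_exposed")}
    permanova_tables: dict[str, mv.PermanovaTable] = {}
    permanova_tables["overall"] = mv.permanova(
        dist, design, terms=("treatment", "population", "family", "sex"),
        n_permutations=config.n_permutations, seed=config.seed + 10)
    design_by_id = {s.library_id: s for s in design}
    for treatment, libs in libs_by_treatment.items():
        idx = [dist.library_ids.index(l) for l in libs]
        sub = mv.DistanceMatrix(
            library_ids=libs,
            values=dist.values[np.ix_(idx, idx)])
        permanova_tables[treatment] = mv.permanova(
            sub, [design_by_id[l] for l in libs],
            terms=("population", "family", "sex"),
            n_permutations=config.n_permutations, seed=config.seed + 11)
    for name, table in permanova_tables.items():
        table.to_frame().to_csv(out_dir / f"permanova_{name}.tsv", sep="\t",
                                index=False)
        manifest.record("permanova", model=name,
                        n_permutations=table.n_permutations)

    nmds_results: dict[str, mv.NmdsResult] = {}
    nmds_results["overall"] = mv.nmds(
        dist, dims=config.nmds_dims, n_starts=config.nmds_starts,
        seed=config.seed + 12)
    nmds_results["overall"].to_frame().to_csv(
        out_dir / "nmds_coordinates.tsv", sep="\t", index_label="library_id")
    manifest.record("nmds", stress=round(nmds_results["overall"].stress, 4))

    # -- differential expression -------------------------------------------
    pop_libs = {
        pop: {
            t: [s.library_id for s in design
                if s.population == pop and s.treatment == t]
            for t in ("control", "once_exposed", "twice_exposed")}
        for pop in ("lake", "river")}
    treatment_groups = {s.library_id: f"{s.population}:{s.treatment}"
                        for s in design}
    dispersion = de.estimate_dispersion(
        counts, treatment_groups, shrinkage_weight=config.shrinkage_weight)
    manifest.record("dispersion",
                    common=round(dispersion.common_dispersion, 4))

    de_tables: dict[str, pd.DataFrame] = {}
    for contrast, after, before_t in DE_CONTRASTS:
        for pop in ("lake", "river"):
            table = de.exact_test(
                counts, pop_libs[pop][after], pop_libs[pop][before_t],
                dispersion=dispersion, prior_count=config.prior_count)
            table = de.annotate_significance(table, alpha=config.alpha)
            key = f"{pop}_{contrast}"
            de_tables[key] = table
            table.to_csv(out_dir / f"de_{key}.tsv", sep="\t",
                         index_label="gene_id")
            manifest.record("de", contrast=key,
                            n_significant=int((table["fdr"] < config.alpha).sum()))

    population_sets: dict[str, de.PopulationSpecificSets] = {}
    chisq: dict[str, tuple[float, float]] = {}
    for contrast, _, _ in DE_CONTRASTS:
        sets = de.classify_population_specific(
            de_tables[f"lake_{contrast}"], de_tables[f"river_{contrast}"],
            alpha=config.alpha)
        population_sets[contrast] = sets
        sets.to_frame().to_csv(out_dir / f"population_sets_{contrast}.tsv",
                               sep="\t", index=False)
        table2x2 = sets.counts_2x2()
        if (table2x2.sum(axis=0) > 0).all() and (table2x2.sum(axis=1) > 0).all():
            chisq[contrast] = de.chisq_2x2(table2x2)
        manifest.record("classify", contrast=contrast,
                        lake_only_up=len(sets.lake_only_up),
                        lake_only_down=len(sets.lake_only_down),
                        river_only_up=len(sets.river_only_up),
                        river_only_down=len(sets.river_only_down))

    # -- enrichment ---------------------------------------------------------
    closed = enr.propagate_annotations(dag, annotations)
    universe = frozenset(closed.direct) & frozenset(counts.gene_ids)
    enrichment_tables: dict[str, pd.DataFrame] = {}
    profiles: dict[str, pd.Series] = {}
    for contrast, _, _ in DE_CONTRASTS:
        sets = population_sets[contrast]
        for pop, gene_set in (("lake", sets.lake_only_up),
                              ("river", sets.river_only_up)):
            study = frozenset(gene_set) & universe
            key = f"{pop}_up_{contrast}"
            if not study:
                continue
            table = enr.fisher_enrichment(study, universe, closed,
                                          min_genes=config.min_genes)
            enrichment_tables[key] = table
            table.to_csv(out_dir / f"enrichment_{key}.tsv", sep="\t",
                         index=False)
            profiles[key] = enr.second_order_profile(study, dag, closed)
            profiles[key].to_csv(out_dir / f"profile_{key}.tsv", sep="\t",
                                 index_label="term")
            manifest.record("enrichment", gene_set=key, n_genes=len(study),
                            n_terms_tested=len(table))

    manifest.write(out_dir / "manifest.json")
    return PipelineResult(
        manifest=manifest, counts=counts, permanova=permanova_tables,
        nmds=nmds_results, de_tables=de_tables,
        population_sets=population_sets, chisq=chisq,
        enrichment=enrichment_tables, profiles=profiles)
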