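"""End-to-end orchestration: filter -> associate -> annotate -> sweep ->
enrich -> validate, with per-stage row counts logged and deterministic
outputs for a fixed config."""

from __future__ import annotations

import json
import logging
import time

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as psio
from .annotation import SnpAnnotation, aggregate, annotate_sites
from .association import AssociationRecord, FDRResult, associate_sites
from .enrichment import EnrichmentResult, category_polymorphism_enrichment
from .filters import (
    FilterConfig,
    FilterReport,
    _group_masks,
    select_common_polymorphic_sites,
)
from .genes import GeneIndex, GeneModel, read_gene_models
from .models import SiteTable
from .sweep import (
    SweepRecord,
    SweepTestResult,
    chromosome_sweep_tests,
    sweep_records,
    sweep_table,
)
from .validation import GenotypeTable, concordance_report

logger = logging.getLogger("poolscan")


@dataclass
class PipelineConfig:
    counts_path: Optional[str] = None
    counts_format: str = "tsv"
    gff3_path: Optional[str] = None
    categories_path: Optional[str] = None
    fasta_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    alpha_fdr: float = 0.01
    sweep_flank: int = 1_400_000
    enrichment_category: str = "detox"
    output_dir: str = "poolscan_out"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_fdr < 1):
            raise ValueError("alpha_fdr must be in (0, 1)")


@dataclass
class PipelineResult:
    filter_report: FilterReport
    filtered: SiteTable
    association: list[AssociationRecord]
    fdr: list[FDRResult]
    significant: list[AssociationRecord]
    annotations: list[SnpAnnotation]
    per_gene: Optional[pd.DataFrame]
    sweep_records: list[SweepRecord]
    sweep_tests: list[SweepTestResult]
    enrichment: list[EnrichmentResult]
    validation: Optional[pd.DataFrame]
    log: list[dict]


def run_analysis(
    table: SiteTable,
    genes: Optional[Sequence[GeneModel]] = None,
    fasta=None,
    filter_config: Optional[FilterConfig] = None,
    alpha_fdr: float = 0.01,
    enrichment_category: str = "detox",
    genotypes: Optional[GenotypeTable] = None,
    genotype_locus_key=None,
) -> PipelineResult:
    """Run every analysis stage on an in-memory site table.

    ``genes`` enables annotation and enrichment; ``fasta`` additionally
    enables coding-effect calls; ``genotypes`` (plus the SiteKey of the
    genotyped locus) enables the pool-vs-genotype concordance report.
    """
    log: list[dict] = []

    def stage(name: str, n_in: int, n_out: int, t0: float) -> None:
        entry = {
            "stage": name,
            "input_rows": n_in,
            "output_rows": n_out,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.append(entry)
        logger.info("%(stage)s: %(input_rows)d -> %(output_rows)d rows", entry)

    t0 = time.perf_counter()
    fc = filter_config or FilterConfig()
    filtered, report = select_common_polymorphic_sites(table, fc)
    stage("filter", len(table), len(filtered), t0)

    t0 = time.perf_counter()
    records, fdr = associate_sites(filtered, alpha=alpha_fdr)
    significant = [r for r in records if r.fdr_pass]
    stage("associate", len(filtered), len(significant), t0)

    annotations: list[SnpAnnotation] = []
    per_gene = None
    enrichment: list[EnrichmentResult] = []
    if genes is not None:
        index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
        t0 = time.perf_counter()
        annotations = annotate_sites(significant, index, fasta)
        per_gene, _ = aggregate(annotations, significant)
        stage("annotate", len(significant), len(annotations), t0)

        t0 = time.perf_counter()
        # the filtered table is already the polymorphic subset; rebuild the
        # analysed universe (common sites) for enrichment denominators
        masks = _group_masks(table, fc)
        common_mask = masks["resistant"]["het"] & masks["susceptible"]["het"]
        common = table.subset(common_mask)
        cpool = common.counts.sum(axis=1)
        csorted = np.sort(cpool, axis=1)[:, ::-1]
        cdepth = cpool.sum(axis=1)
        cpoly = (csorted[:, 1] >= fc.min_minor_count) & (
            csorted[:, 1] / np.maximum(cdepth, 1) >= fc.min_minor_freq
        )
        enrichment = category_polymorphism_enrichment(
            common.keys(), cpoly, index, enrichment_category
        )
        stage("enrich", len(common), len(enrichment), t0)

    t0 = time.perf_counter()
    sweeps = sweep_records(significant)
    tests = chromosome_sweep_tests(sweeps)
    stage("sweep", len(significant), len(tests), t0)

    validation = None
    if genotypes is not None and genotype_locus_key is not None:
        t0 = time.perf_counter()
        lib_counts = {}
        keys = {(k.chrom, k.pos): i for i, k in enumerate(table.keys())}
        i = keys.get((genotype_locus_key.chrom, genotype_locus_key.pos))
        if i is not None:
            ref_i = "ACGT".index(table.ref[i])
            for j, lib in enumerate(table.libraries):
                c = table.counts[i, j]
                alt_count = int(c.sum() - c[ref_i])
                lib_counts[lib.id] = (alt_count, int(c.sum()))
            validation = concordance_report(genotypes, lib_counts)
        stage("validate", 1, 0 if validation is None else len(validation), t0)

    return PipelineResult(
        filter_report=report,
        filtered=filtered,
        association=records,
        fdr=fdr,
        significant=significant,
        annotations=annotations,
        per_gene=per_gene,
        sweep_records=sweeps,
        sweep_tests=tests,
        enrichment=enrichment,
        validation=validation,
        log=log,
    )


def result_rows(
    records: Sequence[AssociationRecord],
    annotations: Sequence[SnpAnnotation] = (),
) -> list[dict]:
    """Merge association records with annotations into result-table rows."""
    ann_by_key: dict[tuple, SnpAnnotation] = {}
    for a in annotations:
        ann_by_key.setdefault((a.key.chrom, a.key.pos), a)
    rows = []
    for r in records:
        a = ann_by_key.get((r.key.chrom, r.key.pos))
        freqs = r.group_frequencies()
        alt = a.alt_base if a and a.alt_base else r.alt_base()
        rows.append(
            {
                "chromosome": r.key.chrom,
                "position": r.key.pos,
                "ref": r.key.ref,
                "alt": alt,
                "feature_class": a.feature_class if a else None,
                "substitution_type": a.substitution_type if a else None,
                "residue": a.residue_number if a else None,
                "codon_position": a.codon_position if a else None,
                "freq_resistant": freqs["resistant"].get(alt, 0.0),
                "freq_susceptible": freqs["susceptible"].get(alt, 0.0),
                "chi2": r.chi2,
                "df": r.df,
                "neg_log10_p": r.neg_log10_p,
                "fdr_pass": r.fdr_pass,
            }
        )
    return rows


def run_all(config: PipelineConfig, table: Optional[SiteTable] = None) -> PipelineResult:
    """File-based pipeline entry: read inputs, run, write the result bundle.

    Any stage failure propagates with the stage name in the log; outputs are
    TSV (plus BED for significant SNPs) under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if table is None:
        if config.counts_path is None:
            raise ValueError("either a counts_path or an in-memory table is required")
        records = psio.read_site_counts(config.counts_path, config.counts_format)
        lib_ids = list(records[0].counts) if records else []
        from .models import GROUPS, LibraryMeta

        libs = []
        for lid in lib_ids:
            group = "resistant" if lid.startswith(("res", "R", "alive")) else "susceptible"
            rep = int("".join(ch for ch in lid if ch.isdigit()) or 1)
            libs.append(LibraryMeta(lid, group, rep))
        table = SiteTable.from_records(records, libs)

    genes = None
    if config.gff3_path:
        genes = read_gene_models(config.gff3_path, config.categories_path)
    fasta = None
    if config.fasta_path:
        from pyfaidx import Fasta

        fasta = Fasta(config.fasta_path)
    genotypes = None
    if config.genotypes_path:
        from .validation import read_genotype_table

        genotypes = read_genotype_table(config.genotypes_path)

    result = run_analysis(
        table,
        genes=genes,
        fasta=fasta,
        filter_config=config.filter_config,
        alpha_fdr=config.alpha_fdr,
        enrichment_category=config.enrichment_category,
        genotypes=genotypes,
    )

    pd.DataFrame(result.filter_report.as_rows()).to_csv(
        out / "filter_report.tsv", sep="\t", index=False
    )
    psio.write_results(
        result_rows(result.association, result.annotations), out / "association.tsv"
    )
    psio.write_results(
        result_rows(result.significant, result.annotations),
        out / "significant.bed",
        format="bed",
    )
    pd.DataFrame(
        [
            {
                "chromosome": f.chromosome,
                "m": f.m,
                "k": f.k,
                "threshold_neg_log10": f.threshold_neg_log10,
            }
            for f in result.fdr
        ]
    ).to_csv(out / "fdr_summary.tsv", sep="\t", index=False)
    sweep_table(result.sweep_tests).to_csv(out / "sweep_tests.tsv", sep="\t", index=False)
    if result.enrichment:
        pd.DataFrame(
            [
                {
                    "category": e.category,
                    "chromosome": e.chromosome,
                    "a": e.a,
                    "b": e.b,
                    "c": e.c,
                    "d": e.d,
                    "proportion_in": e.proportion_in,
                    "proportion_out": e.proportion_out,
                    "fisher_p": e.fisher_p,
                }
                for e in result.enrichment
            ]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if result.per_gene is not None:
        result.per_gene.to_csv(out / "per_gene.tsv", sep="\t", index=False)
    if result.validation is not None:
        result.validation.to_csv(out / "validation.tsv", sep="\t", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2)
    return result
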