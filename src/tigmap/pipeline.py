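"""End-to-end pipeline driver.

Stage order mirrors the mapping study: genotype QC -> exclusion ->
grouping/ordering -> nrBC confirmation -> map statistics -> downstream
analyses (SNP effects, synteny). Every threshold applied and every marker
excluded is logged; given a seed the run is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import io as tio
from .genotypes import GenotypeMatrix
from .mapbuild import NrbcReport
from .mapstats import MapSummary
from .model import LinkageMapModel, LinkageMapResults
from .snpeffects import EffectSummary, SnpAnnotation, annotate_sites, \
    summarize_effects
from .synteny import SyntenyResult, multi_genome_report, permutation_test

logger = logging.getLogger("tigmap")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Report bundle from a full pipeline run."""

    results: LinkageMapResults
    map_summary: MapSummary
    nrbc_report: Optional[NrbcReport] = None
    annotations: Optional[List[SnpAnnotation]] = None
    effect_summary: Optional[EffectSummary] = None
    synteny: Dict[str, SyntenyResult] = field(default_factory=dict)
    synteny_report: Optional[pd.DataFrame] = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}"
                                   ) from exc
        return wrapped
    return deco


def run_pipeline(config: tio.PipelineConfig,
                 out_dir: Optional[str] = None) -> PipelineResult:
    """Run mapping and all configured downstream analyses.

    ``config.genotypes`` is required; nrBC confirmation, SNP-effect
    annotation and synteny testing run only when their inputs are
    configured. When ``out_dir`` is given, all artifact tables are written
    beneath it.
    """
    logger.info("configuration: %s", config)
    if config.genotypes is None:
        raise RuntimeError("pipeline stage 'mapping' failed: no genotype "
                           "matrix configured")

    matrix = _stage("read_genotypes")(tio.read_genotypes)(
        config.genotypes, config.dialect)
    logger.info("read %d markers x %d individuals", matrix.n_markers,
                matrix.n_individuals)

    model = LinkageMapModel(matrix, lod_min=config.lod_min,
                            r_max=config.r_max,
                            chi2_flag_threshold=config.chi2_flag,
                            rf_threshold=config.rf_threshold)
    results = _stage("mapping")(model.fit)()
    for m in results.excluded_markers:
        logger.info("excluded marker %s (implied female recombination > %g)",
                    m, config.rf_threshold)
    n_flagged = int(results.segregation["flagged"].sum())
    logger.info("segregation test: %d marker(s) flagged at chi2 > %g",
                n_flagged, config.chi2_flag)
    logger.info("map: %d groups, %.1f cM summed", results.map.n_groups,
                results.map.summed_length_cM)

    nrbc_report = None
    if config.nrbc:
        nrbc = _stage("read_nrbc")(tio.read_genotypes)(config.nrbc,
                                                       config.dialect)
        nrbc_report = _stage("nrbc_confirmation")(results.confirm_nrbc)(nrbc)
        logger.info("nrBC confirmation: %s",
                    "consistent" if nrbc_report.all_consistent
                    else "INCONSISTENT")

    map_summary = _stage("map_stats")(results.map_summary)(
        genome_size_Mb=config.genome_Mb,
        reference_length_cM=config.reference_length_cM)

    annotations = effect_summary = None
    if config.transcripts_fasta and config.cds_table and config.snp_sites:
        transcripts = _stage("read_transcripts")(tio.read_transcripts)(
            config.transcripts_fasta, config.cds_table)
        sites, site_tr = _stage("read_snp_sites")(tio.read_snp_sites)(
            config.snp_sites)
        annotations = _stage("snp_effects")(annotate_sites)(
            transcripts, sites, site_tr or None)
        effect_summary = summarize_effects(annotations)
        logger.info("snp effects: %d/%d translated, %d synonymous",
                    effect_summary.n_translated, effect_summary.n_total,
                    effect_summary.n_synonymous)

    synteny_results: Dict[str, SyntenyResult] = {}
    synteny_frame = None
    if config.homologs:
        tables = _stage("read_homologs")(tio.read_homologs)(config.homologs)
        for ref, table in tables.items():
            synteny_results[ref] = _stage(f"synteny[{ref}]")(
                permutation_test)(table, n_perm=config.n_perm,
                                  alpha=config.alpha,
                                  n_tests=config.n_tests,
                                  rng_seed=config.rng_seed)
            logger.info("synteny %s: %d units, p = %.4g", ref,
                        synteny_results[ref].observed_units,
                        synteny_results[ref].p_value)
        synteny_frame = multi_genome_report(synteny_results.values())

    bundle = PipelineResult(results=results, map_summary=map_summary,
                            nrbc_report=nrbc_report,
                            annotations=annotations,
                            effect_summary=effect_summary,
                            synteny=synteny_results,
                            synteny_report=synteny_frame)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tio.write_map(bundle.results.map, out / "map.tsv")
    bundle.results.pairwise.to_csv(out / "pairwise.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    qc = bundle.results.segregation.merge(
        bundle.results.rf_filter[["marker", "rf_hat", "excluded"]],
        on="marker", how="left")
    qc.to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.6g")
    bundle.results.marker_accounting().to_csv(out / "markers.tsv", sep="\t",
                                              index=False)
    with (out / "summary.txt").open("w") as fh:
        fh.write(bundle.results.summary() + "\n")
    if bundle.synteny_report is not None:
        bundle.synteny_report.to_csv(out / "synteny.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    if bundle.annotations is not None:
        rows = [{
            "marker": a.marker, "located": a.located,
            "transcript": a.transcript_id, "strand": a.strand,
            "position": a.position, "translated": a.translated,
            "codon_p1": a.codons[0] if a.codons else None,
            "codon_p2": a.codons[1] if a.codons else None,
            "synonymous": a.synonymous,
            "n_additional_synonymous": a.n_additional_synonymous,
        } for a in bundle.annotations]
        pd.DataFrame(rows).to_csv(out / "snp_effects.tsv", sep="\t",
                                  index=False)
    logger.info("artifacts written to %s", out)
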