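"""File formats and configuration.

All tables are tab-delimited text with a header row; coordinates are
1-based inclusive. Genotype matrices are marker-major: first column the
marker id, remaining columns one per individual, calls in a declared code
dialect (default ``AA/AB/BB/--``; JoinMap-style ``a/h/b/-`` accepted via
``dialect="joinmap"``). Malformed rows are reported with their line
number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .genome import GenomeModel
from .genotypes import DIALECTS, GenotypeMatrix
from .mapbuild import GeneticMap
from .snpeffects import SnpSite, TranscriptRecord
from .synteny import HomologTable

__all__ = ["read_genotypes", "write_genotypes", "read_genome", "write_genome",
           "read_map", "write_map", "read_homologs", "read_transcripts",
           "read_snp_sites", "PipelineConfig", "load_config"]


# ----------------------------------------------------------------------
# Genotype matrices
# ----------------------------------------------------------------------

def read_genotypes(path, dialect: str = "default") -> GenotypeMatrix:
    """Read a marker-major genotype matrix (see module docstring)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")
    mapping = DIALECTS[dialect]
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: line 1: expected marker column plus "
                             "at least one individual")
        individuals = header[1:]
        markers, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            marker, calls = fields[0], fields[1:]
            if marker in markers:
                raise ValueError(f"{path}: line {lineno}: duplicated marker "
                                 f"id {marker!r}")
            row = np.empty(len(calls), dtype=np.int8)
            for j, code in enumerate(calls):
                code = code.strip()
                if code not in mapping:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown genotype code "
                        f"{code!r} for dialect {dialect!r}")
                row[j] = mapping[code]
            markers.append(marker)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no marker rows")
    return GenotypeMatrix(markers, individuals, np.stack(rows))


def write_genotypes(matrix: GenotypeMatrix, path,
                    dialect: str = "default") -> None:
    inverse = {v: k for k, v in DIALECTS[dialect].items()}
    with Path(path).open("w") as fh:
        fh.write("marker\t" + "\t".join(matrix.individuals) + "\n")
        for i, marker in enumerate(matrix.markers):
            codes = [inverse[int(c)] for c in matrix.calls[i]]
            fh.write(marker + "\t" + "\t".join(codes) + "\n")


# ----------------------------------------------------------------------
# Genome model and genetic map tables
# ----------------------------------------------------------------------

def _read_table(path, required: List[str]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    return frame


def read_genome(path) -> GenomeModel:
    """Read (chromosome, marker, position_cM) rows into a GenomeModel."""
    return GenomeModel.from_frame(
        _read_table(path, ["chromosome", "marker", "position_cM"]))


def write_genome(genome: GenomeModel, path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    """Read (group, marker, position_cM) rows into a GeneticMap."""
    return GeneticMap.from_frame(
        _read_table(path, ["group", "marker", "position_cM"]))


def write_map(genetic_map: GeneticMap, path) -> None:
    genetic_map.to_frame().to_csv(path, sep="\t", index=False,
                                  float_format="%.6g")


# ----------------------------------------------------------------------
# Homolog tables
# ----------------------------------------------------------------------

def read_homologs(path, include_unanchored: bool = True
                  ) -> Dict[str, HomologTable]:
    """Read a homolog table, split per reference genome.

    Columns: ``marker, tcal_chr, ref_genome, ref_chr`` plus optional
    ``evalue`` and ``anchored``.
    """
    frame = _read_table(path, ["marker", "tcal_chr", "ref_genome", "ref_chr"])
    tables = {}
    for ref, grp in frame.groupby("ref_genome", sort=False):
        sub = grp.drop(columns=["ref_genome"]).reset_index(drop=True)
        if sub["marker"].duplicated().any():
            dup = sub.loc[sub["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"{path}: duplicated marker {dup!r} for "
                             f"reference {ref!r}")
        tables[str(ref)] = HomologTable(sub, str(ref),
                                        include_unanchored=include_unanchored)
    return tables


# ----------------------------------------------------------------------
# Transcripts and SNP sites
# ----------------------------------------------------------------------

def read_transcripts(fasta_path, cds_table_path
                     ) -> Dict[str, TranscriptRecord]:
    """FASTA transcripts plus a (transcript, cds_start, cds_end) table."""
    cds = _read_table(cds_table_path, ["transcript", "cds_start", "cds_end"])
    intervals = {str(r.transcript): (int(r.cds_start), int(r.cds_end))
                 for r in cds.itertuples()}
    records = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in intervals:
            raise ValueError(f"no CDS interval for transcript {rec.id!r}")
        start, end = intervals[rec.id]
        records[rec.id] = TranscriptRecord(rec.id, str(rec.seq), start, end)
    return records


def read_snp_sites(path) -> Tuple[List[SnpSite], Dict[str, str]]:
    """Read SNP anchor sites; returns (sites, marker -> transcript map).

    Columns: ``marker, anchor, offset, allele_p1, allele_p2`` plus an
    optional ``transcript`` column tying each site to its transcript.
    """
    frame = _read_table(path, ["marker", "anchor", "offset",
                               "allele_p1", "allele_p2"])
    sites, site_tr = [], {}
    for r in frame.itertuples():
        sites.append(SnpSite(str(r.marker), str(r.anchor), int(r.offset),
                             (str(r.allele_p1), str(r.allele_p2))))
        if "transcript" in frame.columns and not pd.isna(r.transcript):
            site_tr[str(r.marker)] = str(r.transcript)
    return sites, site_tr


# ----------------------------------------------------------------------
# Pipeline configuration
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat keyed configuration; unknown keys are rejected on load.

    The reference constants default to the published values for
    *T. californicus*: haploid genome size 244.5 Mb and a previously
    published corrected map length of 484.8 cM.
    """

    genotypes: Optional[str] = None
    nrbc: Optional[str] = None
    genome: Optional[str] = None
    homologs: Optional[str] = None
    transcripts_fasta: Optional[str] = None
    cds_table: Optional[str] = None
    snp_sites: Optional[str] = None
    dialect: str = "default"
    lod_min: float = 1.0
    r_max: float = 0.4
    chi2_flag: float = 14.0
    rf_threshold: float = 0.25
    alpha: float = 0.05
    n_tests: int = 4
    n_perm: int = 1000
    genome_Mb: float = 244.5
    reference_length_cM: float = 484.8
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.lod_min or not 0 < self.r_max <= 0.5:
            raise ValueError("lod_min must be > 0 and r_max in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1 or self.n_tests < 1:
            raise ValueError("n_perm and n_tests must be >= 1")
        if not 0 <= self.rf_threshold <= 0.5:
            raise ValueError("rf_threshold must be in [0, 0.5]")


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON-dialect config file, rejecting unknown keys."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
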