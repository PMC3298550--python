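"""Predicted effect of mapped SNPs on protein sequence.

Each SNP is carried on a short anchor sequence (the genotyping-assay
extension/flank). The anchor, with each allele substituted at the SNP
offset, is matched exactly against the transcript and its reverse
complement; a unique match locates the SNP on the transcript. Sites
inside the CDS are classified as synonymous or nonsynonymous under the
standard genetic code, and the number of *additional* synonymous alleles
at the site — third/fourth bases, distinct from both observed alleles,
whose codon encodes the same amino acid as the P1 codon — is counted.

All coordinates in the public interfaces are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from Bio.Seq import Seq

__all__ = ["TranscriptRecord", "SnpSite", "SnpAnnotation",
           "AmbiguousLocationError", "locate_snp", "classify_effect",
           "annotate_sites", "summarize_effects", "EffectSummary"]

_BASES = ("A", "C", "G", "T")


class AmbiguousLocationError(ValueError):
    """The anchor matches the transcript at more than one location."""


@dataclass
class TranscriptRecord:
    """A transcript with its coding interval (1-based, inclusive)."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not (1 <= self.cds_start <= self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"CDS [{self.cds_start}, {self.cds_end}] outside transcript "
                f"{self.id!r} of length {len(self.sequence)}")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError(f"CDS length of {self.id!r} not divisible by 3")

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1:self.cds_end]


@dataclass
class SnpSite:
    """A SNP anchored on an assay extension/flanking sequence.

    ``offset`` is the 1-based position of the SNP within ``anchor``;
    ``alleles`` are the (P1, P2) bases as read on the anchor strand.
    """

    marker: str
    anchor: str
    offset: int
    alleles: Tuple[str, str]

    def __post_init__(self):
        self.anchor = self.anchor.upper()
        self.alleles = (self.alleles[0].upper(), self.alleles[1].upper())
        if not 1 <= self.offset <= len(self.anchor):
            raise ValueError(f"offset outside anchor for {self.marker!r}")
        if (self.alleles[0] == self.alleles[1]
                or any(a not in _BASES for a in self.alleles)):
            raise ValueError(
                f"alleles must be two distinct bases, got {self.alleles}")


@dataclass
class SnpAnnotation:
    marker: str
    located: bool
    transcript_id: Optional[str] = None
    strand: Optional[str] = None          # "+" or "-"
    position: Optional[int] = None        # 1-based on the transcript
    translated: Optional[bool] = None
    codons: Optional[Tuple[str, str]] = None
    amino_acids: Optional[Tuple[str, str]] = None
    synonymous: Optional[bool] = None
    n_additional_synonymous: Optional[int] = None


def _find_all(haystack: str, needle: str) -> List[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def locate_snp(transcript: TranscriptRecord, site: SnpSite
               ) -> Optional[Tuple[int, str]]:
    """Locate a SNP on a transcript by exact anchor matching.

    The anchor with each allele substituted at the SNP offset is searched
    on both strands; all hits must agree on a single (position, strand).
    Returns the 1-based transcript position of the SNP and the strand, or
    ``None`` when no variant matches anywhere.
    """
    if len(site.anchor) < 12:
        raise ValueError(
            f"anchor for {site.marker!r} shorter than 12 nt; matching would "
            "not be reliable")
    seq = transcript.sequence
    off0 = site.offset - 1
    hits = set()
    for allele in site.alleles:
        variant = (site.anchor[:off0] + allele + site.anchor[off0 + 1:])
        for i in _find_all(seq, variant):
            hits.add((i + off0 + 1, "+"))
        rc = str(Seq(variant).reverse_complement())
        for i in _find_all(seq, rc):
            hits.add((i + (len(variant) - 1 - off0) + 1, "-"))
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousLocationError(
            f"anchor for {site.marker!r} matches {transcript.id!r} at "
            f"{sorted(hits)}")
    return next(iter(hits))


def classify_effect(transcript: TranscriptRecord, position: int,
                    alleles: Tuple[str, str], strand: str = "+",
                    marker: str = "") -> SnpAnnotation:
    """Classify a located SNP as untranslated/synonymous/nonsynonymous.

    ``position`` is 1-based on the transcript; ``alleles`` are as read on
    the matched strand (complemented here when strand is "-"). The
    additional-synonymous count is over the remaining bases (distinct from
    both observed alleles) whose codon is synonymous with the P1 codon.
    """
    if not 1 <= position <= len(transcript.sequence):
        raise ValueError(f"position {position} outside transcript "
                         f"{transcript.id!r}")
    if strand == "-":
        alleles = tuple(str(Seq(a).complement()) for a in alleles)
    elif strand != "+":
        raise ValueError(f"unknown strand: {strand!r}")
    a1, a2 = (a.upper() for a in alleles)

    ann = SnpAnnotation(marker=marker, located=True,
                        transcript_id=transcript.id, strand=strand,
                        position=position)
    if not transcript.cds_start <= position <= transcript.cds_end:
        ann.translated = False
        return ann
    ann.translated = True
    cds_off = position - transcript.cds_start
    codon_start = cds_off - cds_off % 3
    within = cds_off % 3
    codon = transcript.cds[codon_start:codon_start + 3]

    def sub(base):
        return codon[:within] + base + codon[within + 1:]

    codon1, codon2 = sub(a1), sub(a2)
    aa1, aa2 = (str(Seq(c).translate()) for c in (codon1, codon2))
    ann.codons = (codon1, codon2)
    ann.amino_acids = (aa1, aa2)
    ann.synonymous = aa1 == aa2
    ann.n_additional_synonymous = sum(
        1 for b in _BASES
        if b not in (a1, a2) and str(Seq(sub(b)).translate()) == aa1)
    return ann


def annotate_sites(transcripts: Dict[str, TranscriptRecord],
                   sites: Iterable[SnpSite],
                   site_transcripts: Optional[Dict[str, str]] = None
                   ) -> List[SnpAnnotation]:
    """Locate and classify each site.

    ``site_transcripts`` maps marker -> transcript id; without it every
    transcript is searched and a unique match across all of them is
    required. Sites that match nowhere yield ``located=False``.
    """
    out = []
    for site in sites:
        if site_transcripts and site.marker in site_transcripts:
            candidates = [transcripts[site_transcripts[site.marker]]]
        else:
            candidates = list(transcripts.values())
        found = []
        for tr in candidates:
            loc = locate_snp(tr, site)
            if loc is not None:
                found.append((tr, loc))
        if not found:
            out.append(SnpAnnotation(marker=site.marker, located=False))
            continue
        if len(found) > 1:
            raise AmbiguousLocationError(
                f"anchor for {site.marker!r} matches multiple transcripts: "
                f"{[tr.id for tr, _ in found]}")
        tr, (pos, strand) = found[0]
        out.append(classify_effect(tr, pos, site.alleles, strand,
                                   marker=site.marker))
    return out


@dataclass
class EffectSummary:
    n_total: int
    n_located: int
    n_translated: int
    pct_translated: float          # of all annotations
    n_synonymous: int
    pct_synonymous: float          # of translated
    n_with_additional_synonymous: int

    def rounded(self, decimals: int = 0) -> "EffectSummary":
        return EffectSummary(
            self.n_total, self.n_located, self.n_translated,
            round(self.pct_translated, decimals), self.n_synonymous,
            round(self.pct_synonymous, decimals),
            self.n_with_additional_synonymous)


def summarize_effects(annotations: Iterable[SnpAnnotation]) -> EffectSummary:
    """Counts and percentages: translated, synonymous, extra-allele loci."""
    anns = list(annotations)
    if not anns:
        raise ValueError("no annotations to summarise")
    n_total = len(anns)
    n_located = sum(a.located for a in anns)
    translated = [a for a in anns if a.translated]
    n_syn = sum(1 for a in translated if a.synonymous)
    n_extra = sum(1 for a in translated
                  if a.synonymous and (a.n_additional_synonymous or 0) >= 1)
    return EffectSummary(
        n_total=n_total, n_located=n_located, n_translated=len(translated),
        pct_translated=100.0 * len(translated) / n_total,
        n_synonymous=n_syn,
        pct_synonymous=(100.0 * n_syn / len(translated)) if translated else 0.0,
        n_with_additional_synonymous=n_extra)
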