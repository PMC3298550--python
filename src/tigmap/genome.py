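"""Genome model: the map truth used by the cross simulator.

A :class:`GenomeModel` is an ordered set of chromosomes, each carrying
ordered markers with positions in centimorgans from the chromosome start.
It plays the role of the "true" linkage map in simulation studies: the
per-chromosome genetic length ``L_i`` is the last marker position and
``m_i`` is the marker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd


@dataclass
class Chromosome:
    """One chromosome: ordered markers with cM positions from the start."""

    chrom_id: str
    markers: List[str]
    positions_cM: np.ndarray

    def __post_init__(self):
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        if len(self.markers) == 0:
            raise ValueError(f"chromosome {self.chrom_id!r} has no markers")
        if len(self.markers) != len(self.positions_cM):
            raise ValueError("markers and positions differ in length")
        if np.any(np.diff(self.positions_cM) < 0):
            raise ValueError(
                f"positions not non-decreasing on chromosome {self.chrom_id!r}")

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1] - self.positions_cM[0])

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class GenomeModel:
    """Ordered chromosomes; marker ids must be globally unique."""

    chromosomes: List[Chromosome] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m in seen:
                    raise ValueError(f"duplicated marker id: {m!r}")
                seen.add(m)

    @property
    def markers(self) -> List[str]:
        return [m for c in self.chromosomes for m in c.markers]

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    @property
    def total_length_cM(self) -> float:
        return float(sum(c.length_cM for c in self.chromosomes))

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.chrom_id, m, p)
                for c in self.chromosomes
                for m, p in zip(c.markers, c.positions_cM)]
        return pd.DataFrame(rows, columns=["chromosome", "marker", "position_cM"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenomeModel":
        chroms = []
        for chrom_id, grp in frame.groupby("chromosome", sort=False):
            chroms.append(Chromosome(str(chrom_id),
                                     [str(m) for m in grp["marker"]],
                                     grp["position_cM"].to_numpy(float)))
        return cls(chroms)


def default_genome(n_chromosomes: int = 12, n_markers: int = 190,
                   min_length_cM: float = 19.0, max_length_cM: float = 32.0,
                   ) -> GenomeModel:
    """Study-scale genome: 12 chromosomes spanning 19-32 cM, 190 markers.

    Chromosome lengths are evenly graded from ``min_length_cM`` to
    ``max_length_cM``; markers are allocated proportionally to length
    (largest-remainder rounding, at least two per chromosome) and spaced
    uniformly along each chromosome.
    """
    if n_chromosomes < 1 or n_markers < 2 * n_chromosomes:
        raise ValueError("need >= 2 markers per chromosome")
    lengths = np.linspace(min_length_cM, max_length_cM, n_chromosomes)
    # proportional allocation with largest-remainder rounding
    quota = n_markers * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 2)
    remainder = quota - np.floor(quota)
    short = n_markers - counts.sum()
    if short > 0:
        for i in np.argsort(-remainder)[:short]:
            counts[i] += 1
    elif short < 0:
        for i in np.argsort(remainder):
            if short == 0:
                break
            if counts[i] > 2:
                counts[i] -= 1
                short += 1
    chroms = []
    k = 0
    for i, (L, m) in enumerate(zip(lengths, counts), start=1):
        markers = [f"chr{i:02d}_m{j + 1:02d}" for j in range(m)]
        positions = np.linspace(0.0, L, m)
        chroms.append(Chromosome(f"chr{i:02d}", markers, positions))
        k += m
    return GenomeModel(chroms)
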