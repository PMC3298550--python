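"""Summary statistics of a genetic map.

Implements the standard report quantities for a linkage map:

* mean and maximum intermarker distance — mean = summed map length over
  the number of adjacent intervals (n_markers - n_groups);
* corrected total map length (chromosome-end correction)
  ``Ltot = sum_i (L_i + 2) * (m_i + 1) / (m_i - 1)``, where L_i is the
  genetic length of group i and m_i its marker count;
* expected genome coverage ``c = 1 - exp(-2 d n / L)`` for mean spacing
  d (cM), marker count n and reference genome length L (cM);
* genome-wide recombination rate (cM/Mbp) and marker density
  (Mbp/marker) given a physical genome size.

Two coverage conventions are supported (see :class:`MapSummary`): the
default "reconstructed" profile takes d = summed length / n and an
externally supplied reference map length; the alternative "results"
profile takes d = mean intermarker distance and the map's own corrected
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .mapbuild import GeneticMap

__all__ = ["MapSummary", "intermarker_stats", "corrected_length", "coverage",
           "rate_and_density", "summarize_map"]


def intermarker_stats(genetic_map: GeneticMap) -> Tuple[float, float]:
    """(mean, max) adjacent intermarker distance in cM.

    The mean is summed map length / (n_markers - n_groups), i.e. per
    adjacent interval; the max is over all adjacent intervals.
    """
    intervals = np.concatenate([np.diff(g.positions_cM)
                                for g in genetic_map.groups
                                if g.n_markers >= 2] or [np.empty(0)])
    if intervals.size == 0:
        raise ValueError("map has no adjacent marker intervals")
    n_intervals = genetic_map.n_markers - genetic_map.n_groups
    mean = genetic_map.summed_length_cM / n_intervals
    return float(mean), float(intervals.max())


def corrected_length(genetic_map: GeneticMap) -> float:
    """Chromosome-end-corrected total map length in cM.

    ``sum_i (L_i + 2) * (m_i + 1) / (m_i - 1)``. Single-marker groups
    contribute ``L_i + 2`` with a warning (the correction factor is
    undefined at m = 1).
    """
    total = 0.0
    for g in genetic_map.groups:
        if g.n_markers < 2:
            warnings.warn(
                f"group {g.group_id} has a single marker; contributing "
                "L + 2 without the (m+1)/(m-1) factor", stacklevel=2)
            total += g.length_cM + 2.0
        else:
            total += (g.length_cM + 2.0) * (g.n_markers + 1) / (g.n_markers - 1)
    return float(total)


def coverage(d: float, n: int, L: float) -> float:
    """Expected proportion of the genome within d cM of a marker.

    ``c = 1 - exp(-2 d n / L)`` with d the mean intermarker distance (cM),
    n the marker count and L the genome map length (cM).
    """
    if d <= 0 or n <= 0 or L <= 0:
        raise ValueError("d, n and L must all be positive")
    return float(1.0 - np.exp(-2.0 * d * n / L))


def rate_and_density(map_length_cM: float, genome_size_Mb: float,
                     n_markers: int) -> Tuple[float, float]:
    """(recombination rate cM/Mbp, marker density Mbp/marker)."""
    if map_length_cM <= 0 or genome_size_Mb <= 0 or n_markers <= 0:
        raise ValueError("inputs must be positive")
    return (float(map_length_cM / genome_size_Mb),
            float(genome_size_Mb / n_markers))


@dataclass
class MapSummary:
    """Printed summary statistics of a genetic map."""

    n_markers: int
    n_groups: int
    summed_length_cM: float
    mean_intermarker_cM: float
    max_intermarker_cM: float
    corrected_length_cM: float
    coverage: Optional[float] = None
    recomb_rate_cM_per_Mbp: Optional[float] = None
    density_Mbp_per_marker: Optional[float] = None

    def __post_init__(self):
        if self.coverage is not None and not 0 <= self.coverage <= 1:
            raise ValueError("coverage outside [0, 1]")


def summarize_map(genetic_map: GeneticMap,
                  genome_size_Mb: Optional[float] = None,
                  reference_length_cM: Optional[float] = None,
                  coverage_convention: str = "reconstructed") -> MapSummary:
    """Compute the full summary for a map.

    ``coverage_convention="reconstructed"`` (default) evaluates coverage
    with d = summed length / n_markers against ``reference_length_cM`` (a
    previously published corrected map length); ``"results"`` uses the
    mean intermarker distance and this map's own corrected length.
    Coverage is omitted when the needed reference is unavailable; rate and
    density are omitted without ``genome_size_Mb``.
    """
    mean_d, max_d = intermarker_stats(genetic_map)
    ltot = corrected_length(genetic_map)
    n = genetic_map.n_markers
    summed = genetic_map.summed_length_cM

    cov = None
    if coverage_convention == "reconstructed":
        if reference_length_cM is not None:
            cov = coverage(summed / n, n, reference_length_cM)
    elif coverage_convention == "results":
        cov = coverage(mean_d, n, ltot)
    else:
        raise ValueError(f"unknown coverage convention: {coverage_convention!r}")

    rate = density = None
    if genome_size_Mb is not None:
        rate, density = rate_and_density(ltot, genome_size_Mb, n)

    return MapSummary(
        n_markers=n, n_groups=genetic_map.n_groups,
        summed_length_cM=summed, mean_intermarker_cM=mean_d,
        max_intermarker_cM=max_d, corrected_length_cM=ltot,
        coverage=cov, recomb_rate_cM_per_Mbp=rate,
        density_Mbp_per_marker=density)
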