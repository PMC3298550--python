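"""Model/Results interface for linkage-map estimation.

:class:`LinkageMapModel` is constructed from an F2 genotype matrix and
the mapping thresholds; :meth:`LinkageMapModel.fit` runs the full
estimation — segregation-distortion testing, all-pairs two-point
estimation under female achiasmy, single-linkage grouping, SARF ordering,
Kosambi positioning, and the implied-female-recombination exclusion
filter (after which the map is rebuilt without the excluded markers) —
and returns a :class:`LinkageMapResults` carrying the map, the
per-stage tables, diagnostics and a ``summary()`` report.

Example
-------
>>> from tigmap import default_genome, simulate_f2, CrossConfig
>>> from tigmap.model import LinkageMapModel
>>> genome = default_genome()
>>> f2 = simulate_f2(genome, CrossConfig(rng_seed=1))
>>> res = LinkageMapModel(f2).fit()
>>> res.map.n_groups
12
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .mapbuild import (GeneticMap, NrbcReport, build_map, confirm_with_nrbc,
                       group_markers)
from .mapstats import MapSummary, summarize_map
from .qc import female_recomb_filter, segregation_frame, segregation_test
from .twopoint import pairwise_estimates


class LinkageMapModel:
    """Achiasmatic-F2 linkage map estimator.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        F2 intercross calls (P1 homozygote / heterozygote / P2 homozygote /
        missing), markers x individuals.
    lod_min, r_max : float
        Grouping thresholds: a marker pair links when LOD >= lod_min and
        r_hat <= r_max.
    chi2_flag_threshold : float
        Flagging threshold for the segregation-distortion chi-square.
    rf_threshold : float
        Implied-female-recombination level above which a marker is
        excluded from the final map.
    """

    def __init__(self, genotypes: GenotypeMatrix, lod_min: float = 1.0,
                 r_max: float = 0.4, chi2_flag_threshold: float = 14.0,
                 rf_threshold: float = 0.25):
        self.genotypes = genotypes
        self.lod_min = lod_min
        self.r_max = r_max
        self.chi2_flag_threshold = chi2_flag_threshold
        self.rf_threshold = rf_threshold

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, dialect: str = "default",
                       **kwargs) -> "LinkageMapModel":
        """Build from a string-coded marker x individual DataFrame."""
        return cls(GenotypeMatrix.from_frame(frame, dialect), **kwargs)

    def fit(self, apply_rf_filter: bool = True) -> "LinkageMapResults":
        """Estimate the map; see the module docstring for the stages."""
        matrix = self.genotypes
        segregation = segregation_frame(
            segregation_test(matrix, self.chi2_flag_threshold))

        pairwise = pairwise_estimates(matrix)
        partition = group_markers(matrix.markers, pairwise,
                                  self.lod_min, self.r_max)
        initial_map = build_map(partition, pairwise)

        rf_table = pd.DataFrame(columns=["marker", "group", "rf_hat",
                                         "excluded", "note"])
        excluded: List[str] = []
        final_map = initial_map
        if apply_rf_filter:
            rf_table = female_recomb_filter(initial_map, matrix,
                                            self.rf_threshold)
            excluded = sorted(rf_table.loc[rf_table["excluded"], "marker"])
            if excluded:
                kept = matrix.drop(excluded)
                pairwise_kept = pairwise[
                    ~pairwise["marker_i"].isin(excluded)
                    & ~pairwise["marker_j"].isin(excluded)]
                partition = group_markers(kept.markers, pairwise_kept,
                                          self.lod_min, self.r_max)
                final_map = build_map(partition, pairwise_kept)

        return LinkageMapResults(
            model=self, map=final_map, initial_map=initial_map,
            pairwise=pairwise, segregation=segregation,
            rf_filter=rf_table, excluded_markers=excluded)


@dataclass
class LinkageMapResults:
    """Fitted linkage map with per-stage tables and diagnostics."""

    model: LinkageMapModel
    map: GeneticMap
    initial_map: GeneticMap
    pairwise: pd.DataFrame
    segregation: pd.DataFrame
    rf_filter: pd.DataFrame
    excluded_markers: List[str]
    _nrbc_report: Optional[NrbcReport] = field(default=None, repr=False)

    # ------------------------------------------------------------------
    def map_summary(self, genome_size_Mb: Optional[float] = None,
                    reference_length_cM: Optional[float] = None,
                    coverage_convention: str = "reconstructed") -> MapSummary:
        """Map statistics (lengths, spacing, coverage, rate, density)."""
        return summarize_map(self.map, genome_size_Mb, reference_length_cM,
                             coverage_convention)

    def confirm_nrbc(self, nrbc: GenotypeMatrix,
                     max_mismatch_rate: float = 0.0) -> NrbcReport:
        """Check linkage groups against non-recombinant backcross calls."""
        self._nrbc_report = confirm_with_nrbc(self.map, nrbc,
                                              max_mismatch_rate)
        return self._nrbc_report

    def marker_accounting(self) -> pd.DataFrame:
        """Every input marker with its fate: mapped or excluded (reason)."""
        mapped = set(self.map.markers)
        rows = []
        for m in self.model.genotypes.markers:
            if m in mapped:
                rows.append({"marker": m, "status": "mapped", "reason": ""})
            elif m in self.excluded_markers:
                rows.append({"marker": m, "status": "excluded",
                             "reason": "implied female recombination "
                                       f"> {self.model.rf_threshold}"})
            else:
                rows.append({"marker": m, "status": "unplaced", "reason": ""})
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def summary(self, genome_size_Mb: Optional[float] = None,
                reference_length_cM: Optional[float] = None) -> str:
        """Human-readable estimation report."""
        s = self.map_summary(genome_size_Mb, reference_length_cM)
        lines = [
            "Linkage map estimation (achiasmatic F2 model)",
            "=" * 53,
            f"Individuals:             {self.model.genotypes.n_individuals}",
            f"Input markers:           {self.model.genotypes.n_markers}",
            f"Mapped markers:          {s.n_markers}",
            f"Excluded (rf filter):    {len(self.excluded_markers)}",
            f"Distortion-flagged:      "
            f"{int(self.segregation['flagged'].sum())}"
            f" (chi2 > {self.model.chi2_flag_threshold})",
            f"Linkage groups:          {s.n_groups}",
            f"Summed map length:       {s.summed_length_cM:.1f} cM",
            f"Corrected length (Ltot): {s.corrected_length_cM:.1f} cM",
            f"Mean intermarker:        {s.mean_intermarker_cM:.2f} cM",
            f"Max intermarker:         {s.max_intermarker_cM:.2f} cM",
        ]
        if s.coverage is not None:
            lines.append(f"Genome coverage:         {100 * s.coverage:.1f} %")
        if s.recomb_rate_cM_per_Mbp is not None:
            lines.append(
                f"Recombination rate:      {s.recomb_rate_cM_per_Mbp:.2f} cM/Mbp")
            lines.append(
                f"Marker density:          {s.density_Mbp_per_marker:.2f} "
                "Mbp/marker")
        lines.append("-" * 53)
        lines.append("group  markers  length_cM")
        for g in self.map.groups:
            lines.append(f"{g.group_id:>5}  {g.n_markers:>7}  {g.length_cM:>9.1f}")
        if self._nrbc_report is not None:
            ok = self._nrbc_report.all_consistent
            lines.append("-" * 53)
            lines.append(f"nrBC confirmation:       "
                         f"{'all groups consistent' if ok else 'INCONSISTENT'}")
            if self._nrbc_report.flagged_pairs:
                lines.append(f"  co-segregating pairs:  "
                             f"{self._nrbc_report.flagged_pairs}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_map(self, ax=None):
        """Simple linkage-map diagram (groups as bars, markers as ticks)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for x, g in enumerate(self.map.groups, start=1):
            ax.plot([x, x], [0, g.length_cM], color="0.4", lw=4,
                    solid_capstyle="round", zorder=1)
            ax.hlines(g.positions_cM, x - 0.18, x + 0.18, color="k",
                      lw=0.8, zorder=2)
        ax.set_xticks(range(1, self.map.n_groups + 1))
        ax.set_xticklabels([g.group_id for g in self.map.groups])
        ax.invert_yaxis()
        ax.set_xlabel("linkage group")
        ax.set_ylabel("position (cM)")
        return ax
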