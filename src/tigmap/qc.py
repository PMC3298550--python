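"""Marker quality control.

Two exclusion procedures are provided:

* a per-marker segregation-distortion test — observed P1 vs P2 allele
  counts against the Mendelian 1:1 expectation, chi-square with df = 1,
  flagged when the statistic exceeds a configurable threshold (default
  14.0) and Bonferroni-corrected p-values across tested markers;
* the implied-female-recombination filter — for each mapped marker, fit
  the sex-specific two-point model against its nearest map neighbours; a
  marker whose haplotypes can only be explained by female recombination
  above a threshold (default 25%) is excluded, since female recombination
  is biologically known not to occur above the percent level. Inflated
  implied female recombination is the signature of genotyping artefacts
  such as cryptic polymorphism.

The allele-count reading of the distortion test (df = 1) is the default;
the 1:2:1 genotype test (df = 2) is available via ``test="genotype"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .genotypes import GenotypeMatrix
from .mapbuild import GeneticMap
from .twopoint import count_pair_classes, estimate_r_sexspecific

__all__ = ["SegregationTestResult", "segregation_test",
           "female_recomb_filter"]


@dataclass
class SegregationTestResult:
    marker: str
    chi_square: float
    df: int
    p_value: float
    bonferroni_p: float
    flagged: bool


def segregation_test(matrix: GenotypeMatrix,
                     chi2_flag_threshold: float = 14.0,
                     test: str = "allele") -> List[SegregationTestResult]:
    """Per-marker segregation-distortion chi-square test.

    ``test="allele"`` compares P1 allele count 2*AA + AB against P2 allele
    count 2*BB + AB under a 1:1 expectation (df = 1); ``test="genotype"``
    compares AA:AB:BB against 1:2:1 (df = 2). A marker is flagged iff its
    statistic exceeds ``chi2_flag_threshold``; Bonferroni-corrected
    p-values across all testable markers are also reported. All-missing
    markers yield an undefined (NaN) statistic and are never flagged.
    """
    if test not in ("allele", "genotype"):
        raise ValueError(f"unknown test: {test!r}")
    results = []
    stats, ps = [], []
    for marker in matrix.markers:
        calls = matrix.row(marker)
        n = np.bincount(calls[calls >= 0], minlength=3)
        total = n.sum()
        if total == 0:
            results.append(SegregationTestResult(marker, np.nan, 0, np.nan,
                                                 np.nan, False))
            stats.append(np.nan)
            ps.append(np.nan)
            continue
        if test == "allele":
            nA = 2 * n[0] + n[1]
            nB = 2 * n[2] + n[1]
            stat = (nA - nB) ** 2 / (nA + nB)
            df = 1
        else:
            expected = total * np.array([0.25, 0.5, 0.25])
            stat = float(((n - expected) ** 2 / expected).sum())
            df = 2
        p = float(chi2_dist.sf(stat, df))
        results.append(SegregationTestResult(marker, float(stat), df, p,
                                             np.nan, stat > chi2_flag_threshold))
        stats.append(stat)
        ps.append(p)
    n_tested = sum(1 for p in ps if not np.isnan(p))
    for res, p in zip(results, ps):
        if not np.isnan(p):
            res.bonferroni_p = min(1.0, p * n_tested)
    return results


def segregation_frame(results: List[SegregationTestResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"marker": r.marker, "chi2": r.chi_square, "df": r.df,
         "p": r.p_value, "bonferroni_p": r.bonferroni_p, "flagged": r.flagged}
        for r in results])


def female_recomb_filter(genetic_map: GeneticMap, matrix: GenotypeMatrix,
                         rf_threshold: float = 0.25,
                         markers: Optional[List[str]] = None) -> pd.DataFrame:
    """Exclude markers whose haplotypes imply female recombination.

    For each mapped marker (or the subset in ``markers``), the sex-specific
    two-point model is fitted against each nearest neighbour in map order
    (both sides where defined). The marker is excluded iff the minimum
    fitted female recombination fraction over its neighbours exceeds
    ``rf_threshold``: even the most favourable neighbour requires
    implausible female recombination to explain the data.

    Returns a table with columns ``marker, group, rf_hat, excluded, note``;
    ``rf_hat`` is the minimum over neighbours. Markers in single-marker
    groups are skipped with a note.
    """
    check = set(markers) if markers is not None else None
    rows = []
    for g in genetic_map.groups:
        for i, m in enumerate(g.markers):
            if check is not None and m not in check:
                continue
            if g.n_markers < 2:
                rows.append({"marker": m, "group": g.group_id,
                             "rf_hat": np.nan, "excluded": False,
                             "note": "single-marker group; skipped"})
                continue
            neighbours = [g.markers[j] for j in (i - 1, i + 1)
                          if 0 <= j < g.n_markers]
            rf = []
            for nb in neighbours:
                counts = count_pair_classes(matrix, m, nb)
                if counts.n_complete == 0:
                    continue
                rf.append(estimate_r_sexspecific(counts).r_f)
            if not rf:
                rows.append({"marker": m, "group": g.group_id,
                             "rf_hat": np.nan, "excluded": False,
                             "note": "no informative neighbour"})
                continue
            rf_min = float(min(rf))
            rows.append({"marker": m, "group": g.group_id, "rf_hat": rf_min,
                         "excluded": rf_min > rf_threshold, "note": ""})
    return pd.DataFrame(rows, columns=["marker", "group", "rf_hat",
                                       "excluded", "note"])
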