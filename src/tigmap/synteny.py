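"""Macrosynteny scoring against reference genomes.

Markers with a detected homolog in a reference genome form a table of
(marker, T. californicus chromosome, reference chromosome/scaffold) rows.
Where k >= 2 homologs colocalize on a single chromosome in *both* species
— i.e. share one (tcal_chr, ref_chr) cell — they contribute k - 1
syntenic units; the statistic is the total over cells. Significance is
assessed by permuting the reference-chromosome column against the fixed
map positions and recomputing the statistic, with Bonferroni correction
across the reference genomes tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["HomologTable", "SyntenyResult", "count_syntenic_units",
           "permutation_test", "multi_genome_report"]


@dataclass
class HomologTable:
    """Marker homolog locations for one reference genome.

    ``table`` columns: ``marker, tcal_chr, ref_chr`` (an optional boolean
    ``anchored`` column marks homologs on chromosome-anchored sequence).
    ``include_unanchored=False`` drops rows with ``anchored == False``,
    the treatment used for fully assembled genomes; scaffold-level
    references keep everything.
    """

    table: pd.DataFrame
    reference: str
    include_unanchored: bool = True
    n_linkage_groups: Optional[int] = None   # 1n of the reference, metadata

    def __post_init__(self):
        required = {"marker", "tcal_chr", "ref_chr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"homolog table missing columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            raise ValueError("one row per marker required")

    @property
    def rows(self) -> pd.DataFrame:
        if not self.include_unanchored and "anchored" in self.table.columns:
            return self.table[self.table["anchored"].astype(bool)]
        return self.table

    @property
    def n_alignments(self) -> int:
        return len(self.rows)


def _units(tcal: np.ndarray, ref: np.ndarray) -> int:
    # sum over (tcal_chr, ref_chr) cells of (k - 1) = n_rows - n_cells
    cells = {(a, b) for a, b in zip(tcal, ref)}
    return len(tcal) - len(cells)


def count_syntenic_units(table: HomologTable) -> int:
    """Total syntenic units: a cell of k colocalizing homologs scores k - 1."""
    rows = table.rows
    if len(rows) == 0:
        raise ValueError("empty homolog table")
    return _units(rows["tcal_chr"].to_numpy(), rows["ref_chr"].to_numpy())


@dataclass
class SyntenyResult:
    reference: str
    observed_units: int
    permutation_units: np.ndarray
    p_value: float
    threshold: float          # (1 - alpha/n_tests) quantile of the null
    permutation_max: int
    n_alignments: int
    alpha_corrected: float
    n_linkage_groups: Optional[int] = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_corrected


def permutation_test(table: HomologTable, n_perm: int = 1000,
                     alpha: float = 0.05, n_tests: int = 4,
                     rng_seed: int = 0) -> SyntenyResult:
    """Permutation test of the syntenic-unit count.

    Each permutation shuffles the reference-chromosome column against the
    fixed map chromosomes and recomputes the statistic; the add-one
    estimator ``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` avoids
    p = 0 from finite permutations. The reported threshold is the
    empirical (1 - alpha/n_tests) quantile of the null distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rows = table.rows
    if len(rows) < 2:
        raise ValueError("need at least 2 homolog rows")
    tcal = rows["tcal_chr"].to_numpy()
    ref = rows["ref_chr"].to_numpy().copy()
    observed = _units(tcal, ref)
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        rng.shuffle(ref)
        null[i] = _units(tcal, ref)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    alpha_corr = alpha / n_tests
    threshold = float(np.quantile(null, 1 - alpha_corr, method="higher"))
    return SyntenyResult(
        reference=table.reference, observed_units=observed,
        permutation_units=null, p_value=p, threshold=threshold,
        permutation_max=int(null.max()), n_alignments=len(rows),
        alpha_corrected=alpha_corr,
        n_linkage_groups=table.n_linkage_groups)


def multi_genome_report(results: Iterable[SyntenyResult]) -> pd.DataFrame:
    """One row per reference genome, starred when significant."""
    rows = []
    for res in results:
        rows.append({
            "reference": res.reference,
            "linkage_groups": res.n_linkage_groups,
            "n_align": res.n_alignments,
            "n_units": res.observed_units,
            "threshold": res.threshold,
            "permutation_max": res.permutation_max,
            "p_value": res.p_value,
            "significant": "*" if res.significant else "",
        })
    return pd.DataFrame(rows, columns=["reference", "linkage_groups",
                                       "n_align", "n_units", "threshold",
                                       "permutation_max", "p_value",
                                       "significant"])
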