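"""Genotype matrix container for two-line cross data.

Calls are stored marker-major as small integers:

====  =====================================
code  meaning
====  =====================================
0     AA — homozygote for the P1 (SD) allele
1     AB — heterozygote
2     BB — homozygote for the P2 (SC) allele
-1    missing call
====  =====================================

String dialects (``AA/AB/BB/--`` and the JoinMap-style ``a/h/b/-``) are
handled at the I/O boundary (:mod:`tigmap.io`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

AA, AB, BB, MISSING = 0, 1, 2, -1

#: canonical string codes, index-aligned with the integer codes
CODES = {0: "AA", 1: "AB", 2: "BB", -1: "--"}

DIALECTS = {
    "default": {"AA": 0, "AB": 1, "BB": 2, "--": -1},
    "joinmap": {"a": 0, "h": 1, "b": 2, "-": -1},
}


class GenotypeMatrix:
    """Markers x individuals matrix of genotype calls.

    Parameters
    ----------
    markers : sequence of str
        Marker identifiers (rows); must be unique.
    individuals : sequence of str
        Individual identifiers (columns); must be unique.
    calls : ndarray of int8, shape (n_markers, n_individuals)
        Integer genotype codes; only ``{0, 1, 2, -1}`` may appear.
    """

    def __init__(self, markers: Sequence[str], individuals: Sequence[str],
                 calls: np.ndarray):
        markers = list(markers)
        individuals = list(individuals)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(individuals)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(markers)} markers x {len(individuals)} individuals")
        if len(set(markers)) != len(markers):
            raise ValueError("duplicated marker id")
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicated individual id")
        bad = ~np.isin(calls, (0, 1, 2, -1))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(calls[bad])}")
        self.markers = markers
        self.individuals = individuals
        self.calls = calls
        self._index = {m: i for i, m in enumerate(markers)}

    # ------------------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def marker_index(self, marker: str) -> int:
        try:
            return self._index[marker]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker!r}") from None

    def row(self, marker: str) -> np.ndarray:
        return self.calls[self.marker_index(marker)]

    def subset(self, markers: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given markers, preserving the given order."""
        idx = [self.marker_index(m) for m in markers]
        return GenotypeMatrix(list(markers), self.individuals, self.calls[idx])

    def drop(self, markers: Sequence[str]) -> "GenotypeMatrix":
        drop = set(markers)
        keep = [m for m in self.markers if m not in drop]
        return self.subset(keep)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """String-coded DataFrame (markers as index, individuals as columns)."""
        arr = np.vectorize(CODES.get)(self.calls)
        return pd.DataFrame(arr, index=self.markers, columns=self.individuals)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dialect: str = "default"
                   ) -> "GenotypeMatrix":
        """Build from a string-coded DataFrame in the given code dialect."""
        try:
            mapping = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown genotype dialect: {dialect!r}") from None
        calls = np.empty(frame.shape, dtype=np.int8)
        values = frame.to_numpy()
        for i in range(frame.shape[0]):
            for j in range(frame.shape[1]):
                code = str(values[i, j]).strip()
                if code not in mapping:
                    raise ValueError(
                        f"unknown genotype code {code!r} for dialect "
                        f"{dialect!r} (marker {frame.index[i]!r})")
                calls[i, j] = mapping[code]
        return cls(list(frame.index), [str(c) for c in frame.columns], calls)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.markers == other.markers
                and self.individuals == other.individuals
                and np.array_equal(self.calls, other.calls))

    def __repr__(self) -> str:
        return (f"<GenotypeMatrix {self.n_markers} markers x "
                f"{self.n_individuals} individuals>")
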