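"""Linkage-group formation, marker ordering and map assembly.

Grouping is single-linkage transitive closure over the relation
``lod >= lod_min AND r_hat <= r_max`` (conjunction of the two thresholds,
defaults LOD 1.0 and r 0.4). Within-group ordering minimises the sum of
adjacent Kosambi distances (SARF): a chain is seeded from the pair with
the largest finite distance, remaining markers are inserted greedily at
the SARF-minimising position, and 2-opt segment reversals are applied to
convergence. Positions are cumulative Kosambi distances over adjacent
ordered pairs; adjacent estimates at r >= 0.5 are clamped to 0.4999 with
a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .twopoint import kosambi

__all__ = ["LinkageGroup", "GeneticMap", "group_markers", "order_group",
           "build_map", "confirm_with_nrbc", "NrbcReport"]

R_CLAMP = 0.4999   # stand-in for unlinked pairs when a finite distance is needed


@dataclass
class LinkageGroup:
    group_id: int
    markers: List[str]
    positions_cM: np.ndarray

    def __post_init__(self):
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        if len(self.markers) != len(self.positions_cM):
            raise ValueError("markers and positions differ in length")
        if len(self.positions_cM) and (
                self.positions_cM[0] != 0.0
                or np.any(np.diff(self.positions_cM) < 0)):
            raise ValueError("positions must start at 0 and be non-decreasing")

    @property
    def length_cM(self) -> float:
        """Genetic length L_i: position of the last marker."""
        return float(self.positions_cM[-1]) if len(self.positions_cM) else 0.0

    @property
    def n_markers(self) -> int:
        """Marker count m_i."""
        return len(self.markers)


@dataclass
class GeneticMap:
    """Ordered linkage groups with provenance metadata."""

    groups: List[LinkageGroup]
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for g in self.groups:
            for m in g.markers:
                if m in seen:
                    raise ValueError(f"marker {m!r} in more than one group")
                seen.add(m)

    @property
    def markers(self) -> List[str]:
        return [m for g in self.groups for m in g.markers]

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def summed_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    def to_frame(self) -> pd.DataFrame:
        rows = [(g.group_id, m, p) for g in self.groups
                for m, p in zip(g.markers, g.positions_cM)]
        return pd.DataFrame(rows, columns=["group", "marker", "position_cM"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: Optional[Dict] = None
                   ) -> "GeneticMap":
        groups = []
        for gid, grp in frame.groupby("group", sort=False):
            pos = grp["position_cM"].to_numpy(float)
            groups.append(LinkageGroup(int(gid), [str(m) for m in grp["marker"]],
                                       pos - pos[0]))
        return cls(groups, metadata or {})


# ----------------------------------------------------------------------
# Pairwise lookup helper
# ----------------------------------------------------------------------

class _PairTable:
    """Symmetric lookup of (r_hat, lod) from the long pairwise table."""

    def __init__(self, pairwise: pd.DataFrame):
        self.r = {}
        self.lod = {}
        mi = pairwise["marker_i"].to_numpy()
        mj = pairwise["marker_j"].to_numpy()
        rr = pairwise["r_hat"].to_numpy(float)
        ll = pairwise["lod"].to_numpy(float)
        for a, b, r, l in zip(mi, mj, rr, ll):
            self.r[(a, b)] = self.r[(b, a)] = r
            self.lod[(a, b)] = self.lod[(b, a)] = l

    def r_hat(self, a, b, default=0.5):
        r = self.r.get((a, b), default)
        return default if r is None or np.isnan(r) else r

    def distance(self, a, b):
        """Kosambi distance with unlinked pairs clamped to a finite value."""
        return kosambi(min(self.r_hat(a, b), R_CLAMP))


# ----------------------------------------------------------------------
# Grouping
# ----------------------------------------------------------------------

def group_markers(markers: Sequence[str], pairwise: pd.DataFrame,
                  lod_min: float = 1.0, r_max: float = 0.4
                  ) -> List[List[str]]:
    """Partition markers by single-linkage closure of the LOD/r relation.

    A pair joins when ``lod >= lod_min`` and ``r_hat <= r_max``; missing
    pairs are treated as unlinked. Groups are returned ordered by
    descending size, ties broken by the smallest member id; markers within
    a group are in sorted id order (ordering happens later). The result is
    invariant to the input order of ``markers``.
    """
    markers = sorted(markers)
    if not markers:
        return []
    index = {m: i for i, m in enumerate(markers)}
    parent = list(range(len(markers)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    linked = pairwise[(pairwise["lod"] >= lod_min)
                      & (pairwise["r_hat"] <= r_max)]
    for a, b in zip(linked["marker_i"], linked["marker_j"]):
        if a in index and b in index:
            ra, rb = find(index[a]), find(index[b])
            if ra != rb:
                parent[ra] = rb

    clusters: Dict[int, List[str]] = {}
    for m in markers:
        clusters.setdefault(find(index[m]), []).append(m)
    groups = sorted(clusters.values(), key=lambda g: (-len(g), g[0]))
    return groups


# ----------------------------------------------------------------------
# Ordering
# ----------------------------------------------------------------------

def _sarf(order: List[str], dist) -> float:
    return sum(dist(a, b) for a, b in zip(order, order[1:]))


def order_group(group: Sequence[str], pairwise: pd.DataFrame) -> List[str]:
    """Order one linkage group by SARF minimisation.

    Seed chain from the pair with the largest finite Kosambi distance
    (falling back to the overall largest if every pair is unlinked), greedy
    insertion of the remaining markers at the SARF-minimising position,
    then 2-opt reversal passes to convergence. The orientation with the
    lexicographically smaller terminal marker first is returned; all ties
    break by marker id.
    """
    group = sorted(group)
    if len(group) <= 2:
        return group
    table = _PairTable(pairwise)
    dist = table.distance

    # seed: largest finite distance (r < 0.5); fall back to largest clamped
    best_pair, best_d = None, -1.0
    for a, b in itertools.combinations(group, 2):
        if table.r_hat(a, b) >= 0.5:
            continue
        d = dist(a, b)
        if d > best_d:
            best_pair, best_d = (a, b), d
    if best_pair is None:
        best_pair = max(itertools.combinations(group, 2),
                        key=lambda p: (dist(*p), p))
    order = list(best_pair)

    remaining = [m for m in group if m not in order]
    while remaining:
        best = None   # (delta, marker, position)
        for m in remaining:
            for pos in range(len(order) + 1):
                if pos == 0:
                    delta = dist(m, order[0])
                elif pos == len(order):
                    delta = dist(order[-1], m)
                else:
                    a, b = order[pos - 1], order[pos]
                    delta = dist(a, m) + dist(m, b) - dist(a, b)
                cand = (delta, m, pos)
                if best is None or cand < best:
                    best = cand
        _, m, pos = best
        order.insert(pos, m)
        remaining.remove(m)

    order = _two_opt(order, dist)
    if order[-1] < order[0]:
        order.reverse()
    return order


def _two_opt(order: List[str], dist) -> List[str]:
    improved = True
    while improved:
        improved = False
        n = len(order)
        for i in range(n - 1):
            for j in range(i + 1, n):
                # reversing order[i:j+1] changes only the boundary edges
                delta = 0.0
                if i > 0:
                    delta += dist(order[i - 1], order[j]) - dist(order[i - 1], order[i])
                if j < n - 1:
                    delta += dist(order[i], order[j + 1]) - dist(order[j], order[j + 1])
                if delta < -1e-12:
                    order[i:j + 1] = reversed(order[i:j + 1])
                    improved = True
    return order


# ----------------------------------------------------------------------
# Map assembly
# ----------------------------------------------------------------------

def build_map(partition: Sequence[Sequence[str]], pairwise: pd.DataFrame,
              order: bool = True, metadata: Optional[Dict] = None
              ) -> GeneticMap:
    """Assemble a genetic map from a marker partition and pairwise estimates.

    Each group is ordered (unless ``order=False``, in which case the given
    order is kept) and positions are cumulative Kosambi distances over
    adjacent pairs; adjacent ``r_hat >= 0.5`` is clamped to 0.4999 with a
    warning.
    """
    table = _PairTable(pairwise)
    groups = []
    for gid, members in enumerate(partition, start=1):
        ordered = order_group(members, pairwise) if order else list(members)
        positions = [0.0]
        for a, b in zip(ordered, ordered[1:]):
            r = table.r_hat(a, b)
            if r >= 0.5:
                warnings.warn(
                    f"adjacent pair ({a}, {b}) has r_hat >= 0.5; "
                    f"clamping to {R_CLAMP}", stacklevel=2)
                r = R_CLAMP
            positions.append(positions[-1] + kosambi(r))
        groups.append(LinkageGroup(gid, ordered, np.array(positions)))
    return GeneticMap(groups, metadata or {})


# ----------------------------------------------------------------------
# Non-recombinant backcross confirmation
# ----------------------------------------------------------------------

@dataclass
class NrbcReport:
    """Outcome of checking a map against non-recombinant backcross data."""

    consistent: Dict[int, bool]            # group id -> within-group constancy
    mismatch_rates: Dict[int, float]       # worst per-individual mismatch rate
    cosegregation: pd.DataFrame            # group x group correlation
    flagged_pairs: List[tuple]             # groups with identical inheritance
    n_bb_calls: int

    @property
    def all_consistent(self) -> bool:
        return all(self.consistent.values())


def confirm_with_nrbc(genetic_map: GeneticMap, nrbc: GenotypeMatrix,
                      max_mismatch_rate: float = 0.0) -> NrbcReport:
    """Confirm linkage groups against the non-recombinant backcross.

    Because the backcross mother is achiasmatic, every individual must be
    uniformly AA or uniformly AB across the markers of a true chromosome:
    a group is consistent iff each individual's non-missing calls within it
    are constant up to ``max_mismatch_rate``. BB calls are impossible under
    the cross (the father carries only P1 alleles); they trigger a warning
    and count as mismatches. Groups whose per-individual inheritance
    vectors are identical across all individuals are flagged as possibly
    the same chromosome.
    """
    n_bb = 0
    consistent, worst = {}, {}
    vectors = {}
    for g in genetic_map.groups:
        present = [m for m in g.markers if m in nrbc._index]
        if not present:
            consistent[g.group_id] = True
            worst[g.group_id] = 0.0
            vectors[g.group_id] = np.full(nrbc.n_individuals, -1)
            continue
        calls = np.stack([nrbc.row(m) for m in present])
        bb = calls == 2
        if bb.any():
            n_bb += int(bb.sum())
            warnings.warn(
                f"{int(bb.sum())} BB call(s) in group {g.group_id}: "
                "impossible under the non-recombinant backcross; treated as "
                "mismatches", stacklevel=2)
        rates = np.zeros(nrbc.n_individuals)
        majority = np.full(nrbc.n_individuals, -1)
        for j in range(nrbc.n_individuals):
            col = calls[:, j]
            obs = col[col >= 0]
            if len(obs) == 0:
                continue
            counts = np.bincount(np.where(obs == 2, 3, obs), minlength=4)
            maj = int(np.argmax(counts[:2]))     # majority among AA/AB only
            majority[j] = maj
            rates[j] = np.mean(obs != maj)
        consistent[g.group_id] = bool(np.all(rates <= max_mismatch_rate))
        worst[g.group_id] = float(rates.max()) if len(rates) else 0.0
        vectors[g.group_id] = majority

    gids = [g.group_id for g in genetic_map.groups]
    corr = pd.DataFrame(np.eye(len(gids)), index=gids, columns=gids)
    flagged = []
    for a, b in itertools.combinations(gids, 2):
        va, vb = vectors[a], vectors[b]
        ok = (va >= 0) & (vb >= 0)
        if ok.sum() >= 2 and va[ok].std() > 0 and vb[ok].std() > 0:
            c = float(np.corrcoef(va[ok], vb[ok])[0, 1])
        elif ok.sum() and np.array_equal(va[ok], vb[ok]):
            c = 1.0
        else:
            c = np.nan
        corr.loc[a, b] = corr.loc[b, a] = c
        if ok.sum() and np.array_equal(va[ok], vb[ok]):
            flagged.append((a, b))
    return NrbcReport(consistent=consistent, mismatch_rates=worst,
                      cosegregation=corr, flagged_pairs=flagged,
                      n_bb_calls=n_bb)
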