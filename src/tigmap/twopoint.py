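"""Two-point linkage estimation under female achiasmy.

In *Tigriopus californicus* females transmit whole, non-recombinant
chromosomes, so all recombination observed in an F1 x F1 intercross is
paternal. For a pair of biallelic markers with F1 phase AB/ab this gives
two-locus genotype class probabilities

    P(AABB) = P(aabb) = (1-r)/4        P(AaBb) = (1-r)/2
    P(AABb) = P(AaBB) = P(Aabb) = P(aaBb) = r/4
    P(AAbb) = P(aaBB) = 0

where r is the male recombination fraction. The double-homozygote
recombinant classes AAbb/aaBB are impossible under this model; observed
individuals in those classes are excluded from the estimate and surfaced
in ``n_impossible`` (they signal genotyping error or cryptic female
recombination, which the QC stage tests explicitly).

The maximum-likelihood estimate is closed form: with R the total count of
the four single-heterozygote (recombinant) classes and n the retained
sample size, ``r_hat = R / n``, and the LOD against free recombination
(r = 1/2) is ``R*log10(2*r_hat) + (n-R)*log10(2*(1-r_hat))``.

A relaxed model with both a female (r_f) and a male (r_m) recombination
fraction is also provided; it underlies the distorted-marker filter. The
two-locus F2 likelihood is symmetric in (r_f, r_m) — the parents are not
identifiable from unphased genotypes — so the reported r_f is the smaller
of the two MLE coordinates, reflecting the biological prior that female
recombination is rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genotypes import GenotypeMatrix

__all__ = [
    "PairCounts", "TwoPointEstimate", "SexSpecificEstimate",
    "kosambi", "kosambi_inverse", "count_pair_classes",
    "estimate_r_achiasmatic", "estimate_r_sexspecific",
    "pairwise_estimates",
]

# class order used throughout: index = 3*g_i + g_j with g in {0:AA,1:Aa,2:aa}
CLASS_NAMES = ("AABB", "AABb", "AAbb",
               "AaBB", "AaBb", "Aabb",
               "aaBB", "aaBb", "aabb")

_RECOMBINANT = ("AABb", "AaBB", "Aabb", "aaBb")
_PARENTAL = ("AABB", "aabb", "AaBb")
_IMPOSSIBLE = ("AAbb", "aaBB")


# ----------------------------------------------------------------------
# Kosambi map function
# ----------------------------------------------------------------------

def kosambi(r):
    """Kosambi map distance in cM for recombination fraction ``r``.

    d = 25 * ln((1+2r)/(1-2r)) cM  (i.e. 1/4 ln(...) Morgans).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    if np.any(r >= 0.5):
        raise ValueError("kosambi distance is infinite at r >= 0.5")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(distance_cM):
    """Recombination fraction for a Kosambi map distance in cM.

    r = tanh(d_cM / 50) / 2; inverse of :func:`kosambi` to 1e-10.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ----------------------------------------------------------------------
# Pair counts
# ----------------------------------------------------------------------

@dataclass
class PairCounts:
    """Counts of the nine two-locus genotype classes for one marker pair."""

    AABB: int = 0
    AABb: int = 0
    AAbb: int = 0
    AaBB: int = 0
    AaBb: int = 0
    Aabb: int = 0
    aaBB: int = 0
    aaBb: int = 0
    aabb: int = 0

    def __post_init__(self):
        for name in CLASS_NAMES:
            if getattr(self, name) < 0:
                raise ValueError("class counts must be >= 0")

    @property
    def n_complete(self) -> int:
        return sum(getattr(self, name) for name in CLASS_NAMES)

    @property
    def n_impossible(self) -> int:
        return self.AAbb + self.aaBB

    @property
    def n_recombinant(self) -> int:
        return sum(getattr(self, name) for name in _RECOMBINANT)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CLASS_NAMES], float)


def count_pair_classes(matrix: GenotypeMatrix, marker_i: str, marker_j: str
                       ) -> PairCounts:
    """Tally the nine two-locus classes for a marker pair.

    Individuals missing at either marker are excluded; the A allele is the
    P1 allele by the matrix's fixed convention.
    """
    gi = matrix.row(marker_i)
    gj = matrix.row(marker_j)
    ok = (gi >= 0) & (gj >= 0)
    idx = 3 * gi[ok].astype(int) + gj[ok].astype(int)
    counts = np.bincount(idx, minlength=9)
    return PairCounts(**{name: int(c) for name, c in zip(CLASS_NAMES, counts)})


# ----------------------------------------------------------------------
# Achiasmatic estimator
# ----------------------------------------------------------------------

@dataclass
class TwoPointEstimate:
    """MLE of the paternal recombination fraction for one marker pair."""

    r_hat: float
    lod: float
    n: int              # retained sample size (complete minus impossible)
    n_impossible: int

    def __post_init__(self):
        if not 0.0 <= self.r_hat <= 0.5:
            raise ValueError("r_hat outside [0, 0.5]")


def _lod(R: float, n: float, r: float) -> float:
    lod = 0.0
    if R > 0:
        lod += R * np.log10(2 * r) if r > 0 else -np.inf
    if n - R > 0:
        lod += (n - R) * np.log10(2 * (1 - r))
    return lod


def estimate_r_achiasmatic(counts: PairCounts) -> TwoPointEstimate:
    """Closed-form MLE of r and the LOD score under female achiasmy."""
    n = counts.n_complete - counts.n_impossible
    if n <= 0:
        raise ValueError(
            "no informative individuals (all complete observations fall in "
            "impossible classes)")
    R = counts.n_recombinant
    r_hat = min(R / n, 0.5)
    lod = max(_lod(R, n, r_hat), 0.0)
    return TwoPointEstimate(r_hat=r_hat, lod=lod, n=n,
                            n_impossible=counts.n_impossible)


def pairwise_estimates(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Achiasmatic two-point estimates for every marker pair.

    Vectorised over all pairs via indicator-matrix products. Returns a long
    table with columns ``marker_i, marker_j, r_hat, lod, n, n_impossible``
    (upper triangle, i < j in matrix order). Pairs with no informative
    individuals get ``r_hat = NaN`` and ``lod = 0``.
    """
    G = matrix.calls
    ind = [(G == g).astype(np.float64) for g in (0, 1, 2)]
    N = {}  # N[(a, b)][i, j] = #individuals with class a at i and b at j
    for a in range(3):
        for b in range(3):
            N[(a, b)] = ind[a] @ ind[b].T

    R = N[(0, 1)] + N[(1, 0)] + N[(1, 2)] + N[(2, 1)]
    P = N[(0, 0)] + N[(2, 2)] + N[(1, 1)]
    n_imp = N[(0, 2)] + N[(2, 0)]
    n = R + P

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, R / np.maximum(n, 1), np.nan)
        r = np.minimum(r, 0.5)
        lod = np.where(R > 0, R * np.log10(np.maximum(2 * r, 1e-300)), 0.0)
        lod += np.where(n - R > 0, (n - R) * np.log10(2 * (1 - r)), 0.0)
        lod = np.where(n > 0, np.maximum(lod, 0.0), 0.0)

    iu, ju = np.triu_indices(matrix.n_markers, k=1)
    markers = np.asarray(matrix.markers, dtype=object)
    return pd.DataFrame({
        "marker_i": markers[iu],
        "marker_j": markers[ju],
        "r_hat": r[iu, ju],
        "lod": lod[iu, ju],
        "n": n[iu, ju].astype(int),
        "n_impossible": n_imp[iu, ju].astype(int),
    })


# ----------------------------------------------------------------------
# Sex-specific estimator
# ----------------------------------------------------------------------

@dataclass
class SexSpecificEstimate:
    """Joint MLE of female and male recombination fractions."""

    r_f: float
    r_m: float
    log_likelihood: float

    def __post_init__(self):
        if not (0 <= self.r_f <= 0.5 and 0 <= self.r_m <= 0.5):
            raise ValueError("recombination fractions outside [0, 0.5]")


def sexspecific_class_probs(r_f, r_m) -> np.ndarray:
    """Nine-class probabilities when both sexes recombine.

    Maternal gametes AB/ab each (1-r_f)/2 and Ab/aB each r_f/2; paternal
    likewise with r_m; classes by convolution of the two gametes. Order
    follows :data:`CLASS_NAMES`. Accepts scalars or broadcastable arrays
    (last axis of the result indexes the class).
    """
    u, v = np.broadcast_arrays(np.asarray(r_f, float), np.asarray(r_m, float))
    par = (1 - u) * (1 - v) / 4          # AABB, aabb
    imp = u * v / 4                      # AAbb, aaBB
    het = ((1 - u) * v + u * (1 - v)) / 4  # the four single-het classes
    dbl = ((1 - u) * (1 - v) + u * v) / 2  # AaBb
    return np.stack([par, het, imp, het, dbl, het, imp, het, par], axis=-1)


def _sexspecific_loglik(counts_arr: np.ndarray, u, v):
    # probabilities floored to keep the surface finite for the optimizer;
    # 0 * log(0) = 0 by convention
    p = np.maximum(sexspecific_class_probs(u, v), 1e-300)
    terms = np.where(counts_arr[..., :] == 0, 0.0, counts_arr * np.log(p))
    return terms.sum(axis=-1)


def estimate_r_sexspecific(counts: PairCounts, grid_step: float = 0.01
                           ) -> SexSpecificEstimate:
    """Joint MLE of (r_f, r_m) on [0, 0.5]^2.

    Coarse grid search followed by bounded quasi-Newton refinement. The
    likelihood is symmetric under swapping the two fractions, so the smaller
    coordinate is reported as r_f (see module docstring). With no
    impossible-class individuals the maximum lies on the r_f = 0 edge and
    the fit reduces exactly to the achiasmatic model.
    """
    arr = counts.as_array()
    if arr.sum() <= 0:
        raise ValueError("empty pair counts")
    grid = np.arange(0.0, 0.5 + 1e-12, grid_step)
    U, V = np.meshgrid(grid, grid, indexing="ij")
    ll = _sexspecific_loglik(arr, U, V)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)

    res = minimize(lambda x: -_sexspecific_loglik(arr, x[0], x[1]),
                   x0=[U[i, j], V[i, j]],
                   bounds=[(0.0, 0.5), (0.0, 0.5)], method="L-BFGS-B")
    u, v = res.x
    if -res.fun < ll[i, j]:       # refinement must not lose to the grid
        u, v = U[i, j], V[i, j]
    r_f, r_m = (u, v) if u <= v else (v, u)
    return SexSpecificEstimate(r_f=float(r_f), r_m=float(r_m),
                               log_likelihood=float(
                                   _sexspecific_loglik(arr, r_f, r_m)))
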