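"""Synthetic F2 and non-recombinant backcross genotype data.

The generator reproduces the statistical structure of an SD x SC
*Tigriopus californicus* mapping cross:

* the two parental isofemale lines are fixed for alternate alleles at
  every marker, so F1 phase is known (one all-P1 and one all-P2 haplotype);
* females are achiasmatic — a female gamete carries one whole parental
  chromosome per chromosome, with no within-chromosome switch points;
* male meiosis is modelled as a first-order Markov chain along each
  chromosome: between adjacent markers the parental-origin label switches
  with probability equal to the inverse-Kosambi of the intermarker map
  distance. No explicit interference model is imposed beyond what Kosambi
  distances encode at the adjacent-interval level.

F2 offspring unite a (non-recombinant) female F1 gamete with a
(recombinant) male F1 gamete. The non-recombinant backcross (nrBC),
(SD f x SC m) F1 female x SD male, pairs a whole maternal chromosome with
a paternal all-SD chromosome, so each chromosome is either all-AA or
all-AB per individual and BB never occurs — chromosome membership of
markers can be read off directly.

Noise layers (symmetric genotyping error, missingness) and optional
per-marker viability selection are applied after gamete union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .genome import GenomeModel
from .genotypes import MISSING, GenotypeMatrix
from .twopoint import kosambi_inverse

__all__ = ["CrossConfig", "simulate_gamete", "simulate_f2", "simulate_nrbc",
           "apply_noise"]


@dataclass
class CrossConfig:
    """Cross design and noise parameters.

    Defaults follow the study design: 250 F2 nauplii and 19 nrBC adults,
    clean calls (the QC stages are exercised by switching noise on).
    ``viability_weights`` maps marker id -> length-3 weights multiplying
    the survival probability of the AA/AB/BB classes.
    """

    n_f2: int = 250
    n_nrbc: int = 19
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    viability_weights: Optional[Dict[str, Tuple[float, float, float]]] = None
    rng_seed: int = 0

    def __post_init__(self):
        for rate in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.viability_weights:
            for m, w in self.viability_weights.items():
                if len(w) != 3 or any(x < 0 for x in w):
                    raise ValueError(
                        f"viability weights for {m!r} must be 3 values >= 0")


def _interval_switch_probs(genome: GenomeModel):
    """Per-chromosome adjacent-interval switch probabilities (inverse Kosambi)."""
    return [kosambi_inverse(np.diff(c.positions_cM)) if c.n_markers > 1
            else np.empty(0) for c in genome.chromosomes]


def simulate_gamete(genome: GenomeModel, parent_phase, sex: str,
                    rng: np.random.Generator) -> np.ndarray:
    """One gamete as parental-origin labels (0/1) per marker.

    ``parent_phase`` is a pair of haplotypes (arrays over all markers in
    genome order); the returned array holds the transmitted allele at each
    marker. Female meiosis transmits one whole parental chromosome per
    chromosome; male meiosis switches origin between adjacent markers with
    the inverse-Kosambi probability of the interval.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex label: {sex!r}")
    hap0, hap1 = (np.asarray(h) for h in parent_phase)
    if hap0.shape != (genome.n_markers,) or hap1.shape != hap0.shape:
        raise ValueError("phase haplotypes must cover every marker")
    origins = _simulate_origin_labels(genome, sex, 1, rng)[:, 0]
    phase = np.stack([hap0, hap1])
    return phase[origins, np.arange(genome.n_markers)]


def _simulate_origin_labels(genome: GenomeModel, sex: str, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Origin labels (markers x n gametes), vectorised over gametes."""
    switch = _interval_switch_probs(genome)
    blocks = []
    for chrom, r in zip(genome.chromosomes, switch):
        start = rng.integers(0, 2, size=n)
        if sex == "female" or chrom.n_markers == 1:
            blocks.append(np.broadcast_to(start, (chrom.n_markers, n)).copy())
            continue
        flips = rng.random((chrom.n_markers - 1, n)) < r[:, None]
        labels = np.empty((chrom.n_markers, n), dtype=np.int64)
        labels[0] = start
        np.cumsum(flips, axis=0, out=labels[1:])
        labels[1:] += start
        labels[1:] %= 2
        labels[0] %= 2
        blocks.append(labels)
    return np.concatenate(blocks, axis=0)


def _viability_accept_prob(genome: GenomeModel, calls: np.ndarray,
                           weights) -> np.ndarray:
    """Per-individual acceptance probability, normalised to max 1."""
    w = np.ones((genome.n_markers, 3))
    for idx, m in enumerate(genome.markers):
        if m in weights:
            w[idx] = weights[m]
    logw = np.log(np.maximum(w, 1e-300))
    per_ind = logw[np.arange(calls.shape[0])[:, None], calls].sum(axis=0)
    per_ind -= logw.max(axis=1).sum()   # normalise by the fittest genotype
    return np.exp(per_ind)


def simulate_f2(genome: GenomeModel, config: CrossConfig) -> GenotypeMatrix:
    """Simulate an F2 intercross (F1 female x F1 male) genotype matrix.

    Each offspring is the union of an achiasmatic female F1 gamete and a
    recombinant male F1 gamete; genotyping error, missingness and optional
    viability selection are applied afterwards. Fully determined by
    ``config.rng_seed``.
    """
    if config.n_f2 <= 0:
        raise ValueError("n_f2 must be positive")
    rng = np.random.default_rng(config.rng_seed)
    calls = _simulate_f2_calls(genome, config.n_f2, rng,
                               config.viability_weights)
    calls = apply_noise_array(calls, config.genotyping_error_rate,
                              config.missing_rate, rng)
    individuals = [f"F2_{i + 1:04d}" for i in range(config.n_f2)]
    return GenotypeMatrix(genome.markers, individuals, calls)


def _simulate_f2_calls(genome, n, rng, viability=None) -> np.ndarray:
    out = np.empty((genome.n_markers, 0), dtype=np.int8)
    while out.shape[1] < n:
        batch = max(n - out.shape[1], 1)
        # F1 phase: haplotype 0 = all P1 alleles, haplotype 1 = all P2
        maternal = _simulate_origin_labels(genome, "female", batch, rng)
        paternal = _simulate_origin_labels(genome, "male", batch, rng)
        calls = (maternal + paternal).astype(np.int8)  # 0=AA, 1=AB, 2=BB
        if viability:
            accept = rng.random(batch) < _viability_accept_prob(
                genome, calls, viability)
            calls = calls[:, accept]
        out = np.concatenate([out, calls], axis=1)
    return out[:, :n]


def simulate_nrbc(genome: GenomeModel, config: CrossConfig) -> GenotypeMatrix:
    """Simulate the non-recombinant backcross: F1 female x SD (P1) male.

    With zero noise every individual is, per chromosome, uniformly AA
    (maternal P1 chromosome) or uniformly AB (maternal P2 chromosome);
    BB cannot occur because the father carries only P1 alleles.
    """
    if config.n_nrbc <= 0:
        raise ValueError("n_nrbc must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.rng_seed, 1]).generate_state(1)[0])
    maternal = _simulate_origin_labels(genome, "female", config.n_nrbc, rng)
    calls = maternal.astype(np.int8)      # paternal allele always P1: 0 or 1
    calls = apply_noise_array(calls, config.genotyping_error_rate,
                              config.missing_rate, rng)
    individuals = [f"nrBC_{i + 1:03d}" for i in range(config.n_nrbc)]
    return GenotypeMatrix(genome.markers, individuals, calls)


def apply_noise_array(calls: np.ndarray, error_rate: float,
                      missing_rate: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """Corrupt integer calls in place-free fashion; see :func:`apply_noise`."""
    for rate in (error_rate, missing_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    calls = calls.copy()
    observed = calls >= 0
    if error_rate > 0:
        err = (rng.random(calls.shape) < error_rate) & observed
        # replace by one of the two other genotype codes, equiprobably
        shift = rng.integers(1, 3, size=calls.shape)
        calls[err] = (calls[err] + shift[err]) % 3
    if missing_rate > 0:
        miss = (rng.random(calls.shape) < missing_rate) & observed
        calls[miss] = MISSING
    return calls


def apply_noise(matrix: GenotypeMatrix, error_rate: float, missing_rate: float,
                rng: np.random.Generator) -> GenotypeMatrix:
    """Apply symmetric genotyping error, then missingness, per call.

    Each observed call is independently replaced with probability
    ``error_rate`` by one of the other two genotype codes (uniformly) and
    with probability ``missing_rate`` by the missing code. Already-missing
    calls are left untouched.
    """
    return GenotypeMatrix(matrix.markers, matrix.individuals,
                          apply_noise_array(matrix.calls, error_rate,
                                            missing_rate, rng))
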