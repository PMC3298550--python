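# Methods

## Cross model and assumptions

`tigmap` targets an F2 intercross between two lines fixed for alternate
alleles at every marker (here the San Diego and Santa Cruz
*Tigriopus californicus* isofemale lines), plus a non-recombinant
backcross (nrBC) of an F1 female to the P1 line. Two biological
assumptions drive everything:

1. **Female achiasmy.** Females transmit one whole parental chromosome per
   chromosome. Every crossover seen in the F2 is paternal, and in the
   nrBC each offspring is, per chromosome, uniformly heterozygous or
   uniformly P1-homozygous — chromosome membership of markers can be read
   directly.
2. **Known F1 phase.** Because the parental lines are fixed, every F1 is
   `AB/ab` at every marker pair; no phase inference is needed.

Male meiosis is simulated as a first-order Markov chain along each
chromosome: between adjacent markers the parental-origin label switches
with probability equal to the inverse Kosambi transform of the intermarker
distance, `r = ½·tanh(2d)` (d in Morgans). No explicit crossover
interference process is imposed beyond what the Kosambi function encodes
at the adjacent-interval scale; simulating at the level of adjacent
recombination fractions makes the simulation truth and the estimation
model consistent by construction, without committing to an interference
model the data could not check.

## Two-point estimation

Under achiasmy the nine two-locus genotype classes have probabilities
`(1−r)/4` (each parental homozygote class), `(1−r)/2` (double
heterozygote), `r/4` (each single-heterozygote class) and 0 for
`AAbb`/`aaBB`. The MLE is `r̂ = R/n` with R the single-heterozygote total
and n the informative count; the LOD against free recombination is
`R·log₁₀(2r̂) + (n−R)·log₁₀(2(1−r̂))`. Impossible-class individuals are
excluded from n and surfaced as `n_impossible` rather than silently
dropped: they are the model's own diagnostic for genotyping artefacts.
Estimates are clamped to [0, 0.5]; all pairs of a matrix are computed at
once via indicator-matrix products (nine m×m integer matrices from one
pass over the calls).

Note that for markers on *different* chromosomes the achiasmatic model is
misspecified (true independence puts 1/8 of individuals in the impossible
classes); the estimator then concentrates at the clamped boundary
r̂ = 0.5 with LOD ≈ 0, which is exactly the behaviour the grouping stage
needs.

### Sex-specific likelihood and identifiability

The relaxed model gives both parents recombination fractions (r_f, r_m);
class probabilities follow by convolving the two gamete distributions.
This likelihood is **exactly symmetric** under swapping r_f and r_m:
unphased F2 genotypes cannot tell which parent recombined. The package
therefore reports r_f as the *smaller* MLE coordinate, encoding the prior
that female recombination in this species is known to be rare (< 1%).
The consequence is deliberate: a marker is excluded only when even the
most favourable assignment of recombination to the parents requires
female recombination above the threshold. Maximisation uses a coarse grid
(step 0.01) on [0, 0.5]² followed by bounded L-BFGS-B refinement; class
probabilities are floored at 1e-300 so the surface stays finite at the
boundary; a refinement that loses to the grid is discarded.

## Map construction

* **Grouping** is single-linkage transitive closure of
  `LOD ≥ 1.0 AND r̂ ≤ 0.4` (both thresholds conjunctive — the conservative
  reading when the thresholds are stated separately). Missing pairs count
  as unlinked. Group ids are assigned by descending size, then smallest
  member id; the partition is invariant to marker input order.
* **Ordering** minimises the sum of adjacent Kosambi distances (SARF): the
  chain is seeded from the pair with the largest finite distance, the
  remaining markers are inserted greedily at the SARF-minimising position
  (ties broken by marker id), and 2-opt segment reversals run to
  convergence. Orientation is canonicalised so the lexicographically
  smaller terminal marker comes first. Exhaustive enumeration is the test
  oracle at small sizes; at the study's group sizes (12-20 markers) the
  procedure recovers the generating order or its mirror essentially
  always at n = 2000, and with ≥ 9 of 12 chromosomes exact at n = 250
  (residual flips are between near-zero-recombinant neighbours).
* **Positions** are cumulative Kosambi distances over adjacent ordered
  pairs. An adjacent estimate at r̂ ≥ 0.5 is clamped to 0.4999 with a
  warning rather than made infinite.
* **nrBC confirmation**: a group is consistent when every individual's
  non-missing calls within it are constant (configurable mismatch
  tolerance, default 0). BB calls are impossible under the backcross and
  are warned about and counted as mismatches. Groups whose per-individual
  inheritance vectors are identical across all individuals are flagged as
  possibly belonging to one chromosome — with 19 individuals two true
  chromosomes collide with probability 19 choose... 2⁻¹⁹ per orientation,
  i.e. ~2·10⁻⁶ per group pair, negligible at 12 groups.

## Marker QC

* **Segregation distortion**: per marker, P1 vs P2 allele counts
  (2·AA + AB vs 2·BB + AB) against 1:1 by χ² with df = 1 — the
  allele-count reading matches the published degrees of freedom; the
  1:2:1 genotype test (df = 2) is available via `test="genotype"`. A
  marker is flagged when χ² exceeds a configurable threshold whose
  default, 14.0, follows the source analysis even though it is not the
  df = 1 critical value for p < 0.001 (10.83); Bonferroni-corrected
  p-values across tested markers are reported alongside. Under a clean
  cross the flag rate is ≈ 1.4·10⁻⁴ per marker; note that with Bonferroni
  at family-wise α = 0.05, about 2-5% of whole crosses will still show
  one significant marker — that is the definition of the correction, not
  a defect.
* **Implied female recombination**: after map construction, each mapped
  marker is fitted with the sex-specific model against its nearest map
  neighbours (both sides where defined) and excluded when the minimum
  fitted r_f over neighbours exceeds 0.25. Markers in single-marker
  groups are skipped with a notice. When exclusions occur the map is
  regrouped and rebuilt without them. A consequence of the two thresholds
  worth knowing: for a *symmetric* artefact (calls scrambled regardless
  of parent, fitted r_f = r_m = t) the two-point estimate to a clean
  neighbour is 2t/(1+t), so "still grouped at r ≤ 0.4" and "excluded at
  t > 0.25" touch exactly at t = 0.25. Artefacts that load homozygote
  miscalls (e.g. cryptic polymorphism reading one line's allele as the
  other's) populate the impossible classes disproportionately and are
  detected comfortably inside the grouped region.

## Map statistics

Mean intermarker distance is summed length over adjacent intervals
(n − g); the corrected total length is `Σᵢ (Lᵢ+2)(mᵢ+1)/(mᵢ−1)`
(single-marker groups contribute Lᵢ + 2 with a warning); coverage is
`c = 1 − e^(−2dn/L)`. Two coverage conventions are supported because the
published figure is reproduced by d = summed length/n against the
*previously published* corrected reference length (484.8 cM), not by the
same report's own mean spacing and corrected length (which give ≈ 0.82).
The reconstructed convention is the default (`coverage_convention=
"reconstructed"`); the self-contained one is available as `"results"`.
The reference constants (haploid genome size 244.5 Mb, reference map
length 484.8 cM) live in configuration, not code.

## SNP effect classification

SNPs ride on assay anchor sequences (extension/flanks). Each anchor, with
each allele substituted at the SNP offset, is matched exactly against the
transcript and its reverse complement; a unique (position, strand) is
required — zero matches return not-found, multiple raise an ambiguity
error, because silently mislocating a SNP in the presence of repeats or
cryptic paralogy would corrupt downstream counts. Sites inside the CDS
are classified under the standard genetic code (nuclear transcripts);
`n_additional_synonymous` counts the at-most-two remaining bases whose
codon encodes the P1 amino acid. All public coordinates are 1-based
inclusive. Anchors shorter than 12 nt are refused as unreliable.

## Synteny

Homolog tables give one (map chromosome, reference chromosome) cell per
marker; a cell with k ≥ 2 homologs contributes k − 1 syntenic units
(generalising the stated k = 2 and k = 3 cases to any k). Significance:
the reference-chromosome column is shuffled against the fixed map column
(default 1000 permutations) and the add-one estimator
`p = (1 + #{null ≥ obs})/(n_perm + 1)` avoids exact zeros; the reported
threshold is the empirical (1 − α/n_tests) quantile of the null
(Bonferroni over the reference genomes tested, default 4 → α 0.0125),
with the null maximum also reported. Unanchored scaffolds can be dropped
(`include_unanchored=False`) for chromosome-level assemblies and kept for
scaffold-level ones. The statistic is invariant to chromosome relabelling
in either species, and a constant reference column yields p = 1 exactly.

## Synthetic data: what it does and does not emulate

The default genome is 12 chromosomes with genetic lengths graded 19-32 cM
and 190 markers allocated proportionally to length, uniformly spaced —
the study's scale, with uniform spacing standing in for the unpublished
per-chromosome marker positions. The generator reproduces achiasmatic
inheritance, Mendelian segregation, Kosambi-consistent male
recombination, symmetric genotyping error, missingness, and optional
per-marker viability selection (off by default; the study found no
distortion in larvae). It does not emulate assay chemistry, linked
viability selection across loci, triallelic sites, or real marker spacing
heterogeneity; passing tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to every
artefact of mass-spectrometry genotyping.

## Problem sizes and numerical choices in the test suite

Simulation-backed tests use 250-10,000 individuals depending on what the
assertion needs (10,000 for ±0.01 recombination-fraction recovery; 2000
for order recovery over 100 seeds; 250 at the study scale). The null
flag-rate check uses 50 crosses × 200 markers = 10⁴ marker-tests.
Grid-search oracles use step 10⁻⁴ for the one-parameter likelihood and
10⁻³ for the two-parameter one. Kosambi round-trips are exact to 10⁻¹⁰.
Ties everywhere break toward smaller values / lexicographically smaller
marker ids so all procedures are deterministic; every stochastic
component takes an explicit integer seed.

## Known limitations

* No multipoint likelihood: ordering quality rests on two-point
  estimates, which is adequate at n = 250 for ~2 cM spacing but can flip
  adjacent near-coincident markers.
* The sex-specific fit cannot attribute recombination to a specific
  parent from unphased F2 data (see identifiability above); the excess
  over the minimum assignment is what the filter acts on.
* The permutation test treats markers as exchangeable units; clustered
  paralogs violating that would inflate apparent synteny.
* Coverage and rate/density depend on externally supplied reference
  constants and inherit their uncertainty.
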