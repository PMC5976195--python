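# Methods

`panelforge` builds and validates SNP panels for individual identification
of wild ungulates (the default parameterization follows a moose,
*Alces alces*, monitoring panel). This note records the models implemented,
the defaults and why they were chosen, and what the synthetic-data module
does and does not emulate.

## Digest planning

Reduced-representation libraries start from a restriction digest. The
planner treats cut sites as a Poisson process: the per-bp probability that
a recognition motif starts at a position is the product over motif
positions of base probabilities, with `p(G)=p(C)=gc/2` and
`p(A)=p(T)=(1-gc)/2`; IUPAC degeneracies sum their bases. Fragment lengths
are then exponential with mean `mu = 1/p_cut`, and the fraction of genomic
base mass on fragments inside a size-selection window `(a, b)` is

    [(a + mu) e^(-a/mu) - (b + mu) e^(-b/mu)] / mu.

Base-mass (length-biased) weighting is used rather than fragment-count
weighting because breadth of coverage is a base-mass quantity; for Eae I
(`YGGCCR`) at GC 0.45 on a 3 Gb genome this gives mu = 1561 bp,
1.92 million cut sites, and 2.5% of the genome in a 300–500 bp window —
consistent with typical planning figures for this enzyme (a rounded
1500 bp mean and a ~2% breadth target at 20X). Read-length effects on
breadth are deliberately not modeled; the window mass is reported as the
breadth estimate and the read-depth target is recorded, not multiplied in.

## Catalog simulation

The synthetic catalog stands in for a de novo stack catalog. Each locus is
a random 150 bp consensus with a SNP planted at an offset that admits
40 bp invariant flanks. Population structure follows the Balding–Nichols
construction: an ancestral minor-allele frequency `p` is drawn uniformly
on `maf_spectrum` (default 0.02–0.5, wide enough that the MAF > 0.2 filter
has bite), and each population's frequency is Beta-distributed with mean
`p` and variance `p(1-p)F`, with `F` the target differentiation (default
0.08, split over two populations of 17 individuals each, seven location
groups per population). Genotypes are Hardy–Weinberg within population;
missingness is applied uniformly after the truth matrix is recorded.

Special loci exercise the filters: multi-SNP loci carry a second SNP
inside the flank window; monomorphic stacks carry no SNP record; linked
pairs copy a source SNP's genotype column, re-drawing each genotype from
the source's population frequency with probability `linkage_copy_error`
(default 0.02). The re-draw construction (rather than a literal genotype
flip) keeps genotypes valid and gives a dosage correlation of about
`1 - e`, i.e. a tunable r² of about `(1-e)²`.

The generator emulates genotype-level properties only. It does not
simulate reads, sequencing error, allele-balance artifacts, stack
misassembly, or linkage blocks larger than the planted pairs, so passing
tests demonstrate correctness of the downstream statistics and filters on
idealized genotype data, not robustness to raw-data pathologies.

## Filtering cascade

Candidate SNPs pass, in order: (1) polymorphic stacks; (2) joint quality
criteria — exactly one SNP per locus, all three genotype classes observed,
called in at least 24 of 34 individuals, observed in every sampling
location, pooled MAF > 0.2; (3) least-linked selection to the target panel
size; (4) the assay flank rule (40 bp invariant flanks), applied last as
in assay design. The flank verdict is computed alongside the other
predicates but applied as the final stage so the report mirrors the
design-then-assay workflow; when all selected SNPs already satisfy it the
stage is a no-op.

"Least linked" is implemented as greedy minimax elimination: a SNP's
linkage score is its maximum pairwise r² (squared Pearson correlation of
0/1/2 dosages, pairwise-complete) against the current candidates, and the
highest scorer is removed until the target count remains. Ties are broken
by removing the lower-MAF (less informative) SNP, then the
lexicographically smaller id, making the selection deterministic. Greedy
minimax is a documented choice — the per-SNP "r² score" admits several
readings — and is exact on the planted-pair constructions the tests use.
MAF is computed pooled over populations after missing-data exclusion.
Hardy–Weinberg is not a discovery-stage filter (it belongs to validation);
a `hwe_alpha` hook exists but defaults off.

## Validation statistics

* **HWE**: the exact conditional test — given the sample size and minor
  allele count, heterozygote counts follow the standard hypergeometric-
  style null with weight `2^n_AB`; the two-sided p-value sums all
  configurations no more probable than the observed one. Computed with
  log-gamma arithmetic and verified against exact-integer enumeration.
* **LD**: r² on dosage vectors; significance by a seeded permutation test
  (plus-one corrected) rather than an MCMC exact test — same null,
  deterministic given the seed. The test is mildly conservative because
  dosage correlations are discrete.
* **F_st**: the Weir–Cockerham (1984) theta, summing among-population,
  among-individual and within-individual variance components over loci.
  Loci with fewer than two called populations are skipped. Small negative
  estimates for undifferentiated data are expected and not clipped.
* **Probability of identity**: per locus, `PI = sum p_i^4 +
  sum_{i<j} (2 p_i p_j)^2` for unrelated pairs and `PI_sibs = 0.25 +
  0.5*S2 + 0.5*S2^2 - 0.25*S4` (with `S2 = sum p_i^2`, `S4 = sum p_i^4`)
  for full siblings; both equal brute-force genotype-pair enumeration to
  1e-12. Cumulative curves order loci most informative (lowest per-locus
  PI) first. At MAF 0.5, five loci give PI = 0.375^5 ≈ 7.4e-3 and ten give
  PI_sibs = 0.59375^10 ≈ 5.4e-3, both below the 0.01 working bound.
* **Relatedness**: Lynch & Ritland (1999), locus-weighted and symmetrized
  by averaging the two reference/proband directions, and Ritland (1996)
  with equal locus weights (biallelic loci). Monomorphic reference loci
  and loci missing in either sample are skipped. Note the LR heterozygote-
  reference weight is singular at p = 0.5 exactly; such loci contribute
  nothing in that degenerate case, which is why recovery tests use a
  spread of frequencies. Reference frequencies should come from the
  pruned sample set, which is the pipeline's order of operations.
* **Pruning**: pairs with r above 0.35 are broken greedily, removing the
  individual in the most flagged pairs (ties: lexicographically first)
  until none remain; an isolated pair loses exactly one member.

## Replicate error estimation

The validation design replicates 2 samples 10 times and 12 samples twice.
Per locus and group, the consensus is the plurality call among amplified
replicates and the mismatch count is the number of amplified calls
deviating from it; for a disagreeing duplicate pair this counts one
mismatch in two amplified calls. (Excluding tied groups instead would
silence every disagreement in the 2-replicate groups and bias the
duplicate-group rate to zero, so plurality counting is used.) The
per-locus rate pools mismatches over groups; the overall rate is the
unweighted mean over loci, and the 10x and 2x group classes are also
reported separately. Mismatches with an unambiguous consensus are
classified as dropout (het to hom), drop-in (hom to het) or other
(hom to the other hom).

Error injection in the simulator is conditional: dropout applies to
heterozygotes, drop-in to homozygotes. `calibrated_error_model` converts a
target marginal rate (e.g. the 0.002 panel figure) into conditional rates
analytically, using the expected heterozygote fraction of the MAF
spectrum, with a 2:1 dropout:drop-in share.

Call-rate filtering removes SNP columns below 75% first, then re-judges
sample rows; the threshold is a strict less-than, so a sample at exactly
0.75 is retained.

## Assignment

Sex is a Y-presence test: five markers with a fixed male haplotype
(T, G, G, T, C); at least 3/5 positive amplifications call a male, zero
positives with autosomal call rate of at least 75% call a female, zero
positives on a failing sample is no-call, and anything between is
ambiguous. A marker amplifying a non-male allele is treated as negative.
The five markers carry per-marker enable flags (one marker is known to
underperform in practice and can be switched off without changing the
3-of-5 rule's denominator semantics).

Species diagnosis checks a five-marker mitochondrial profile against
per-species allele sets; all compatible species are returned, and when
none is compatible a nearest-species ranking by mismatch count is
reported separately so novel haplotypes are flagged rather than
force-assigned. Roe deer and reindeer are mutually inseparable when the
profile carries C at the first marker — the table's documented gap.

Individual matching single-links samples whose genotypes disagree at no
more than `max_mismatch` loci (default 2; at an error rate of 0.002 over
83 loci a sample pair expects about 0.33 mismatches) over at least
`min_overlap` jointly called loci.

## Problem sizes and numerical choices

The test suite and pipeline defaults use desk-scale simulations chosen to
make Monte-Carlo tolerances meaningful: theta recovery averages 20 seeds
of 200 loci x 200 individuals (tolerance ±0.02); relatedness recovery uses
500 loci x 100 dyads (±0.05); error-rate recovery uses 200 simulations of
the 83-locus validation design (±30% relative at 0.002); the LD size check
uses 400–500 null pairs at 399 permutations (±0.03 around 0.05).
Permutation counts in the pipeline default to 199 per pair. All
randomness flows from explicit seeds; identical configuration and seed
reproduce byte-identical reports.

Known limitations: no read-level simulation; the Genepop writer is
biallelic-only; the LD permutation test is conservative under heavy ties;
greedy least-linked selection and greedy pruning are heuristics (both are
verified against brute force only on small constructions); and the
species table's ambiguity handling assumes the packaged allele sets are
exhaustive for the five species.
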