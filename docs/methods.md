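# Methods

## Model and procedure

The package estimates effective population size (Ne) from the decay of
linkage disequilibrium (LD) with physical distance in unphased diploid SNP
genotypes.  Under neutral drift–recombination balance, Sved's
approximation relates expected LD between loci at recombination distance
*c* Morgans to population size, E[r²] ≈ 1/(1 + 4Ne·c); inverting gives
Ne = (1/4c)(1/r² − 1).  LD at distance *c* integrates drift over roughly
the last 1/(2c) generations, so each distance bin is assigned the
generation T = 1/(2c) and the binned decay curve becomes an Ne-versus-time
trajectory: long-range bins (large *c*) estimate recent Ne, short-range
bins ancient Ne.

Assumptions inherited from this framework: random mating, no selection or
migration structure, a linear genetic map (physical distance is converted
at a genome-average rate, default 1 cM/Mb), and that bin-mean r² is an
adequate stand-in for the expectation at the bin's mean pair distance.
Sved's one-term form also ignores mutation and higher-order drift terms;
it is known to be least accurate at small 4Ne·c, which motivates the
mid-range pooling described below.

## r² estimator

Phase is unavailable in array data, so LD is measured as the squared
Pearson correlation of 0/1/2 genotype dosages over pairwise-complete
samples (the composite estimator).  Pairs with fewer than 3 complete
samples or a locus monomorphic on the complete subset are undefined and
are skipped and counted rather than imputed.  Observed r² carries a
finite-sample inflation of order 1/n; the trajectory subtracts 1/n by
default (1/(2n) and no correction are selectable, and the mode is stamped
into every output).  Bins whose corrected r² is ≤ 0 carry no usable
signal and are dropped with a logged reason.

## Binning

Pairs are restricted to the same chromosome with separation in
[mindist, maxdist) = [10 kb, 40 Mb) by default.  Bins are `num_bins` (40)
equal-width, left-closed/right-open intervals over that range; a fixed
`binwidth` is honoured only when `num_bins` is unset, because the two
parameterisations cannot both hold over this range.  Each bin reports the
mean pair distance (used as the bin's representative distance — less
biased than the midpoint when pair density varies), mean r², and pair
count; bins under `min_pairs_per_bin` (100) are flagged low-confidence
rather than dropped, as are trajectory points beyond a configurable
generation horizon (default 2000).  Chromosomes over `max_snps_per_chrom`
are uniformly thinned with an explicit seed before pairing, preserving the
distance distribution.

## Quality control

Filters run in a fixed order — sample call rate, SNP call rate, MAF, HWE
exact test, unplaced/sex-chromosome removal — and each removed SNP is
attributed to the first filter it fails, so report counts are disjoint and
`before − removed = after` holds exactly.  Sample missingness is computed
on the pristine SNP set; SNP statistics on the surviving samples.
Defaults: >5% missing per sample or SNP removed, MAF < 5% removed
(monomorphic SNPs fall in here as MAF 0; a separate monomorphic filter
applies only when the MAF filter is disabled), HWE exact p < 10⁻⁶
removed.  The HWE test is the standard two-sided conditional exact test
without mid-p correction, computed with log-gamma terms and renormalised;
the test suite checks it against an exact rational-arithmetic enumeration
for every genotype-count triple up to n = 50.

## Synthetic data

The simulator is a forward Wright–Fisher model: a diploid population of
piecewise-constant size N evolves in discrete generations; each offspring
receives one recombinant gamete from each of two uniformly drawn parents;
crossover occurs independently per adjacent-site interval with probability
equal to the interval's map length in Morgans (at most one crossover per
interval per meiosis, no interference; chromosomes assort freely).  Sites
start as independent biallelic loci with frequencies uniform on
[0.05, 0.95] and a burn-in (default 4N generations) establishes
drift–recombination equilibrium before the scheduled epochs run.  There is
no mutation, so drift steadily fixes sites; fixed sites are retained in
the output for QC to remove, mirroring monomorphic probes on real arrays.

A forward (rather than coalescent) simulator was chosen for direct
per-generation control of N, matching the per-generation semantics of
T = 1/(2c); it is comfortably fast at the study scale (N ≤ 1000, ≤ 2000
sites).  What the generator does **not** emulate: ascertainment bias of
commercial SNP chips, heterogeneous recombination maps, genotyping error,
relatedness structure, or selection.  Passing validation therefore shows
the estimator recovers truth under the model's own assumptions, not that
real-array complications are handled.

## Validation studies and problem sizes

Two canned studies (`ldne.experiments`) drive the heavy validation:

* **Constant-Ne recovery** — N = 100, burn-in 400 generations, panels of
  2 chromosomes × 500 sites × 50 Mb at 1 cM/Mb, n = 50 sampled, 10
  replicate seeds through QC → LD → Ne with the 1/n correction.  The
  per-replicate estimate is the pair-count-weighted median Ne over bins
  with mean pair distance in [1, 15] Mb.  That window is fixed a priori:
  below ~1 Mb (4Ne·c ≲ 4) Sved's one-term approximation biases Ne upward,
  while in the longest bins the corrected signal (r² − 1/n ≈ 0.005) is
  dominated by sampling noise at n = 50.  The same runs, pooled pair-wise
  across replicates per bin, yield the decay-monotonicity statistic (the
  Spearman rank correlation between bin index and pooled mean r²);
  per-replicate profiles from 1000-site panels are too sparse for a stable
  per-seed rank test.
* **Decline detection** — two epochs (N 500 for 300 generations, then
  N 50 for 30), burn-in 2 × 500 generations, panels of 2 × 500 sites ×
  10 Mb (20 kb spacing, so the trajectory resolves T > 100 as well as the
  recent epoch), 10 replicate seeds.  Recent Ne is the pair-weighted
  median over points with T ≤ 30 (the recent epoch's length); ancient Ne
  the same over points with T > 100.  A detected decline is
  recent < ancient.

These sizes keep the full validation suite in the minutes range on one
CPU while leaving each bin hundreds-to-thousands of supporting pairs.

## Numerical and design choices

* Allele2 is the dosage-counted allele everywhere (the binary-PLINK
  convention); MAF is min(p₂, 1 − p₂).
* The text PLINK dialect carries no marker of which allele is counted, so
  the text reader orients alleles lexicographically; panels written by
  this package round-trip exactly, while a panel with reversed allele
  order is canonicalised (dosages and labels flipped together, genotypes
  preserved in meaning).
* Half-missing text genotypes ("A 0") are treated as fully missing.
* Pair distance is |bp_i − bp_j|; a pair at exactly `mindist` is
  included, at exactly `maxdist` excluded.
* Trajectory convergence (`stabilized_from_T`) is the smallest T from
  which the relative change in Ne between every pair of adjacent points
  stays below a tolerance (default 1%).
* "Current Ne" in the summary row is the smallest-T point; the
  ~10-generations-ago value uses nearest-T matching.
* Duplicate (chrom, bp) variants are accepted at read time; dropping data
  silently is never a reader's job.

## Known limitations

* Sved's relation is an approximation; even on ideal simulated data,
  single-bin inversions scatter widely at n = 50 and short-distance bins
  are biased — consumers should pool bins, as the validation studies do.
* The 1/n correction is a first-order de-inflation, not an exact small-
  sample theory; with very small n the corrected long-range signal can
  vanish entirely (bins are then dropped and reported).
* No confidence intervals are attached to Ne points.
* The physical→genetic map is linear; regional recombination-rate
  variation will distort both c and T in proportion.
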